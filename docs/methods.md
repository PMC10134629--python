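# Methods

## The central power relation

The package models a genome-wide association test as a likelihood-ratio
test of nested normal linear models, y ~ Norm(0, σ₀²) against
y ~ Norm(βx, σ₁²), over N individuals. With R² the fraction of variance
explained by the alternative, the statistic q² = N ln(RSS₀/RSS₁) =
N ln(1 + R²/(1−R²)) is asymptotically χ²₁ under the null and noncentral
χ² with noncentrality q₁² = N R²/(1−R²) under the alternative. All
power arithmetic uses the one-tailed normal approximation: power =
Φ(q₁ − z_I) with q₁ the positive root. The opposite-tail contribution
Φ(−q₁ − z_I) is below 10⁻⁸ at genome-wide thresholds and is omitted.
Setting power = 1 − β gives the central identity
(z_I − z_II)² = N R²/(1−R²), which every other routine inverts or
perturbs.

Assumptions worth keeping in mind: effects are small (R² ≪ 1, the
regime where the noncentral-χ² and shifted-normal pictures coincide);
tests are treated as independent (the A ≈ 10⁶ figure for GWAS already
stands in for the effective number of independent SNPs after linkage
disequilibrium); and Bonferroni rather than FDR control.

## Tail conventions

A per-test p-value threshold p maps to a normal quantile two ways:
`threshold_as_tail` reads p itself as the upper-tail area (z = 5.327 at
5×10⁻⁸), `two_sided_halved` reads it as a two-sided p-value and uses
p/2 (z = 5.451). Published treatments mix the two: the scale factor
ζ(ζ−z_II)/2 = 17.15 requires ζ = 5.451, while the numerically exact
calibration values (equivalent strengths near 16.7/123/4315, contour
slopes 17.0 and 14.4) are reproduced under `threshold_as_tail` and not
under the halved convention (which yields 18.9/151/6168). Both are
implemented; each operation's documented default is the convention
under which its reference values are reproduced, and every design
carries its convention explicitly. At two-decimal rounding the
equal-performance accuracies are insensitive to the choice.

Tail numerics go through `scipy.stats.norm.sf`/`isf` (complementary-
error-function based), never 1 − CDF, so nothing underflows at z ≈ 5.5;
survival values are accurate to ~15 significant digits on |z| ≤ 8. The
steepest-descents form (2π)^(−1/2) z⁻¹ e^(−z²/2) is the one-term Mills
ratio bound: it over-estimates the exact tail for all z > 0 with
relative error ~z⁻², under 7% beyond z = 4. It is provided for the
analytic approximations only; all "numerically exact" results use the
exact survival function.

## Oracular prior calibration

Because the critical effect size depends on the design only through
(z_I − z_II)²/N, the prior strength matching a ρ-fold cohort increase
solves (z_I(S) − z_II)² = (z_I(1) − z_II)²/ρ. This is explicit —
z_I(S) = z_II + (z_I(1) − z_II)/√ρ — so no iteration is used; the
strength is recovered as S = SF(z_I(S))/threshold. The absolute N
cancels exactly, a property asserted in tests by solving the full
critical-R² contour match with Brent's method at N ∈ {10³, 10⁵, 10⁷}
(the independent route kept deliberately separate from the closed
form). Contour slopes |d ln S/d ln N| use N ∝ (z_I(S) − z_II)² (the
small-R² contour): a centered finite difference in ln S with relative
step 0.5% for the local slope, and the chord for the secant. The
"slope at strength 100" benchmark is the S = 1 → 100 secant; the local
derivative there is ≈12 and does not reproduce the published 14.4. The
local slope at S = 1 agrees with the analytic Mills-ratio expression
(φ(ζ)/SF(ζ))·(ζ−z_II)/2 to three significant figures.

## Non-oracular priors

A prior of accuracy f keeps a true positive in the tested set with
probability f, so overall power factorizes as f × statistical power
and a requested overall power 1−β forces the test to power (1−β)/f —
infeasible once f ≤ 1−β (raised as a distinct `InfeasiblePowerError`).
The equal-performance accuracy solves
(z_I(S) − z_{(1−β)/f})² = (z_I(1) − z_{1−β})². Of the two square roots,
the branch z_{(1−β)/f} = z_I(S) − (z_I(1) − z_II) is physical: it is
the only one with statistical power below 1, giving f* in (1−β, 1].
f* is kept at full precision internally and rounded to two decimals
only at reporting.

## Doubling-time pipeline

Studies are grouped by trait, dates converted to fractional years
(year + (day-of-year − 1)/days-in-year), and reduced to effective
studies by the strict running-maximum rule on loci counts (ties drop;
the first study is always kept). The pipeline drops studies reporting
zero significant loci before selection: such a study contributes no
association row to a catalog and cannot enter a log-scale fit.

Growth fits are ordinary least squares of log₂(response) on time
(statsmodels OLS; time is mean-centered so the quadratic design matrix
stays conditioned — slopes are unaffected). Model comparison uses the
standard nested F, F = [(RSS_reduced − RSS_full)/Δdf]/[RSS_full/df_resid],
computed directly from residual sums of squares so degenerate cases are
controlled: a numerically saturated full model yields p = 0 when it
explains real extra variation and p = 1 when there is none; a constant
response returns slope exactly 0 with τ reported as infinite and
flagged. A quadratic comparison needs at least four points; with three
it is reported as NaN. Published prose describes the F-statistic's
denominator differently ("variation explained by the full model");
the standard nested form is used here.

The equality test for cohort vs loci doubling times defaults to
z_τ = (τ_N − τ_L)/√(τ_N² + τ_L²) — the form as printed in the analysis
this reproduces — with the conventional Wald denominator
√(σ_N² + σ_L²) available as `standard_errors`. The printed denominator
is strikingly conservative (it scales by the doubling times themselves,
not their errors); neither form is asserted as correct. No
multiple-testing correction is applied across traits.

## Synthetic catalog generator

The generator emulates exactly the structure the pipeline assumes:
cohorts N(t) = N₀·2^(t/τ_N + ε_t) with ε_t ~ Norm(0, noise_sd) in log₂
units; true-locus effect sizes drawn by inverse transform from the
truncated power law ρ(R²) ∝ (R²)^(−(τ_L+τ_N)/τ_L) on [r2_min, r2_max]
(the exponent −1 edge uses the logarithmic CDF branch); and a study
detecting precisely the loci with R² ≥ z_I²/N(t), the 50%-power
detection threshold — the same approximation from which the power law
is derived, rather than the 80%-power critical R². One
`numpy.random.Generator` seeded from the single config seed drives all
randomness (effect sizes first, then cohort noise), so identical
configurations reproduce byte-identical tables.

Defaults: N₀ = 8377 (a 2010-scale case-control effective cohort),
τ_N = 1.5 y, τ_L = 1.6 y, eight studies evenly spanning 2010–2020,
noise_sd = 0.1, 10⁴ true loci, r2_max = 0.01 with r2_min an order of
magnitude below the final study's detection threshold so truncation
does not bind at observed thresholds.

What the generator does *not* emulate — and hence what passing tests do
not show about real catalogs: loci counts carry no noise of their own
(they are a deterministic threshold function of the cohort trajectory
and the frozen effect-size draws), so the OLS standard error of the
loci doubling time is not a calibrated sampling error; upper truncation
of the effect-size support slightly accelerates early loci discovery,
biasing τ̂_L downward by a few percent at small N₀; and there is no
winner's curse, LD structure, or study-level heterogeneity in
ascertainment. Recovery guarantees in the test suite are therefore
anchored on the cohort doubling time, whose generative model matches
the fitted model exactly; the loci response is checked through the
weaker ratio-recovery and equality-test properties.

## Numerical and interface choices

Quantile/tail inversion is exact to 1 unit in the 12th digit over tail
areas [10⁻²³, 0.5] and quantiles z ∈ [−3, 8]; below z ≈ −3 the survival
function saturates toward 1 and roundtrips are limited by float
spacing, not the algorithms. Effective sample sizes are kept real and
rounded only at reporting. Report files print τ and σ_τ to one decimal
and accuracies to two, mirroring conventional reporting; full precision
flows through the API. The study-table format is tab-separated with
columns trait/date/cases/controls/sample_size/n_loci; malformed rows
are rejected individually with row-numbered diagnostics and only an
all-rejected file is fatal. CLI exit codes: 0 success, 2 input error,
3 infeasible query.

## Known limitations

The calculus is asymptotic and normal-theory throughout; it does not
model case-control imbalance beyond the effective-size reduction, rare
variants, or FDR-style error control. The doubling-time pipeline takes
the reported cohort size at face value (discovery vs replication staging
is the data provider's decision). Published calibration strengths
(16.8/124.2/4321.5) differ from this package's exact recomputation
(16.7/123.3/4314.5) by up to 0.7% under every tail convention examined;
the exact values are reported as computed.
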