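"""The central power relation for genome-wide association tests.

A univariate association test of a phenotype on one genotype feature is a
likelihood-ratio test between nested normal linear models.  With N
individuals and a fraction R^2 of phenotypic variance explained, the LRT
statistic q^2 = N ln(1 + R^2/(1-R^2)) is asymptotically chi-square(1)
under the null and noncentral chi-square with noncentrality
q1^2 = N R^2/(1-R^2) under the alternative.  In the normal approximation
the power at one-tailed significance quantile z_I is Phi(q1 - z_I), which
ties the four design quantities together:

    (z_I - z_II)^2 = N R^2 / (1 - R^2)

where z_II is the (negative, at power > 50%) quantile of the type-II
error.  Everything in this module is an exact algebraic consequence of
that relation plus Bonferroni control of the family-wise error rate:
testing A hypotheses at FWER alpha means a per-test threshold alpha/A,
and a hard prior of strength S >= 1 (testing only A/S hypotheses) relaxes
it to S*alpha/A.

Case-control designs enter through the effective sample size
N = 2 * harmonic_mean(N1, N2) = 4 N1 N2 / (N1 + N2), the balanced cohort
with the same variance of the allele-frequency difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

from .stats_core import TailConvention, upper_quantile

__all__ = [
    "TestDesign",
    "CaseControlCounts",
    "PowerPoint",
    "GWAS_THRESHOLD",
    "RNASEQ_THRESHOLD",
    "effective_sample_size",
    "diff_variance",
    "lrt_statistic",
    "power_at",
    "critical_r2",
    "required_n",
]

#: Conventional genome-wide significance threshold (~1e6 independent SNPs at FWER 0.05).
GWAS_THRESHOLD = 5e-8
#: Transcriptome-wide analog: 25,000 gene tests at FWER 0.05.
RNASEQ_THRESHOLD = 2e-6


@dataclass(frozen=True)
class TestDesign:
    """Multiple-testing design: FWER, number of tests, tail convention.

    The per-test threshold is ``fwer_alpha / total_tests`` (Bonferroni)
    unless ``per_test_threshold`` is given explicitly, in which case it
    wins and ``fwer_alpha``/``total_tests`` are informational.
    """

    fwer_alpha: float = 0.05
    total_tests: float = 1e6
    per_test_threshold: float | None = None
    convention: TailConvention = TailConvention.THRESHOLD_AS_TAIL

    def __post_init__(self) -> None:
        thr = self.threshold
        if not 0.0 < thr < 1.0:
            raise ValueError(f"per-test threshold must lie in (0, 1), got {thr}")

    @property
    def threshold(self) -> float:
        """Per-test p-value threshold."""
        if self.per_test_threshold is not None:
            return self.per_test_threshold
        return self.fwer_alpha / self.total_tests

    def significance_quantile(self, prior_strength: float = 1.0) -> float:
        """z_I at the (possibly prior-inflated) threshold S*alpha/A."""
        if prior_strength < 1.0:
            raise ValueError(f"prior strength must be >= 1, got {prior_strength}")
        inflated = prior_strength * self.threshold
        if inflated >= 1.0:
            raise ValueError(
                f"inflated threshold {inflated:.3g} >= 1: prior strength "
                f"{prior_strength} exhausts the multiple-testing burden"
            )
        return upper_quantile(self.convention.tail_area(inflated))

    @classmethod
    def gwas(cls, convention: TailConvention = TailConvention.THRESHOLD_AS_TAIL) -> "TestDesign":
        """GWAS preset: threshold 5e-8 (FWER 0.05 over 1e6 tests)."""
        return cls(fwer_alpha=0.05, total_tests=1e6, convention=convention)

    @classmethod
    def rnaseq(cls, convention: TailConvention = TailConvention.THRESHOLD_AS_TAIL) -> "TestDesign":
        """RNAseq preset: threshold 2e-6 (FWER 0.05 over 25,000 genes)."""
        return cls(fwer_alpha=0.05, total_tests=25_000, convention=convention)


@dataclass(frozen=True)
class CaseControlCounts:
    """Case and control counts, optionally with a shared allele frequency."""

    n_cases: float
    n_controls: float
    allele_freq: float | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError(
                f"case/control counts must be >= 1, got "
                f"({self.n_cases}, {self.n_controls})"
            )


class LRTStatistic(NamedTuple):
    """LRT statistic q^2 and its noncentrality q1^2 = N R^2/(1-R^2)."""

    q2: float
    q1_squared: float


@dataclass(frozen=True)
class PowerPoint:
    """A self-consistent (N, R^2, z_I, z_II) solution of the power relation."""

    n: float
    r2: float
    z_i: float
    z_ii: float
    power: float
    q1_squared: float = field(default=0.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "q1_squared", self.n * self.r2 / (1.0 - self.r2))


def effective_sample_size(counts: CaseControlCounts) -> float:
    """Balanced-design-equivalent cohort size: twice the harmonic mean.

    Returns 4 N1 N2 / (N1 + N2) as a real number; round only at
    reporting (e.g. 3659 cases / 4897 controls -> 8377).
    """
    n1, n2 = counts.n_cases, counts.n_controls
    return 4.0 * n1 * n2 / (n1 + n2)


def diff_variance(counts: CaseControlCounts) -> float:
    """Null variance of the case-control allele-frequency difference.

    Var(p1 - p2) = p(1-p)/2 * (1/N1 + 1/N2), minimized for a balanced
    split of a fixed total; identically p(1-p) * 2/N with N the
    effective sample size.
    """
    p = counts.allele_freq
    if p is None or not 0.0 < p < 1.0:
        raise ValueError(f"allele frequency must lie in (0, 1), got {p}")
    return 0.5 * p * (1.0 - p) * (1.0 / counts.n_cases + 1.0 / counts.n_controls)


def lrt_statistic(r2: float, n: float) -> LRTStatistic:
    """LRT statistic and noncentrality for variance fraction ``r2`` at size ``n``.

    q^2 = N ln(1 + R^2/(1-R^2)) <= q1^2 = N R^2/(1-R^2), with equality
    only at R^2 = 0; the two agree to first order in R^2, which is the
    regime of genome-wide association effects.
    """
    if not 0.0 <= r2 < 1.0:
        raise ValueError(f"variance fraction must lie in [0, 1), got {r2}")
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    ratio = r2 / (1.0 - r2)
    return LRTStatistic(q2=n * math.log1p(ratio), q1_squared=n * ratio)


def power_at(
    n: float,
    r2: float,
    design: TestDesign,
    prior_strength: float = 1.0,
) -> float:
    """Power Phi(q1 - z_I) to detect variance fraction ``r2`` at size ``n``.

    ``q1`` is the positive root of the noncentrality; the opposite-tail
    contribution Phi(-q1 - z_I) is negligible at genome-wide thresholds
    and omitted.  At r2 = 0 this returns the per-test type-I tail.
    """
    z_i = design.significance_quantile(prior_strength)
    q1 = math.sqrt(lrt_statistic(r2, n).q1_squared)
    from .stats_core import upper_tail

    # Phi(q1 - z_I) = P(Z > z_I - q1)
    return upper_tail(z_i - q1)


def critical_r2(
    n: float,
    design: TestDesign,
    prior_strength: float = 1.0,
    power: float = 0.8,
) -> float:
    """Smallest detectable variance fraction at the requested power.

    R^2 = D^2 / (N + D^2) with D = z_I - z_II; the unique R^2 at which
    :func:`power_at` returns exactly ``power``.
    """
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must lie in (0, 1), got {power}")
    z_i = design.significance_quantile(prior_strength)
    z_ii = upper_quantile(power)  # negative for power > 0.5
    d2 = (z_i - z_ii) ** 2
    return d2 / (n + d2)


def required_n(
    r2: float,
    design: TestDesign,
    prior_strength: float = 1.0,
    power: float = 0.8,
) -> float:
    """Cohort size needed to detect variance fraction ``r2``: N = D^2 (1-R^2)/R^2."""
    if not 0.0 < r2 < 1.0:
        raise ValueError(f"variance fraction must lie in (0, 1), got {r2}")
    if not 0.0 < power < 1.0:
        raise ValueError(f"power must lie in (0, 1), got {power}")
    z_i = design.significance_quantile(prior_strength)
    z_ii = upper_quantile(power)
    d2 = (z_i - z_ii) ** 2
    return d2 * (1.0 - r2) / r2
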