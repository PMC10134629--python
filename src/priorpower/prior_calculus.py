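"""Oracular hard-prior calculus: prior strength versus cohort growth.

A hard prior of strength S restricts testing to A/S of the A hypotheses
and relaxes the per-test threshold to S*alpha/A.  An *oracular* prior
(accuracy f = 1) keeps every true positive in the tested subset, so its
whole effect is the smaller significance quantile z_I(S).  Because the
critical effect size depends on design only through (z_I - z_II)^2 / N,
the prior strength equivalent to a rho-fold cohort increase solves

    (z_I(S) - z_II)^2 = (z_I(1) - z_II)^2 / rho,

which is explicit in z_I(S) and independent of the absolute N — the
contour calibration is a property of the tail alone.  Along an
equal-critical-R^2 contour, ln S falls off against ln N with slope
~ zeta (zeta - z_II)/2 (about 17 for GWAS at 80% power): cohort size is
exponentially more valuable than prior strength.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .power_model import TestDesign, critical_r2
from .stats_core import upper_quantile, upper_tail

__all__ = [
    "PriorSpec",
    "CalibrationPoint",
    "inflated_threshold",
    "equivalent_strength_exact",
    "population_ratio_approx",
    "slope_scale",
    "contour_slope",
    "critical_r2_grid",
]


@dataclass(frozen=True)
class PriorSpec:
    """A hard prior: fold-reduction in tests S and accuracy f (1 = oracular)."""

    strength: float = 1.0
    accuracy: float = 1.0

    def __post_init__(self) -> None:
        if self.strength < 1.0:
            raise ValueError(f"prior strength must be >= 1, got {self.strength}")
        if not 0.0 < self.accuracy <= 1.0:
            raise ValueError(f"prior accuracy must lie in (0, 1], got {self.accuracy}")


@dataclass(frozen=True)
class CalibrationPoint:
    """A cohort fold-increase and the prior strength matching its power gain."""

    population_fold: float
    equivalent_strength: float
    power: float
    design: TestDesign


def inflated_threshold(design: TestDesign, prior_strength: float) -> float:
    """Per-test p-value cutoff under a prior of strength S: S*alpha/A."""
    if prior_strength < 1.0:
        raise ValueError(f"prior strength must be >= 1, got {prior_strength}")
    inflated = prior_strength * design.threshold
    if inflated >= 1.0:
        raise ValueError(f"inflated threshold {inflated:.3g} >= 1 is not a p-value cutoff")
    return inflated


def equivalent_strength_exact(
    population_fold: float,
    design: TestDesign,
    power: float = 0.8,
) -> float:
    """Prior strength whose power gain equals a ``population_fold`` cohort increase.

    Solves (z_I(S) - z_II)^2 = (z_I(1) - z_II)^2 / fold on the branch
    z_I(S) < z_I(1), then converts z back to a tail area:
    S = P(Z > z_I(S)) / per-test-threshold.  Exact (no steepest-descents
    step) and independent of the cohort size at which contours are drawn.
    """
    if population_fold < 1.0:
        raise ValueError(f"population fold must be >= 1, got {population_fold}")
    z1 = design.significance_quantile(1.0)
    z_ii = upper_quantile(power)
    z_s = z_ii + (z1 - z_ii) / math.sqrt(population_fold)
    if z_s <= z_ii:
        raise ValueError(
            f"fold {population_fold} pushes the significance quantile to the "
            "power quantile: no prior strength achieves this"
        )
    tail = design.convention.tail_area(design.threshold)
    strength = upper_tail(z_s) / tail
    if strength * design.threshold >= 1.0:
        raise ValueError(
            f"fold {population_fold} requires prior strength {strength:.3g}, "
            "whose inflated threshold is no longer a p-value cutoff"
        )
    return strength


def population_ratio_approx(
    s1: float,
    s2: float,
    design: TestDesign,
    power: float = 0.8,
    method: str = "linear",
) -> float:
    """Approximate cohort ratio N1/N2 matching a prior-strength change S1 -> S2.

    ``linear``: 1 + (2 / (zeta (zeta - z_II))) ln(S2/S1);
    ``exponential``: (S2/S1) ** (2 / (zeta (zeta - z_II))).
    The two agree to second order in the (small) exponent.
    """
    if s1 < 1.0 or s2 < 1.0:
        raise ValueError(f"prior strengths must be >= 1, got ({s1}, {s2})")
    zeta = design.significance_quantile(1.0)
    z_ii = upper_quantile(power)
    coeff = 2.0 / (zeta * (zeta - z_ii))
    log_ratio = math.log(s2 / s1)
    if method == "linear":
        return 1.0 + coeff * log_ratio
    if method == "exponential":
        return math.exp(coeff * log_ratio)
    raise ValueError(f"method must be 'linear' or 'exponential', got {method!r}")


def slope_scale(design: TestDesign, power: float = 0.8) -> float:
    """Analytic contour-slope scale zeta (zeta - z_II) / 2.

    With the two-sided-halved GWAS quantile zeta = 5.45 and 80% power
    (z_II = -0.84) this is 17.15: the ln N per ln S exchange rate.
    """
    zeta = design.significance_quantile(1.0)
    z_ii = upper_quantile(power)
    return zeta * (zeta - z_ii) / 2.0


def _log_contour_n(design: TestDesign, power: float, strength: float) -> float:
    """ln N (up to an additive constant) on the equal-critical-R^2 contour.

    Small-effect form: N proportional to (z_I(S) - z_II)^2.  Accepts
    S slightly below 1 so centered finite differences at S = 1 work.
    """
    z_s = upper_quantile(design.convention.tail_area(strength * design.threshold))
    z_ii = upper_quantile(power)
    d = z_s - z_ii
    if d <= 0.0:
        raise ValueError(f"prior strength {strength} exceeds the feasible contour range")
    return 2.0 * math.log(d)


def contour_slope(
    design: TestDesign,
    power: float = 0.8,
    mode: str = "local_at",
    s_from: float = 1.0,
    s_to: float = 100.0,
    rel_step: float = 0.005,
) -> float:
    """Magnitude |d ln S / d ln N| along the equal-critical-R^2 contour.

    ``local_at`` takes a centered finite difference of ln S against ln N
    at ``s_from`` (relative step <= 1%); ``secant`` takes the chord from
    ``s_from`` to ``s_to``.  For GWAS at 80% power the local slope at
    S = 1 is 17.0 and the S = 1 -> 100 secant is 14.4.
    """
    if s_from < 1.0:
        raise ValueError(f"prior strength must be >= 1, got {s_from}")
    if mode == "local_at":
        if not 0.0 < rel_step <= 0.01:
            raise ValueError(f"relative step must lie in (0, 0.01], got {rel_step}")
        h = math.log1p(rel_step)
        # centered stencil; dipping infinitesimally below S = 1 is legitimate
        # for differentiation (the inflated threshold stays a valid tail area)
        s_lo, s_hi = s_from * math.exp(-h), s_from * math.exp(h)
        d_ln_n = _log_contour_n(design, power, s_hi) - _log_contour_n(design, power, s_lo)
        if d_ln_n == 0.0:
            raise ArithmeticError("degenerate finite-difference step on the contour")
        return abs(math.log(s_hi / s_lo) / d_ln_n)
    if mode == "secant":
        if s_to <= s_from:
            raise ValueError(f"secant needs s_to > s_from, got ({s_from}, {s_to})")
        d_ln_n = _log_contour_n(design, power, s_to) - _log_contour_n(design, power, s_from)
        if d_ln_n == 0.0:
            raise ArithmeticError("degenerate secant on the contour")
        return abs(math.log(s_to / s_from) / d_ln_n)
    raise ValueError(f"mode must be 'local_at' or 'secant', got {mode!r}")


def critical_r2_grid(
    n_values,
    s_values,
    design: TestDesign,
    power: float = 0.8,
) -> pd.DataFrame:
    """Critical R^2 over a (prior strength) x (cohort size) grid.

    Rows are prior strengths, columns cohort sizes; each cell is the
    smallest variance fraction detectable at the requested power.
    Decreasing along both axes.
    """
    n_values = np.asarray(list(n_values), dtype=float)
    s_values = np.asarray(list(s_values), dtype=float)
    grid = np.empty((s_values.size, n_values.size))
    for i, s in enumerate(s_values):
        for j, n in enumerate(n_values):
            grid[i, j] = critical_r2(n, design, prior_strength=s, power=power)
    return pd.DataFrame(grid, index=pd.Index(s_values, name="prior_strength"),
                        columns=pd.Index(n_values, name="cohort_size"))
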