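"""Non-oracular hard priors: power loss from excluded true positives.

A real prior keeps only a fraction f (its *accuracy*) of the true
positives inside the tested subset.  Detection then requires both that a
true positive is in the subset (probability f) and that the statistical
test fires (probability 1 - beta'), so the overall power is their
product.  To deliver a requested overall power 1 - beta, the test itself
must run at power (1 - beta)/f — impossible once f < 1 - beta.

The generalized design relation becomes

    (z_{S*alpha/A} - z_{(1-beta)/f})^2 = N R^2 / (1 - R^2),

reducing to the oracular relation at S = f = 1.  Equating its left-hand
side with the no-prior value defines the equal-performance accuracy
f*(S): above f* the prior beats no prior, below it the prior hurts.  For
GWAS at 80% power f* is ~89% at S = 10 and ~83% at S = 100 — the origin
of the rule of thumb that priors need ~90% accuracy to be worth using.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .power_model import TestDesign, critical_r2, required_n
from .stats_core import upper_quantile, upper_tail

__all__ = [
    "InfeasiblePowerError",
    "NonOracularQuery",
    "overall_power",
    "required_statistical_power",
    "generalized_relation",
    "equal_performance_accuracy",
    "equal_performance_curve",
]


class InfeasiblePowerError(ValueError):
    """Requested power exceeds what the prior accuracy permits."""


@dataclass(frozen=True)
class NonOracularQuery:
    """A design question under a non-oracular prior.

    Exactly one of ``n`` / ``r2`` is left None and solved for by
    :func:`generalized_relation`.
    """

    design: TestDesign
    strength: float = 1.0
    accuracy: float = 1.0
    requested_power: float = 0.8
    n: float | None = None
    r2: float | None = None

    def __post_init__(self) -> None:
        if self.strength < 1.0:
            raise ValueError(f"prior strength must be >= 1, got {self.strength}")
        if not 0.0 < self.accuracy <= 1.0:
            raise ValueError(f"prior accuracy must lie in (0, 1], got {self.accuracy}")
        if not 0.0 < self.requested_power < 1.0:
            raise ValueError(
                f"requested power must lie in (0, 1), got {self.requested_power}"
            )


def overall_power(statistical_power: float, accuracy: float) -> float:
    """Overall power = statistical power x inclusion probability f."""
    if not 0.0 <= statistical_power <= 1.0:
        raise ValueError(f"statistical power must lie in [0, 1], got {statistical_power}")
    if not 0.0 <= accuracy <= 1.0:
        raise ValueError(f"accuracy must lie in [0, 1], got {accuracy}")
    return statistical_power * accuracy


def required_statistical_power(requested_power: float, accuracy: float) -> float:
    """Test power (1 - beta)/f needed so the overall power reaches 1 - beta.

    Raises
    ------
    InfeasiblePowerError
        If (1 - beta)/f >= 1, i.e. the accuracy is at or below the
        requested power and no cohort size can deliver it.
    """
    if not 0.0 < requested_power < 1.0:
        raise ValueError(f"requested power must lie in (0, 1), got {requested_power}")
    if not 0.0 < accuracy <= 1.0:
        raise ValueError(f"accuracy must lie in (0, 1], got {accuracy}")
    stat = requested_power / accuracy
    if stat >= 1.0:
        raise InfeasiblePowerError(
            f"accuracy {accuracy} cannot deliver overall power {requested_power}: "
            f"the test would need power {stat:.3g} >= 1"
        )
    return stat


def generalized_relation(query: NonOracularQuery, solve_for: str) -> float:
    """Solve the generalized power relation for cohort size or effect size.

    The relation is the oracular one with z_I at the inflated threshold
    and z_II at the boosted statistical power (1 - beta)/f; at
    S = f = 1 it reduces exactly to the no-prior formulas.
    """
    stat_power = required_statistical_power(query.requested_power, query.accuracy)
    if solve_for == "n":
        if query.r2 is None or query.n is not None:
            raise ValueError("solving for n requires r2 set and n unset")
        return required_n(query.r2, query.design,
                          prior_strength=query.strength, power=stat_power)
    if solve_for == "r2":
        if query.n is None or query.r2 is not None:
            raise ValueError("solving for r2 requires n set and r2 unset")
        return critical_r2(query.n, query.design,
                           prior_strength=query.strength, power=stat_power)
    raise ValueError(f"solve_for must be 'n' or 'r2', got {solve_for!r}")


def equal_performance_accuracy(
    strength: float,
    design: TestDesign,
    requested_power: float = 0.8,
) -> float:
    """Accuracy f* at which a prior of strength S matches no prior at all.

    Equating the prior and no-prior design relations at common
    (N, R^2) gives z_{(1-beta)/f} = z_I(S) - (z_I(1) - z_II) on the
    physical branch (statistical power below 1), hence

        f* = (1 - beta) / P(Z > z_I(S) - (z_I(1) - z_II)).

    f* lies in (requested_power, 1]; S = 1 returns exactly 1.
    """
    if strength < 1.0:
        raise ValueError(f"prior strength must be >= 1, got {strength}")
    if not 0.0 < requested_power < 1.0:
        raise ValueError(f"requested power must lie in (0, 1), got {requested_power}")
    if strength == 1.0:
        return 1.0
    z1 = design.significance_quantile(1.0)
    z_s = design.significance_quantile(strength)
    z_ii = upper_quantile(requested_power)
    z_prime = z_s - (z1 - z_ii)
    f_star = requested_power / upper_tail(z_prime)
    if not requested_power < f_star <= 1.0 + 1e-12:
        raise ValueError(
            f"no equal-performance accuracy in ({requested_power}, 1] for "
            f"strength {strength}; got {f_star:.4g}"
        )
    return min(f_star, 1.0)


def equal_performance_curve(
    design: TestDesign,
    requested_power: float = 0.8,
    s_grid=(1.0, 10.0, 100.0, 1000.0),
) -> pd.DataFrame:
    """Equal-performance boundary f*(S) over a grid of prior strengths.

    Strictly decreasing in S and bounded below by the requested power:
    the stronger the prior, the more inaccuracy it can absorb, but never
    enough to tolerate f <= 1 - beta.
    """
    rows = [
        {"strength": float(s),
         "equal_performance_accuracy": equal_performance_accuracy(s, design, requested_power)}
        for s in s_grid
    ]
    return pd.DataFrame(rows)
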