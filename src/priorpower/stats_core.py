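"""Standard-normal tail numerics shared by the power and prior calculus.

Genome-wide significance thresholds live deep in the normal tail
(p ~ 5e-8, z ~ 5.3-5.5), where a naive ``1 - CDF(z)`` underflows to zero
in double precision.  All tail areas here therefore go through the
survival function, which scipy evaluates via the complementary error
function and keeps ~15 significant digits out to |z| ~ 37.

Two conventions map a per-test p-value threshold ``p`` to an upper-tail
area:

* ``THRESHOLD_AS_TAIL`` — the threshold is itself the upper-tail area
  (quantile 5.327 at p = 5e-8).
* ``TWO_SIDED_HALVED`` — the threshold is a two-sided p-value, so each
  tail carries p/2 (quantile 5.451 at p = 5e-8).

Both appear in published GWAS power arithmetic; the calibration numbers
reproduced by this package use the first, while the printed scale factor
zeta = 5.45 uses the second.  Every routine that needs a quantile takes
the convention explicitly.
"""

from __future__ import annotations

import enum
import math

from scipy import stats

__all__ = [
    "TailConvention",
    "upper_quantile",
    "upper_tail",
    "sd_tail",
    "sd_quantile_squared",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)


class TailConvention(enum.Enum):
    """How a per-test p-value threshold maps to an upper-tail area."""

    THRESHOLD_AS_TAIL = "threshold_as_tail"
    TWO_SIDED_HALVED = "two_sided_halved"

    def tail_area(self, p_threshold: float) -> float:
        """Upper-tail area implied by a per-test threshold ``p_threshold``."""
        if not 0.0 < p_threshold < 1.0:
            raise ValueError(f"threshold must lie in (0, 1), got {p_threshold}")
        if self is TailConvention.TWO_SIDED_HALVED:
            return p_threshold / 2.0
        return p_threshold


def upper_quantile(epsilon: float) -> float:
    """Quantile z with upper-tail area ``epsilon``: P(Z > z) = epsilon.

    Parameters
    ----------
    epsilon : float
        Upper-tail probability, strictly inside (0, 1).

    Returns
    -------
    float
        The standard-normal quantile; e.g. 5.45 at 2.5e-8, -0.84 at 0.8.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"tail area must lie in (0, 1), got {epsilon}")
    return float(stats.norm.isf(epsilon))


def upper_tail(z: float) -> float:
    """Exact survival function P(Z > z) of the standard normal."""
    if not math.isfinite(z):
        raise ValueError(f"quantile must be finite, got {z}")
    return float(stats.norm.sf(z))


def sd_tail(z: float) -> float:
    """Steepest-descents (one-term Mills-ratio) tail approximation.

    Returns (2*pi)^(-1/2) z^(-1) exp(-z^2/2), the leading term of the
    asymptotic expansion of the survival function.  It over-estimates the
    exact tail for every z > 0 (alternating-series bound) with relative
    error ~ z^(-2), i.e. below 7% for z >= 4.
    """
    if z <= 0.0:
        raise ValueError(f"steepest-descents tail requires z > 0, got {z}")
    return math.exp(-0.5 * z * z) / (_SQRT_2PI * z)


def sd_quantile_squared(epsilon: float, z_ref: float) -> float:
    """Approximate squared quantile: -2 ln(sqrt(2*pi) * z_ref * epsilon).

    Inverts :func:`sd_tail` with ln(z) frozen at a reference quantile
    ``z_ref``, the standard trick for extracting how z^2 shifts under an
    S-fold change of the tail area (z^2 drops by exactly 2 ln S).

    Raises
    ------
    ValueError
        If sqrt(2*pi)*z_ref*epsilon >= 1, where the logarithm changes
        sign and the deep-tail approximation no longer applies.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"tail area must lie in (0, 1), got {epsilon}")
    if z_ref <= 0.0:
        raise ValueError(f"reference quantile must be positive, got {z_ref}")
    arg = _SQRT_2PI * z_ref * epsilon
    if arg >= 1.0:
        raise ValueError(
            f"sqrt(2*pi)*z_ref*epsilon = {arg:.3g} >= 1: outside the "
            "deep-tail regime of the approximation"
        )
    return -2.0 * math.log(arg)
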