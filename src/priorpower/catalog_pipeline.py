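"""Doubling-time analysis of GWAS-catalog-style study series.

Per trait, studies are ordered chronologically and reduced to *effective
studies* — those reporting strictly more genome-wide-significant loci
than every earlier study of the trait — to strip out small replication
cohorts.  Cohort size and loci count are then fit to exponential growth
on a log2 scale, log2 y = beta0 + beta1 * t, so the doubling time is
tau = 1/beta1 with standard error sigma_tau = sigma_beta1 / beta1^2
(delta method).  Growth significance comes from nested one-way model
comparisons: intercept-only vs linear (is there growth?) and linear vs
quadratic (is plain exponential growth enough?), via the standard nested
F-test on residual sums of squares.

Matched doubling times for cohorts (tau_N) and loci (tau_L) imply a
scale-free cumulative effect-size distribution
L(R^2) ~ (R^2)^(-tau_N/tau_L); equal doubling times give the Zipf
exponent -1.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .power_model import CaseControlCounts, effective_sample_size

__all__ = [
    "StudyRecord",
    "DoublingFit",
    "TraitComparison",
    "EffectSizeLaw",
    "to_fractional_year",
    "select_effective_studies",
    "fit_growth",
    "compare_doubling",
    "effect_size_law",
    "trait_robust_filter",
]

#: Minimum effective studies for a log-scale growth fit (intercept + slope + 1 df).
MIN_STUDIES = 3


@dataclass(frozen=True)
class StudyRecord:
    """One catalog row: a study of one trait at one publication date.

    Either ``cohort_size`` (quantitative traits) or both ``n_cases`` and
    ``n_controls`` (case-control) must be present; when both are, the
    case-control effective size wins.
    """

    trait: str
    pub_date: float  # fractional years
    n_loci: int
    n_cases: float | None = None
    n_controls: float | None = None
    cohort_size: float | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.pub_date):
            raise ValueError(f"publication date must be finite, got {self.pub_date}")
        if self.n_loci < 0:
            raise ValueError(f"loci count must be >= 0, got {self.n_loci}")
        has_cc = self.n_cases is not None and self.n_controls is not None
        if not has_cc and self.cohort_size is None:
            raise ValueError(
                f"study of {self.trait!r} at {self.pub_date}: need cohort_size "
                "or both n_cases and n_controls"
            )

    @property
    def effective_size(self) -> float:
        """Effective cohort size: 2 x harmonic mean for case-control, else the cohort."""
        if self.n_cases is not None and self.n_controls is not None:
            return effective_sample_size(CaseControlCounts(self.n_cases, self.n_controls))
        return float(self.cohort_size)  # type: ignore[arg-type]


@dataclass(frozen=True)
class DoublingFit:
    """Exponential-growth fit of one response (cohort size or loci count)."""

    beta0: float
    beta1: float
    tau: float  # 1/beta1; inf when beta1 == 0
    sigma_tau: float
    p_growth: float  # nested F: linear vs intercept-only
    p_quadratic: float  # nested F: quadratic vs linear; nan if < 4 points
    response: str
    n_points: int

    @property
    def tau_defined(self) -> bool:
        return math.isfinite(self.tau)


class TraitComparison(NamedTuple):
    """Two-sided test of equal cohort and loci doubling times."""

    tau_n: float
    sigma_n: float
    tau_l: float
    sigma_l: float
    z_tau: float
    p_value: float


class EffectSizeLaw(NamedTuple):
    """Power-law exponents implied by a (tau_N, tau_L) pair."""

    cumulative_exponent: float  # L(R^2) ~ (R^2)^cumulative_exponent
    density_exponent: float  # rho(R^2) ~ (R^2)^density_exponent


def to_fractional_year(date) -> float:
    """Calendar date -> fractional year; Jan 1 maps to the integer year.

    Accepts :class:`datetime.date`, :class:`datetime.datetime`, or an
    ISO-8601 string.  Uses year + (day_of_year - 1) / days_in_year, so
    Dec 31 of a leap year is year + 365/366.
    """
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValueError(f"unparseable date {date!r}: {exc}") from exc
    if isinstance(date, _dt.datetime):
        date = date.date()
    if not isinstance(date, _dt.date):
        raise ValueError(f"cannot interpret {date!r} as a calendar date")
    doy = date.timetuple().tm_yday
    days = 366 if _dt.date(date.year, 12, 31).timetuple().tm_yday == 366 else 365
    return date.year + (doy - 1) / days


def select_effective_studies(records: Iterable[StudyRecord]) -> list[StudyRecord]:
    """Keep studies reporting strictly more loci than every earlier study.

    Records are sorted by publication date internally; the first study of
    a trait is always retained, ties on the running maximum are dropped.
    """
    records = sorted(records, key=lambda r: r.pub_date)
    traits = {r.trait for r in records}
    if len(traits) > 1:
        raise ValueError(f"records mix traits: {sorted(traits)}")
    kept: list[StudyRecord] = []
    best = -1
    for rec in records:
        if rec.n_loci > best:
            kept.append(rec)
            best = rec.n_loci
    return kept


def _nested_f_pvalue(rss_reduced: float, rss_full: float,
                     df_extra: int, df_resid_full: int, scale: float) -> float:
    """p-value of the standard nested F-test, guarding degenerate fits.

    ``scale`` is a magnitude reference (total SS) for deciding when a
    residual is numerically zero.
    """
    if df_resid_full <= 0:
        return float("nan")
    tol = 1e-12 * max(scale, 1.0)
    extra = max(rss_reduced - rss_full, 0.0)
    if rss_full <= tol:
        # saturated full model: any real improvement is infinitely significant
        return 0.0 if extra > tol else 1.0
    f_stat = (extra / df_extra) / (rss_full / df_resid_full)
    return float(stats.f.sf(f_stat, df_extra, df_resid_full))


def fit_growth(records: Sequence[StudyRecord], response: str = "cohort") -> DoublingFit:
    """Fit log2(response) ~ publication year and report the doubling time.

    ``response`` is ``"cohort"`` (effective cohort size) or ``"loci"``
    (genome-wide-significant loci count).  Requires >= 3 studies with
    strictly positive response values.
    """
    if response == "cohort":
        y = np.array([r.effective_size for r in records], dtype=float)
    elif response == "loci":
        y = np.array([r.n_loci for r in records], dtype=float)
    else:
        raise ValueError(f"response must be 'cohort' or 'loci', got {response!r}")
    t = np.array([r.pub_date for r in records], dtype=float)
    n = t.size
    if n < MIN_STUDIES:
        raise ValueError(f"growth fit needs >= {MIN_STUDIES} studies, got {n}")
    if np.any(y <= 0):
        raise ValueError(f"{response} values must be positive for a log-scale fit")

    log2y = np.log2(y)
    tc = t - t.mean()  # center time: conditions the quadratic design matrix
    tss = float(np.sum((log2y - log2y.mean()) ** 2))

    fit1 = sm.OLS(log2y, sm.add_constant(tc)).fit()
    beta1 = float(fit1.params[1])
    sigma_beta1 = float(fit1.bse[1])
    if tss <= 1e-12 * n * max(1.0, float(np.max(log2y**2))):
        beta1 = 0.0  # constant response: the ~1e-16 OLS slope is pure roundoff
    beta0 = float(fit1.params[0] - beta1 * t.mean())  # uncentered intercept
    rss0 = tss
    rss1 = float(fit1.ssr)
    p_growth = _nested_f_pvalue(rss0, rss1, 1, n - 2, tss)

    if n >= 4:
        x2 = np.column_stack([np.ones(n), tc, tc**2])
        rss2 = float(sm.OLS(log2y, x2).fit().ssr)
        p_quad = _nested_f_pvalue(rss1, rss2, 1, n - 3, tss)
    else:
        p_quad = float("nan")

    if beta1 == 0.0:
        tau, sigma_tau = float("inf"), float("inf")
    else:
        tau = 1.0 / beta1
        sigma_tau = sigma_beta1 / beta1**2
    return DoublingFit(beta0=beta0, beta1=beta1, tau=tau, sigma_tau=sigma_tau,
                       p_growth=p_growth, p_quadratic=p_quad,
                       response=response, n_points=n)


def compare_doubling(
    fit_n: DoublingFit,
    fit_l: DoublingFit,
    denominator: str = "as_printed",
) -> TraitComparison:
    """Two-sided z-test of equal cohort and loci doubling times.

    ``as_printed`` scales the difference by sqrt(tau_N^2 + tau_L^2);
    ``standard_errors`` uses the conventional sqrt(sigma_N^2 + sigma_L^2).
    Both are exposed because the former is how the statistic is defined
    in the analysis this reproduces while the latter is the usual Wald
    form; neither is asserted as the correct one.
    """
    if not (fit_n.tau_defined and fit_l.tau_defined):
        raise ValueError("doubling-time comparison needs finite doubling times")
    if denominator == "as_printed":
        denom = math.hypot(fit_n.tau, fit_l.tau)
    elif denominator == "standard_errors":
        denom = math.hypot(fit_n.sigma_tau, fit_l.sigma_tau)
    else:
        raise ValueError(
            f"denominator must be 'as_printed' or 'standard_errors', got {denominator!r}"
        )
    if denom == 0.0:
        raise ValueError("zero denominator in doubling-time comparison")
    z = (fit_n.tau - fit_l.tau) / denom
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TraitComparison(tau_n=fit_n.tau, sigma_n=fit_n.sigma_tau,
                           tau_l=fit_l.tau, sigma_l=fit_l.sigma_tau,
                           z_tau=z, p_value=p)


def effect_size_law(tau_n: float, tau_l: float) -> EffectSizeLaw:
    """Power-law exponents of the effect-size distribution from doubling times.

    Cumulative: L(R^2) ~ (R^2)^(-tau_N/tau_L); density exponent is one
    lower.  Equal doubling times give the Zipf exponent -1.
    """
    if tau_n <= 0 or tau_l <= 0:
        raise ValueError(f"doubling times must be positive, got ({tau_n}, {tau_l})")
    cum = -tau_n / tau_l
    return EffectSizeLaw(cumulative_exponent=cum, density_exponent=cum - 1.0)


def trait_robust_filter(
    fits: Mapping[str, tuple[DoublingFit, DoublingFit]],
    total_associations: Mapping[str, int],
    max_se: float = 0.5,
    min_associations: int = 10,
) -> set[str]:
    """Traits whose doubling times are robust enough to interpret.

    Keeps a trait when both fits have sigma_tau <= ``max_se`` (boundary
    included) and the trait carries at least ``min_associations``
    genome-wide-significant associations in total.
    """
    kept = set()
    for trait, (fit_n, fit_l) in fits.items():
        if fit_n.sigma_tau <= max_se and fit_l.sigma_tau <= max_se \
                and total_associations.get(trait, 0) >= min_associations:
            kept.add(trait)
    return kept
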