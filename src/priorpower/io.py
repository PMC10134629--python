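"""Table readers/writers and the per-trait pipeline runner.

The canonical interchange format is a tab-separated study table in
GWAS-catalog-export style, one row per study::

    trait  date  cases  controls  sample_size  n_loci

``date`` is ISO-8601 and converted to fractional years at parse time;
``cases``/``controls`` or ``sample_size`` supply the cohort (empty
fields are absent); ``n_loci`` counts associations at genome-wide
significance.  Parsing is strict but row-granular: malformed rows are
rejected with diagnostics naming the row number, and only an
all-rows-rejected file is a hard error.
"""

from __future__ import annotations

import dataclasses
import logging
import math
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog_pipeline import (
    MIN_STUDIES,
    StudyRecord,
    compare_doubling,
    fit_growth,
    select_effective_studies,
    to_fractional_year,
)

__all__ = [
    "StudyTableError",
    "NoUsableDataError",
    "PipelineConfig",
    "read_study_table",
    "write_study_table",
    "run_pipeline",
]

logger = logging.getLogger("priorpower")

REQUIRED_COLUMNS = ("trait", "date", "n_loci")
ALL_COLUMNS = ("trait", "date", "cases", "controls", "sample_size", "n_loci")


class StudyTableError(ValueError):
    """The study table is missing, missing columns, or wholly unparseable."""


class NoUsableDataError(ValueError):
    """No trait in the input has enough effective studies to fit."""


@dataclass
class PipelineConfig:
    """Everything the doubling-time pipeline needs to run reproducibly."""

    input_path: str | Path
    output_path: str | Path
    min_studies: int = MIN_STUDIES
    robust_se: float = 0.5
    min_associations: int = 10
    denominator: str = "as_printed"
    delimiter: str = "\t"
    log_path: str | Path | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)


def _opt_float(value: str, row: int, name: str) -> float | None:
    value = value.strip()
    if value == "":
        return None
    try:
        return float(value)
    except ValueError as exc:
        raise ValueError(f"row {row}: column {name!r} not numeric: {value!r}") from exc


def read_study_table(path: str | Path, delimiter: str = "\t") -> list[StudyRecord]:
    """Parse a study table into :class:`StudyRecord` rows.

    Rows with unparseable required fields are skipped with a logged,
    row-numbered diagnostic; a file in which every row fails raises
    :class:`StudyTableError`, as do a missing file or missing columns.
    """
    path = Path(path)
    if not path.exists():
        raise StudyTableError(f"study table not found: {path}")
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(delimiter)
        missing = [c for c in REQUIRED_COLUMNS if c not in header]
        if missing:
            raise StudyTableError(f"{path}: missing required columns {missing}")
        idx = {name: header.index(name) for name in header}
        records: list[StudyRecord] = []
        failures: list[str] = []
        for row_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split(delimiter)
            try:
                if len(fields) < len(header):
                    raise ValueError(f"row {row_no}: {len(fields)} fields, "
                                     f"expected {len(header)}")
                def get(name: str) -> str:
                    return fields[idx[name]] if name in idx else ""
                date = get("date").strip()
                try:
                    pub_date = to_fractional_year(date)
                except ValueError as exc:
                    raise ValueError(f"row {row_no}: bad date {date!r}") from exc
                n_loci_raw = get("n_loci").strip()
                try:
                    n_loci = int(float(n_loci_raw))
                except ValueError as exc:
                    raise ValueError(
                        f"row {row_no}: n_loci not an integer: {n_loci_raw!r}"
                    ) from exc
                records.append(StudyRecord(
                    trait=get("trait").strip(),
                    pub_date=pub_date,
                    n_loci=n_loci,
                    n_cases=_opt_float(get("cases"), row_no, "cases"),
                    n_controls=_opt_float(get("controls"), row_no, "controls"),
                    cohort_size=_opt_float(get("sample_size"), row_no, "sample_size"),
                ))
            except ValueError as exc:
                failures.append(str(exc))
                logger.warning("%s: rejected %s", path, exc)
    if failures and not records:
        raise StudyTableError(
            f"{path}: every data row rejected; first problem: {failures[0]}"
        )
    return records


def write_study_table(records, path: str | Path, delimiter: str = "\t") -> None:
    """Write records in the canonical study-table schema (round-trips the reader)."""
    path = Path(path)
    rows = []
    for r in records:
        rows.append({
            "trait": r.trait,
            "date": _fractional_year_to_iso(r.pub_date),
            "cases": "" if r.n_cases is None else f"{r.n_cases:g}",
            "controls": "" if r.n_controls is None else f"{r.n_controls:g}",
            "sample_size": "" if r.cohort_size is None else f"{r.cohort_size:g}",
            "n_loci": r.n_loci,
        })
    pd.DataFrame(rows, columns=list(ALL_COLUMNS)).to_csv(path, sep=delimiter, index=False)


def _fractional_year_to_iso(year: float) -> str:
    """Inverse of the fractional-year convention, to the nearest day."""
    import datetime as dt

    y = int(math.floor(year))
    days = 366 if dt.date(y, 12, 31).timetuple().tm_yday == 366 else 365
    doy = int(round((year - y) * days)) + 1
    doy = min(max(doy, 1), days)
    return (dt.date(y, 1, 1) + dt.timedelta(days=doy - 1)).isoformat()


def run_pipeline(config: PipelineConfig) -> pd.DataFrame:
    """Run the per-trait doubling-time analysis end to end.

    Effective-study selection, growth fits for cohort size and loci
    count, the doubling-time comparison, and the robustness flag, one
    report row per trait with enough effective studies.  Writes the
    report to ``config.output_path`` (tab-separated) plus an optional
    run log, and returns the report as a DataFrame.  Raises
    :class:`NoUsableDataError` when no trait can be fit.
    """
    records = read_study_table(config.input_path, delimiter=config.delimiter)
    by_trait: dict[str, list[StudyRecord]] = {}
    for rec in records:
        by_trait.setdefault(rec.trait, []).append(rec)

    rows = []
    for trait in sorted(by_trait):
        # a study with no genome-wide-significant finding contributes no
        # association row to a catalog; it cannot enter a log-scale fit
        with_loci = [r for r in by_trait[trait] if r.n_loci > 0]
        effective = select_effective_studies(with_loci)
        if len(effective) < config.min_studies:
            logger.warning("trait %r: %d effective studies < %d, skipped",
                           trait, len(effective), config.min_studies)
            continue
        fit_n = fit_growth(effective, response="cohort")
        fit_l = fit_growth(effective, response="loci")
        comp = compare_doubling(fit_n, fit_l, denominator=config.denominator)
        total_assoc = max(r.n_loci for r in effective)
        robust = (fit_n.sigma_tau <= config.robust_se
                  and fit_l.sigma_tau <= config.robust_se
                  and total_assoc >= config.min_associations)
        rows.append({
            "trait": trait,
            "n_effective_studies": len(effective),
            "tau_N": fit_n.tau, "sigma_N": fit_n.sigma_tau,
            "tau_L": fit_l.tau, "sigma_L": fit_l.sigma_tau,
            "p_growth_N": fit_n.p_growth, "p_growth_L": fit_l.p_growth,
            "p_quadratic_N": fit_n.p_quadratic, "p_quadratic_L": fit_l.p_quadratic,
            "z_tau": comp.z_tau, "p_tau": comp.p_value,
            "total_associations": total_assoc,
            "robust": robust,
        })

    report = pd.DataFrame(rows)
    if report.empty:
        # still write the (empty) report so downstream tooling sees the schema
        report = pd.DataFrame(columns=[
            "trait", "n_effective_studies", "tau_N", "sigma_N", "tau_L", "sigma_L",
            "p_growth_N", "p_growth_L", "p_quadratic_N", "p_quadratic_L",
            "z_tau", "p_tau", "total_associations", "robust"])
    _write_report(report, config.output_path, delimiter=config.delimiter)
    if config.log_path is not None:
        _write_run_log(config, report)
    if report.empty:
        raise NoUsableDataError(
            f"no trait in {config.input_path} has >= {config.min_studies} effective studies"
        )
    return report


def _write_report(report: pd.DataFrame, path: str | Path, delimiter: str = "\t") -> None:
    """Report writer with the package's precision rules (tau, sigma to 1 dp)."""
    out = report.copy()
    for col in ("tau_N", "sigma_N", "tau_L", "sigma_L"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.1f}" if np.isfinite(v) else "inf")
    for col in ("p_growth_N", "p_growth_L", "p_quadratic_N", "p_quadratic_L",
                "z_tau", "p_tau"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: f"{v:.4g}" if np.isfinite(v) else "")
    out.to_csv(path, sep=delimiter, index=False)


def _write_run_log(config: PipelineConfig, report: pd.DataFrame) -> None:
    import scipy
    import statsmodels

    lines = ["priorpower doubling-time pipeline run", ""]
    for f in dataclasses.fields(config):
        lines.append(f"{f.name} = {getattr(config, f.name)!r}")
    lines.append("")
    lines.append(f"python = {platform.python_version()}")
    for mod in (np, scipy, pd, statsmodels):
        lines.append(f"{mod.__name__} = {mod.__version__}")
    lines.append(f"traits_reported = {len(report)}")
    Path(config.log_path).write_text("\n".join(lines) + "\n")
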