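"""End-to-end cohort pipeline: batch trace fitting and the study analysis.

`run_trace_batch` applies center -> sine fit to every trace CSV in a
directory, isolating per-eye failures. `run_cohort_analysis` reproduces
the study's statistics on a per-eye table: column summaries, intra- and
inter-rater absolute-agreement ICCs of the amplitude, Spearman
correlations of the amplitude with ovality ratio, spherical equivalent,
axial length and body height, the vertical-/horizontal-axis subgroup
correlations, and the fraction of fits passing the R^2 > 0.90 gate.

Tables are read from CSV or XLSX; since deposited datasets rarely share
our canonical column names, ingestion goes through a user-editable
column-mapping dict (canonical name -> file column).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .reliability import (
    CorrelationResult,
    ICCResult,
    RatingMatrix,
    icc_absolute_agreement,
    spearman,
    summarize,
)
from .sinefit import FitOptions, fit_sine
from .trace import center_coordinates, load_trace

__all__ = [
    "CANONICAL_COLUMNS",
    "AnalysisReport",
    "load_cohort",
    "run_trace_batch",
    "run_cohort_analysis",
]

logger = logging.getLogger("disctilt")

#: canonical per-eye column names understood by the analysis
CANONICAL_COLUMNS = (
    "eye_id",
    "amplitude_rater1",
    "amplitude_rater2",
    "amplitude_rater1_repeat",
    "amplitude_mean",
    "ovality_ratio",
    "axis_class",
    "spherical_equivalent",
    "axial_length",
    "body_height",
    "r_squared",
)

#: covariates correlated with the amplitude, in reporting order
CORRELATES = ("ovality_ratio", "spherical_equivalent", "axial_length", "body_height")


@dataclass
class AnalysisReport:
    """Full analysis output for one cohort."""

    n_total: int
    n_used: int
    table1: dict
    correlations: dict  # covariate -> CorrelationResult
    subgroup: dict  # 'vertical'/'horizontal' -> CorrelationResult | None
    n_vertical: int
    n_horizontal: int
    icc_intra: ICCResult | None = None
    icc_inter: ICCResult | None = None
    quality_pass_fraction: float | None = None

    def to_dict(self) -> dict:
        def corr(c):
            return None if c is None else {"rho": c.rho, "p_value": c.p_value, "n": c.n}

        def icc(r):
            if r is None:
                return None
            return {
                "icc": r.icc,
                "ci_lower": r.ci_lower,
                "ci_upper": r.ci_upper,
                "p_value": r.p_value,
                "n": r.n,
                "k": r.k,
                "measures": r.measures,
            }

        return {
            "n_total": self.n_total,
            "n_used": self.n_used,
            "table1": self.table1,
            "correlations": {k: corr(v) for k, v in self.correlations.items()},
            "subgroup": {k: corr(v) for k, v in self.subgroup.items()},
            "n_vertical": self.n_vertical,
            "n_horizontal": self.n_horizontal,
            "icc_intra": icc(self.icc_intra),
            "icc_inter": icc(self.icc_inter),
            "quality_pass_fraction": self.quality_pass_fraction,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def to_text(self) -> str:
        lines = [f"Cohort analysis: n={self.n_used} eyes (of {self.n_total} rows)"]
        lines.append("Column summaries (mean +/- SD, range):")
        for col, s in self.table1.items():
            lines.append(
                f"  {col:22s} {s['mean']:8.2f} +/- {s['sd']:6.2f}   "
                f"{s['min']:.2f} ~ {s['max']:.2f}  (n={s['n']})"
            )
        if self.icc_intra is not None:
            r = self.icc_intra
            lines.append(
                f"Intra-rater ICC(A,1): {r.icc:.3f} (95% CI {r.ci_lower:.3f}-{r.ci_upper:.3f}, "
                f"p={r.p_value:.2g})"
            )
        if self.icc_inter is not None:
            r = self.icc_inter
            lines.append(
                f"Inter-rater ICC(A,1): {r.icc:.3f} (95% CI {r.ci_lower:.3f}-{r.ci_upper:.3f}, "
                f"p={r.p_value:.2g})"
            )
        lines.append("Spearman correlations with amplitude:")
        for name, c in self.correlations.items():
            lines.append(f"  vs {name:22s} R={c.rho:+.2f}  p={c.p_value:.3g}  (n={c.n})")
        lines.append(
            f"Axis subgroups: {self.n_vertical} vertical, {self.n_horizontal} horizontal"
        )
        for name, c in self.subgroup.items():
            if c is None:
                lines.append(f"  {name}: too few eyes for a correlation")
            else:
                lines.append(
                    f"  {name} amplitude~ovality: R={c.rho:+.2f}  p={c.p_value:.3g}  (n={c.n})"
                )
        if self.quality_pass_fraction is not None:
            lines.append(
                f"Fit quality: {100 * self.quality_pass_fraction:.1f}% of fits with R^2 > 0.90"
            )
        return "\n".join(lines)


def load_cohort(
    path: str | Path,
    column_map: dict | None = None,
    sheet: int | str = 0,
) -> pd.DataFrame:
    """Read a per-eye cohort table from CSV or XLSX.

    ``column_map`` maps canonical column names (see ``CANONICAL_COLUMNS``)
    to the column names used in the file; unmapped canonical names are
    looked up verbatim. Unknown file columns are preserved untouched.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    if column_map:
        rename = {v: k for k, v in column_map.items() if v in df.columns}
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise ValueError(f"{path}: mapped columns not found: {missing}")
        df = df.rename(columns=rename)
    return df


def run_trace_batch(
    directory: str | Path, options: FitOptions | None = None
) -> pd.DataFrame:
    """Center and sine-fit every ``*.csv`` trace in a directory.

    Per-eye failures (malformed files, too few points) are logged and
    skipped; the batch continues. Returns one row per successful fit with
    columns eye_id, a, b, c, r_squared, rss, n_points, converged,
    quality_pass, plus a ``failures`` attribute listing skipped files.
    """
    directory = Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise ValueError(f"no trace CSVs found in {directory}")
    rows = []
    failures: list[tuple[str, str]] = []
    for p in paths:
        try:
            fit = fit_sine(center_coordinates(load_trace(p)), options)
        except Exception as exc:  # noqa: BLE001 - error isolation per eye
            logger.warning("skipping %s: %s", p.name, exc)
            failures.append((p.name, str(exc)))
            continue
        rows.append(
            {
                "eye_id": fit.eye_id,
                "a": fit.a,
                "b": fit.b,
                "c": fit.c,
                "r_squared": fit.r_squared,
                "rss": fit.rss,
                "n_points": fit.n_points,
                "converged": fit.converged,
                "quality_pass": fit.quality_pass,
            }
        )
    result = pd.DataFrame(rows)
    result.attrs["failures"] = failures
    return result


def _derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    have_raters = {"amplitude_rater1", "amplitude_rater2"} <= set(df.columns)
    if have_raters:
        mean_of_raters = (df["amplitude_rater1"] + df["amplitude_rater2"]) / 2.0
        if "amplitude_mean" not in df.columns:
            df["amplitude_mean"] = mean_of_raters
    if "amplitude_mean" not in df.columns:
        raise ValueError(
            "cohort table needs 'amplitude_mean' or both rater amplitude columns"
        )
    if "axis_class" not in df.columns and "ovality_ratio" in df.columns:
        # modified-ratio construction: vertical discs sit at ratio <= 1
        df["axis_class"] = np.where(df["ovality_ratio"] > 1.0, "horizontal", "vertical")
    return df


def run_cohort_analysis(table: pd.DataFrame) -> AnalysisReport:
    """Run the full study analysis on a per-eye cohort table.

    Missing cells are handled by listwise deletion per statistic, with
    dropped counts logged. Fails if fewer than 3 usable rows remain.
    """
    n_total = len(table)
    df = _derive_columns(table)
    usable = df["amplitude_mean"].notna()
    n_used = int(usable.sum())
    if n_used < n_total:
        logger.info("dropped %d rows with missing amplitude", n_total - n_used)
    if n_used < 3:
        raise ValueError(f"need at least 3 usable rows, got {n_used}")
    df = df[usable]

    summary_cols = [
        c
        for c in (
            "amplitude_mean",
            "ovality_ratio",
            "spherical_equivalent",
            "axial_length",
            "body_height",
        )
        if c in df.columns
    ]
    table1 = {c: summarize(df[c].dropna()) for c in summary_cols}

    correlations = {}
    for cov in CORRELATES:
        if cov not in df.columns:
            continue
        sub = df[["amplitude_mean", cov]].dropna()
        if len(sub) < 3:
            continue
        correlations[cov] = spearman(sub["amplitude_mean"], sub[cov])

    subgroup: dict[str, CorrelationResult | None] = {}
    n_vertical = n_horizontal = 0
    if {"axis_class", "ovality_ratio"} <= set(df.columns):
        for cls in ("vertical", "horizontal"):
            grp = df[df["axis_class"] == cls][["amplitude_mean", "ovality_ratio"]].dropna()
            if cls == "vertical":
                n_vertical = len(grp)
            else:
                n_horizontal = len(grp)
            try:
                subgroup[cls] = spearman(grp["amplitude_mean"], grp["ovality_ratio"]) if len(grp) >= 3 else None
            except ValueError:
                subgroup[cls] = None

    icc_intra = icc_inter = None
    if {"amplitude_rater1", "amplitude_rater1_repeat"} <= set(df.columns):
        sub = df[["amplitude_rater1", "amplitude_rater1_repeat"]].dropna()
        if len(sub) >= 2:
            icc_intra = icc_absolute_agreement(RatingMatrix(sub.to_numpy()))
    if {"amplitude_rater1", "amplitude_rater2"} <= set(df.columns):
        sub = df[["amplitude_rater1", "amplitude_rater2"]].dropna()
        if len(sub) >= 2:
            icc_inter = icc_absolute_agreement(RatingMatrix(sub.to_numpy()))

    quality = None
    if "r_squared" in df.columns:
        rs = df["r_squared"].dropna()
        if len(rs):
            quality = float((rs > 0.90).mean())

    return AnalysisReport(
        n_total=n_total,
        n_used=n_used,
        table1=table1,
        correlations=correlations,
        subgroup=subgroup,
        n_vertical=n_vertical,
        n_horizontal=n_horizontal,
        icc_intra=icc_intra,
        icc_inter=icc_inter,
        quality_pass_fraction=quality,
    )
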