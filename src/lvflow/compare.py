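"""Two-condition comparison: paired t-tests and intraclass correlation.

Mirrors the agreement analysis used when the same subjects are scanned twice
(e.g. with and without respiratory motion compensation): per metric, a paired
t-test on the within-subject differences and a two-way mixed-effects,
absolute-agreement, single-measurement intraclass correlation (ICC(2,1) in
the Shrout-Fleiss taxonomy), both at alpha 0.05 with no multiple-testing
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedSeries",
    "TTestResult",
    "ICCResult",
    "ComparisonReport",
    "paired_t_test",
    "icc",
    "compare_conditions",
    "DEFAULT_METRICS",
]

ALPHA = 0.05

DEFAULT_METRICS = [
    "frac_DF", "frac_DEF", "frac_RI", "frac_RV",
    "ef", "sv", "mitral_inflow", "valvular_mismatch",
    "abs_def_ri_mismatch", "excluded_fraction",
    "indexed_ke_peak_systole", "indexed_ke_e_peak", "indexed_ke_a_peak",
    "indexed_vorticity_peak_systole", "indexed_vorticity_e_peak", "indexed_vorticity_a_peak",
]


@dataclass
class PairedSeries:
    """One metric measured under two conditions on the same subjects."""

    subjects: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray
    metric: str = ""

    def __post_init__(self) -> None:
        self.subjects = np.asarray(self.subjects)
        self.values_a = np.asarray(self.values_a, dtype=np.float64)
        self.values_b = np.asarray(self.values_b, dtype=np.float64)
        n = self.subjects.shape[0]
        if not (self.values_a.shape == (n,) and self.values_b.shape == (n,)):
            raise ValueError("subject ids and both value columns must have equal length")
        if n < 2:
            raise ValueError("need at least 2 paired observations")
        if not (np.all(np.isfinite(self.values_a)) and np.all(np.isfinite(self.values_b))):
            raise ValueError("paired values must be finite")

    @property
    def n(self) -> int:
        return self.subjects.shape[0]


@dataclass
class TTestResult:
    t: float
    df: int
    p: float
    mean_difference: float  # mean(a - b)


def paired_t_test(series: PairedSeries) -> TTestResult:
    """Classical paired t-test on the within-subject differences (two-sided)."""
    d = series.values_a - series.values_b
    if np.std(d) == 0.0:
        raise ValueError("zero-variance differences: paired t-test undefined")
    res = sps.ttest_rel(series.values_a, series.values_b)
    return TTestResult(
        t=float(res.statistic), df=int(series.n - 1), p=float(res.pvalue),
        mean_difference=float(np.mean(d)),
    )


@dataclass
class ICCResult:
    icc: float
    p: float
    f: float


def icc(series: PairedSeries) -> ICCResult:
    """ICC(2,1): two-way mixed effects, absolute agreement, single measurement.

    Computed from the standard ANOVA mean squares of the subjects x
    conditions table; the p-value is from the F test of between-subject
    variance against residual variance.
    """
    if series.n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    x = np.column_stack([series.values_a, series.values_b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0.0 and mse == 0.0:
        raise ValueError("degenerate table: no between-subject variance")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_val = (msr - mse) / denom
    if mse == 0.0:
        return ICCResult(icc=float(icc_val), p=0.0, f=float("inf"))
    f = msr / mse
    p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    return ICCResult(icc=float(icc_val), p=p, f=float(f))


@dataclass
class ComparisonReport:
    """Per-metric paired comparison between two conditions."""

    table: pd.DataFrame
    n_subjects: int
    excluded_subjects: list
    alpha: float = ALPHA
    icc_variant: str = "ICC(2,1) two-way mixed, absolute agreement, single measures"

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_text(self) -> str:
        lines = [
            f"Paired comparison (n = {self.n_subjects}, alpha = {self.alpha})",
            f"ICC variant: {self.icc_variant}",
        ]
        if self.excluded_subjects:
            lines.append(f"Excluded subjects (quality filter): {self.excluded_subjects}")
        lines.append(self.table.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
        return "\n".join(lines)


def compare_conditions(
    results_a: pd.DataFrame,
    results_b: pd.DataFrame,
    metrics: list[str] | None = None,
    mismatch_exclusion_gate: float | None = None,
) -> ComparisonReport:
    """Compare two matched result tables metric by metric.

    Each table needs a ``subject`` column plus metric columns (the flat rows
    written by the pipeline).  With ``mismatch_exclusion_gate`` set (e.g.
    0.10), subjects whose ``abs_def_ri_mismatch`` exceeds the gate in *both*
    conditions are dropped before testing — the data-quality exclusion used
    for inaccurate particle-tracing analyses.
    """
    for name, df in (("a", results_a), ("b", results_b)):
        if "subject" not in df.columns:
            raise ValueError(f"results_{name} lacks a 'subject' column")
    a = results_a.set_index("subject").sort_index()
    b = results_b.set_index("subject").sort_index()
    if not a.index.equals(b.index):
        raise ValueError(
            f"subject ids do not match: {list(a.index)} vs {list(b.index)}"
        )
    excluded: list = []
    if mismatch_exclusion_gate is not None:
        bad = (a["abs_def_ri_mismatch"] > mismatch_exclusion_gate) & (
            b["abs_def_ri_mismatch"] > mismatch_exclusion_gate
        )
        excluded = list(a.index[bad])
        a, b = a[~bad], b[~bad]
    if metrics is None:
        metrics = [m for m in DEFAULT_METRICS if m in a.columns and m in b.columns]
    rows = []
    for metric in metrics:
        series = PairedSeries(
            subjects=a.index.to_numpy(), values_a=a[metric].to_numpy(),
            values_b=b[metric].to_numpy(), metric=metric,
        )
        try:
            tt = paired_t_test(series)
            t_val, df_val, p_val, md = tt.t, tt.df, tt.p, tt.mean_difference
        except ValueError:
            t_val = p_val = float("nan")
            df_val = series.n - 1
            md = float(np.mean(series.values_a - series.values_b))
        try:
            ic = icc(series)
            icc_val, icc_p = ic.icc, ic.p
        except ValueError:
            icc_val = icc_p = float("nan")
        rows.append({
            "metric": metric,
            "mean_difference": md,
            "t": t_val,
            "df": df_val,
            "p": p_val,
            "significant": bool(p_val < ALPHA) if np.isfinite(p_val) else False,
            "icc": icc_val,
            "icc_p": icc_p,
        })
    return ComparisonReport(
        table=pd.DataFrame(rows), n_subjects=int(a.shape[0]), excluded_subjects=excluded,
    )
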