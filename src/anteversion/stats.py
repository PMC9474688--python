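"""Cohort statistics: per-method summaries, mean differences, t, r and ICC.

The comparison layer summarizes each anteversion method/height cell against
the postoperative stem anteversion (PSA): mean ± SD of the angles, the mean
difference MD = mean(method − PSA) with its SD, a paired two-tailed t-test
on the per-hip differences, and the Pearson correlation with its p-value.
Rater reliability is the two-way ANOVA intraclass correlation, ICC(2,1)
(two-way random effects, absolute agreement, single rater) by default with
ICC(3,1) (consistency) available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import StatsError

__all__ = [
    "CohortRecord",
    "MethodSummary",
    "ReliabilityResult",
    "paired_difference_summary",
    "pearson_with_p",
    "icc_absolute_agreement",
    "summarize_cohort",
    "render_table",
    "COHORT_COLUMNS",
    "METHOD_CELLS",
]

COHORT_COLUMNS = [
    "hip_id",
    "side",
    "crowe_type",
    "psa_deg",
    "am_ct_5",
    "am_ct_10",
    "am_3d_5",
    "am_3d_10",
    "at_3d_5",
    "at_3d_10",
    "truth_nfa_deg",
]

#: (method label, height, cohort column) in report order
METHOD_CELLS = [
    ("AM-CT", 5, "am_ct_5"),
    ("AM-CT", 10, "am_ct_10"),
    ("AM-3D", 5, "am_3d_5"),
    ("AM-3D", 10, "am_3d_10"),
    ("AT-3D", 5, "at_3d_5"),
    ("AT-3D", 10, "at_3d_10"),
]

#: p-values below this render as "0.000"; exact values are kept in the CSV
P_FLOOR = 1e-15


@dataclass(frozen=True)
class CohortRecord:
    """One hip's measured angles (degrees); any method cell may be missing."""

    hip_id: str
    side: str = "right"
    crowe_type: Optional[str] = None
    psa_deg: float = np.nan
    am_ct_5: float = np.nan
    am_ct_10: float = np.nan
    am_3d_5: float = np.nan
    am_3d_10: float = np.nan
    at_3d_5: float = np.nan
    at_3d_10: float = np.nan
    truth_nfa_deg: float = np.nan


@dataclass(frozen=True)
class MethodSummary:
    """Table row: one (method, height) cell compared against PSA."""

    method: str
    height_mm: Optional[float]
    angle_mean: float
    angle_sd: float
    diff_mean: Optional[float]
    diff_sd: Optional[float]
    t_p: Optional[float]
    pearson_r: Optional[float]
    r_p: Optional[float]
    n: int

    def __post_init__(self):
        if self.pearson_r is not None and not -1 <= self.pearson_r <= 1:
            raise StatsError("pearson r outside [-1, 1]")
        for p in (self.t_p, self.r_p):
            if p is not None and not 0 <= p <= 1:
                raise StatsError("p-value outside [0, 1]")


@dataclass(frozen=True)
class ReliabilityResult:
    icc_value: float
    model_label: str
    n_subjects: int
    n_raters: int

    def __post_init__(self):
        if self.icc_value > 1:
            raise StatsError("ICC > 1")


def paired_difference_summary(method_vals, psa_vals):
    """Mean difference, its SD, and the paired two-tailed t-test.

    Differences are d_i = method_i − PSA_i; MD = mean(d), SD with n−1
    denominator, t = MD / (SD/√n) with n−1 degrees of freedom.  A cohort
    with identical pairs (all d = 0) returns t_p = 1; a constant nonzero
    shift has zero variance and is reported with p = 0 and a warning.
    """
    m = np.asarray(method_vals, dtype=float)
    p = np.asarray(psa_vals, dtype=float)
    if m.shape != p.shape or m.ndim != 1:
        raise StatsError("method and PSA lists must be equal-length 1D")
    if len(m) < 3:
        raise StatsError("need at least 3 pairs")
    if not (np.all(np.isfinite(m)) and np.all(np.isfinite(p))):
        raise StatsError("pairs must be complete (no missing values)")
    d = m - p
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    n = len(d)
    if sd == 0.0:
        if md == 0.0:
            return md, sd, 0.0, 1.0
        warnings.warn("zero-variance differences: t-test p below machine floor", stacklevel=2)
        return md, sd, float(np.sign(md) * np.inf), 0.0
    t = md / (sd / np.sqrt(n))
    t_p = float(2.0 * sps.t.sf(abs(t), n - 1))
    return md, sd, float(t), t_p


def pearson_with_p(x, y):
    """Sample Pearson r and its two-tailed p (t distribution, n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise StatsError("need two equal-length 1D arrays with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("undefined correlation: constant input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def icc_absolute_agreement(ratings, model: str = "ICC2") -> ReliabilityResult:
    """Single-rater intraclass correlation from the two-way ANOVA decomposition.

    ``model='ICC2'`` (default) is the two-way random-effects absolute-
    agreement form ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1)MS_E +
    (k/n)(MS_C − MS_E)); ``model='ICC3'`` is the consistency form
    ICC(3,1) = (MS_R − MS_E) / (MS_R + (k−1)MS_E).
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise StatsError("ratings must be a subjects x raters matrix")
    n, k = x.shape
    if n < 5 or k < 2:
        raise StatsError("need >= 5 subjects and >= 2 raters")
    if not np.all(np.isfinite(x)):
        raise StatsError("ratings matrix is incomplete")
    grand = x.mean()
    if np.allclose(x, grand):
        raise StatsError("degenerate ratings: zero total variance")
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    if model == "ICC2":
        icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e))
        label = "ICC(2,1) two-way random, absolute agreement"
    elif model == "ICC3":
        icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
        label = "ICC(3,1) two-way mixed, consistency"
    else:
        raise StatsError(f"unknown ICC model {model!r}")
    return ReliabilityResult(icc_value=float(icc), model_label=label, n_subjects=n, n_raters=k)


def _records_to_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = [r.__dict__ if isinstance(r, CohortRecord) else dict(r) for r in records]
        df = pd.DataFrame(rows)
    if df.empty:
        raise StatsError("empty cohort")
    for col in COHORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if df["hip_id"].duplicated().any():
        raise StatsError("hip_id values are not unique")
    return df


def summarize_cohort(records, min_n: int = 3):
    """Per-(method, height) summaries against PSA, plus the PSA row.

    Uses pairwise-complete deletion per cell.  Cells with no data are
    omitted; cells with 1 <= n < ``min_n`` raise (too small for r/p).
    Returns ``(summaries, table)`` where ``table`` is a tidy DataFrame with
    full-precision numbers (render with :func:`render_table`).
    """
    df = _records_to_frame(records)
    summaries: list[MethodSummary] = []
    for method, height, col in METHOD_CELLS:
        pair = df[[col, "psa_deg"]].dropna()
        if pair.empty:
            continue
        if len(pair) < min_n:
            raise StatsError(f"{method} @ {height} mm: only {len(pair)} complete records")
        vals = pair[col].to_numpy()
        psa = pair["psa_deg"].to_numpy()
        md, sd_d, _t, t_p = paired_difference_summary(vals, psa)
        try:
            r, r_p = pearson_with_p(vals, psa)
        except StatsError:
            r, r_p = None, None
        summaries.append(
            MethodSummary(
                method=method,
                height_mm=height,
                angle_mean=float(vals.mean()),
                angle_sd=float(vals.std(ddof=1)),
                diff_mean=md,
                diff_sd=sd_d,
                t_p=t_p,
                pearson_r=r,
                r_p=r_p,
                n=len(pair),
            )
        )
    psa_all = df["psa_deg"].dropna().to_numpy()
    if len(psa_all) == 0:
        raise StatsError("cohort has no PSA values")
    summaries.append(
        MethodSummary(
            method="PSA",
            height_mm=None,
            angle_mean=float(psa_all.mean()),
            angle_sd=float(psa_all.std(ddof=1)) if len(psa_all) > 1 else np.nan,
            diff_mean=None,
            diff_sd=None,
            t_p=None,
            pearson_r=None,
            r_p=None,
            n=len(psa_all),
        )
    )
    table = pd.DataFrame(
        [
            {
                "method": s.method,
                "height_mm": s.height_mm,
                "angle_mean": s.angle_mean,
                "angle_sd": s.angle_sd,
                "diff_mean": s.diff_mean,
                "diff_sd": s.diff_sd,
                "t_p": s.t_p,
                "pearson_r": s.pearson_r,
                "r_p": s.r_p,
                "n": s.n,
            }
            for s in summaries
        ]
    )
    return summaries, table


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and np.isnan(p)):
        return "N/A"
    return "0.000" if p < P_FLOOR else f"{p:.3f}"


def render_table(summaries) -> str:
    """Plain-text rendering in the standard column order, one decimal."""
    header = ["Parameters", "Height (mm)", "Angle (deg)", "Difference (deg)", "t-test p", "r", "Pearson p"]
    rows = [header]
    for s in summaries:
        rows.append(
            [
                s.method,
                "N/A" if s.height_mm is None else f"{s.height_mm:g}",
                f"{s.angle_mean:.1f} +/- {s.angle_sd:.1f}",
                "N/A" if s.diff_mean is None else f"{s.diff_mean:.1f} +/- {s.diff_sd:.1f}",
                _fmt_p(s.t_p),
                "N/A" if s.pearson_r is None else f"{s.pearson_r:.2f}",
                _fmt_p(s.r_p),
            ]
        )
    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = ["  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip() for row in rows]
    lines.insert(1, "-" * len(lines[0]))
    return "\n".join(lines)
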