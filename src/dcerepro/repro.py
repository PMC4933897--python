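"""Reproducibility statistics: paired t, one-way ANOVA, ICC, CoV.

Measurements arrive as a long-format table with columns
``subject, rater, scan, replicate, metric, value``.  Three designs are
analysed:

- ``intra``  — repeat readings by one observer (2 replicates, rater 1, scan 1);
- ``inter``  — one reading each by several observers (3 raters, scan 1);
- ``rescan`` — repeat acquisitions read by one observer (2 scans, rater 1).

Agreement is quantified by the two-way random-effects, absolute-agreement,
single-measure intraclass correlation ICC(A,1), with the F-distribution
95% CI, banded as good (> 0.75), moderate (0.5-0.75) or poor (< 0.5).
Variability uses the coefficient of variation: per subject, the standard
deviation of that subject's repeat values over their (absolute) mean, as a
percentage, averaged over subjects.  Differences are tested with paired t
tests (intra, rescan) and one-way ANOVA across observers (inter); no
multiple-testing correction is applied, alpha = 0.05 throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ReproResult", "paired_t", "one_way_anova", "icc", "cov",
           "icc_from_matrix", "categorize_icc", "design_matrix"]

DESIGNS = ("intra", "inter", "rescan")


@dataclass
class ReproResult:
    """One reproducibility statistic with its uncertainty and band."""

    statistic: str
    estimate: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p_value: float = float("nan")
    category: str = "n/a"
    extra: dict = field(default_factory=dict)


def categorize_icc(value: float) -> str:
    """Agreement band: good > 0.75, moderate 0.5-0.75, poor < 0.5."""
    if not np.isfinite(value):
        return "n/a"
    if value > 0.75:
        return "good"
    if value >= 0.5:
        return "moderate"
    return "poor"


def paired_t(values_a, values_b) -> ReproResult:
    """Two-sided paired t test between matched per-subject values.

    Identical vectors have zero difference variance, so the statistic is
    undefined; the result is flagged rather than reported as t = 0.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("need two equal-length vectors with >= 2 subjects")
    d = a - b
    if np.std(d, ddof=1) == 0:
        return ReproResult("paired_t", float("nan"),
                           extra={"undefined": True, "reason": "zero difference variance"})
    t, p = stats.ttest_rel(a, b)
    return ReproResult("paired_t", float(t), p_value=float(p),
                       extra={"df": a.size - 1})


def one_way_anova(groups) -> ReproResult:
    """One-way fixed-effects ANOVA across observer groups."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups of >= 2 values")
    if all(np.std(g, ddof=1) == 0 for g in groups):
        return ReproResult("anova_F", float("nan"),
                           extra={"undefined": True, "reason": "zero within-group variance"})
    f, p = stats.f_oneway(*groups)
    return ReproResult("anova_F", float(f), p_value=float(p),
                       extra={"df_between": len(groups) - 1,
                              "df_within": sum(g.size for g in groups) - len(groups)})


def design_matrix(table: pd.DataFrame, design: str, metric: str = None) -> np.ndarray:
    """Pivot the long table into a subjects x measurements matrix.

    intra: replicates 1..R by rater 1, scan 1; inter: raters 1..K at
    replicate 1, scan 1; rescan: scans 1..S by rater 1, replicate 1.
    Raises if any subject x measurement cell is missing or duplicated.
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}")
    df = table
    if metric is not None:
        df = df[df["metric"] == metric]
    if design == "intra":
        df = df[(df["rater"] == df["rater"].min()) & (df["scan"] == df["scan"].min())]
        col = "replicate"
    elif design == "inter":
        df = df[(df["replicate"] == df["replicate"].min()) & (df["scan"] == df["scan"].min())]
        col = "rater"
    else:
        df = df[(df["rater"] == df["rater"].min()) & (df["replicate"] == df["replicate"].min())]
        col = "scan"
    try:
        wide = df.pivot(index="subject", columns=col, values="value")
    except ValueError as e:
        raise ValueError(f"duplicate (subject, {col}) cells in table: {e}") from e
    if wide.isna().any().any():
        missing = [(s, c) for s, c in zip(*np.where(wide.isna().values))]
        raise ValueError(f"incomplete two-way layout; missing cells {missing}")
    if wide.shape[1] < 2:
        raise ValueError(f"design {design!r} needs >= 2 measurements per subject")
    return wide.to_numpy(float)


def icc_from_matrix(data, alpha: float = 0.05) -> ReproResult:
    """ICC(A,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares of an n-subjects x k-measurements
    matrix (MSR rows, MSC columns, MSE error):

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The 95% CI uses the F-distribution method with Satterthwaite degrees of
    freedom; the p-value tests ICC = 0 via F = MSR/MSE.
    """
    x = np.asarray(data, float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need an n x k matrix with n, k >= 2")
    n, k = x.shape
    grand = x.mean()
    row_m = x.mean(axis=1)
    col_m = x.mean(axis=0)

    msr = k * np.sum((row_m - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_m - grand) ** 2) / (k - 1)
    sse = np.sum((x - row_m[:, None] - col_m[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        # zero variance everywhere: agreement is vacuous
        return ReproResult("icc_a1", float("nan"),
                           extra={"undefined": True, "reason": "zero total variance"})
    est = (msr - mse) / denom

    if mse > 0:
        f0 = msr / mse
        p = float(stats.f.sf(f0, n - 1, (n - 1) * (k - 1)))
    else:
        p = 0.0 if est > 0 else float("nan")

    ci_low, ci_high = _icc_a1_ci(est, msr, msc, mse, n, k, alpha)
    est = float(est)
    return ReproResult("icc_a1", est, ci_low=ci_low, ci_high=ci_high,
                       p_value=p, category=categorize_icc(est),
                       extra={"n_subjects": n, "k": k,
                              "msr": msr, "msc": msc, "mse": mse})


def _icc_a1_ci(r, msr, msc, mse, n, k, alpha):
    """McGraw & Wong F-based confidence interval for ICC(A,1)."""
    if mse == 0 and msc == 0:
        return (float("nan"), float("nan")) if not np.isfinite(r) else (1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = k * r / (n * (1.0 - r)) if r < 1 else np.inf
        b = 1.0 + k * r * (n - 1.0) / (n * (1.0 - r)) if r < 1 else np.inf
        if not np.isfinite(a) or not np.isfinite(b):
            return 1.0, 1.0
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        v = num / den if den > 0 else np.nan
    if not np.isfinite(v) or v <= 0:
        return float("nan"), float("nan")
    f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
    hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    return float(lo), float(hi)


def icc(table: pd.DataFrame, design: str, metric: str = None,
        alpha: float = 0.05) -> ReproResult:
    """ICC(A,1) of a long-format measurement table under one design."""
    return icc_from_matrix(design_matrix(table, design, metric), alpha)


def cov(table: pd.DataFrame, design: str, metric: str = None,
        aggregation: str = "per_subject") -> ReproResult:
    """Coefficient of variation (%) of repeat measurements.

    Per subject: sd(repeats, ddof=1) / |mean(repeats)| * 100, then averaged
    over subjects.  The absolute mean keeps the CoV positive for metrics
    whose mean is negative (excess kurtosis routinely is); this is recorded
    in ``extra``.  Subjects with zero mean are excluded and counted.
    ``aggregation="pooled"`` instead reports pooled sd / |pooled mean|.
    """
    x = design_matrix(table, design, metric)
    sds = np.std(x, axis=1, ddof=1)
    means = x.mean(axis=1)
    if aggregation == "pooled":
        pm = abs(x.mean())
        if pm == 0:
            return ReproResult("cov_pct", float("nan"),
                               extra={"undefined": True, "reason": "zero pooled mean"})
        est = float(np.std(x, ddof=1) / pm * 100.0)
        return ReproResult("cov_pct", est, extra={"aggregation": "pooled",
                                                  "abs_mean_denominator": True})
    ok = means != 0
    n_flagged = int((~ok).sum())
    if not ok.any():
        return ReproResult("cov_pct", float("nan"),
                           extra={"undefined": True, "reason": "all subject means zero"})
    per_subject = sds[ok] / np.abs(means[ok]) * 100.0
    return ReproResult("cov_pct", float(per_subject.mean()),
                       extra={"aggregation": "per_subject",
                              "abs_mean_denominator": True,
                              "n_subjects_flagged_zero_mean": n_flagged})
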