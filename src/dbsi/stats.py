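"""Small-cohort statistical layer.

Group comparisons across imaging metrics (Welch's unequal-variances t
with Bonferroni correction), paired pre/post comparisons (Wilcoxon
signed rank, exact for small n), categorical comparisons (Fisher's
exact test), and the diagnosis-timing analysis (weeks gained by the
hindered-map-assisted read over standard of care).

Quantile convention: linear interpolation of order statistics at
position 1 + (n-1)p (numpy's default), which reproduces the published
interquartile ranges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "welch_t",
    "wilcoxon_signed_rank",
    "fisher_exact",
    "bonferroni_alpha",
    "compare_groups",
    "time_to_diagnosis",
    "GroupComparisonResult",
    "TimeToDiagnosisSummary",
]

ANALYZED_DIAGNOSES = ("treatment_effect", "progression")


def welch_t(group_a, group_b):
    """Two-tailed Welch's unequal variances t-test.

    Returns ``(t, df, p)`` with Welch-Satterthwaite degrees of freedom.
    Two identical constant groups give t=0, p=1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def wilcoxon_signed_rank(before, after, exact: bool | None = None):
    """Two-tailed Wilcoxon signed rank test for matched samples.

    Zero differences are dropped (Wilcoxon's original rule) and their
    count reported. Exact enumeration of the 2^n sign assignments for
    n <= 12, normal approximation above; ``exact`` overrides.
    Returns ``(W, p, n_zeros)``; all-zero differences give the
    degenerate p = 1.
    """
    x = np.asarray(before, dtype=float)
    y = np.asarray(after, dtype=float)
    if x.shape != y.shape or len(x) < 2:
        raise ValueError("need equal-length samples with n >= 2")
    d = x - y
    n_zeros = int((d == 0).sum())
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0, n_zeros
    if exact is None:
        exact = len(d) <= 12
    method = "exact" if exact else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", method=method,
                       correction=not exact)
    return float(res.statistic), float(res.pvalue), n_zeros


def fisher_exact(table):
    """Two-sided Fisher's exact test on a 2x2 table.

    Two-sided p is the sum of hypergeometric probabilities no larger
    than the observed table's (the minimum-likelihood rule).
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0):
        raise ValueError("cell counts must be non-negative")
    if t.sum() == 0:
        raise ValueError("at least one margin must be positive")
    _, p = sps.fisher_exact(t, alternative="two-sided")
    return float(p)


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Family-wise threshold alpha/m for m comparisons."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


@dataclass
class GroupComparisonResult:
    """Per-metric Welch comparison between two diagnosis groups."""

    table: pd.DataFrame  # index metric; group means/sds, t, df, p, significant
    alpha: float
    adjusted_alpha: float
    n_metrics: int


def compare_groups(metric_table: pd.DataFrame, labels=None, metrics=None,
                   alpha: float = 0.05) -> GroupComparisonResult:
    """Welch-compare every metric between treatment effect and progression.

    ``metric_table`` holds one row per patient; ``labels`` defaults to
    its Diagnosis column. Significance flags use the Bonferroni
    threshold alpha / (number of metrics), computed on unrounded
    p-values.
    """
    if labels is None:
        labels = metric_table["Diagnosis"]
    labels = np.asarray(labels)
    if metrics is None:
        metrics = [
            c for c in metric_table.columns
            if c not in ("Subject", "Diagnosis")
            and np.issubdtype(metric_table[c].dtype, np.number)
        ]
    in_a = labels == "treatment_effect"
    in_b = labels == "progression"
    if in_a.sum() < 2 or in_b.sum() < 2:
        raise ValueError("each group needs at least 2 patients")
    adj = bonferroni_alpha(alpha, len(metrics))
    rows = {}
    for m in metrics:
        a = metric_table.loc[in_a, m].to_numpy(dtype=float)
        b = metric_table.loc[in_b, m].to_numpy(dtype=float)
        t, df, p = welch_t(a, b)
        rows[m] = dict(
            mean_treatment_effect=a.mean(), sd_treatment_effect=a.std(ddof=1),
            mean_progression=b.mean(), sd_progression=b.std(ddof=1),
            t=t, df=df, p=p, significant=bool(p < adj),
        )
    table = pd.DataFrame(rows).T
    table["significant"] = table["significant"].astype(bool)
    return GroupComparisonResult(table=table, alpha=alpha, adjusted_alpha=adj,
                                 n_metrics=len(metrics))


def _quartiles(x):
    """Linear-interpolation quartiles at positions 1 + (n-1)p."""
    return (
        float(np.percentile(x, 25)),
        float(np.percentile(x, 50)),
        float(np.percentile(x, 75)),
    )


@dataclass
class TimeToDiagnosisSummary:
    """Weeks gained by the assisted diagnosis (SOC minus DBSI) overall
    and per diagnosis group."""

    n_analyzed: int
    n_earlier: int
    fraction_earlier: float
    median: float
    iqr: tuple
    by_group: dict  # diagnosis -> dict(n, n_earlier, median, iqr)
    differences: pd.DataFrame


def time_to_diagnosis(records: pd.DataFrame) -> TimeToDiagnosisSummary:
    """Summarize the diagnosis-timing gain over standard of care.

    Expects columns Subject, Diagnosis, SurgeryToDBSI_weeks,
    SurgeryToSOC_weeks; stable/excluded patients are dropped. The
    per-patient difference is SOC minus DBSI weeks (positive = the
    assisted read was earlier).
    """
    rec = records[records["Diagnosis"].isin(ANALYZED_DIAGNOSES)].copy()
    if len(rec) == 0:
        raise ValueError("no analyzed (treatment effect / progression) records")
    if rec[["SurgeryToDBSI_weeks", "SurgeryToSOC_weeks"]].isna().any().any():
        raise ValueError("analyzed records must have both diagnosis times")
    if "Difference_weeks" in rec and rec["Difference_weeks"].notna().all():
        # a reported difference column (from unrounded source dates)
        # takes precedence over subtracting the rounded times
        diff = rec["Difference_weeks"].to_numpy(float)
    else:
        diff = (rec["SurgeryToSOC_weeks"] - rec["SurgeryToDBSI_weeks"]).to_numpy(float)
    rec["Difference_weeks"] = diff
    q1, med, q3 = _quartiles(diff)
    by_group = {}
    for g, sub in rec.groupby("Diagnosis"):
        d = sub["Difference_weeks"].to_numpy(float)
        gq1, gmed, gq3 = _quartiles(d)
        by_group[g] = dict(
            n=len(d), n_earlier=int((d > 0).sum()), median=gmed, iqr=(gq1, gq3)
        )
    n_earlier = int((diff > 0).sum())
    return TimeToDiagnosisSummary(
        n_analyzed=len(rec),
        n_earlier=n_earlier,
        fraction_earlier=n_earlier / len(rec),
        median=med,
        iqr=(q1, q3),
        by_group=by_group,
        differences=rec.reset_index(drop=True),
    )
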