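"""Longitudinal statistics: interval-adjusted progression, normality-gated
paired comparisons, BH multiplicity adjustment, and the Spearman
progression-correlation matrix.

The progression of a metric over a two-visit pair is the fractional change
rescaled by the ratio of the cohort-average to the individual scan interval:

    progression = ((var_f - var_b) / var_b) * (average_interval / individual_interval)

which assumes an approximately constant per-day progression rate — reasonable
when the interval distribution is narrow (e.g. 360.10 +/- 15.38 days).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "progression",
    "progression_table",
    "TestResult",
    "paired_compare",
    "compare_all",
    "fdr_adjust",
    "spearman_matrix",
]


def progression(
    var_baseline,
    var_followup,
    individual_interval,
    average_interval: float,
):
    """Interval-adjusted fractional change (dimensionless); invariant to
    rescaling the metric's units. Errors on zero baseline (undefined
    fractional change) or non-positive intervals."""
    b = np.asarray(var_baseline, dtype=float)
    f = np.asarray(var_followup, dtype=float)
    ind = np.asarray(individual_interval, dtype=float)
    if np.any(b == 0):
        raise ValueError("baseline value of 0 makes fractional change undefined")
    if average_interval <= 0 or np.any(ind <= 0):
        raise ValueError("scan intervals must be positive")
    out = (f - b) / b * (average_interval / ind)
    return out if out.ndim else float(out)


def progression_table(
    cohort: pd.DataFrame, average_interval: Optional[float] = None
) -> pd.DataFrame:
    """Per subject x metric adjusted progression from a two-visit cohort
    table with columns (subject_id, metric, baseline, followup,
    interval_days). The cohort-average interval defaults to the mean of
    per-subject intervals; it is recorded in ``attrs``."""
    per_subject = cohort.drop_duplicates("subject_id").set_index("subject_id")[
        "interval_days"
    ]
    if average_interval is None:
        average_interval = float(per_subject.mean())
    out = cohort.copy()
    out["progression"] = progression(
        out["baseline"].to_numpy(),
        out["followup"].to_numpy(),
        out["interval_days"].to_numpy(),
        average_interval,
    )
    table = out.pivot(index="subject_id", columns="metric", values="progression")
    table.attrs["average_interval_days"] = average_interval
    return table


@dataclass
class TestResult:
    """Paired-comparison outcome for one metric."""

    metric: str
    baseline_mean: float
    baseline_sd: float
    followup_mean: float
    followup_sd: float
    test_used: str  # 'paired-t' | 'wilcoxon' | 'degenerate'
    p_value: float
    q_value: float = np.nan
    shapiro_p: float = np.nan


def paired_compare(
    baseline: Sequence[float],
    followup: Sequence[float],
    *,
    metric: str = "",
    normality_alpha: float = 0.05,
) -> TestResult:
    """Two-sided paired comparison with a Shapiro-Wilk gate on the paired
    differences: normal differences (p >= ``normality_alpha``) get the
    paired t-test, non-normal ones the Wilcoxon signed-rank test (Pratt
    zero handling; exact distribution for n < 25 when free of zeros and
    ties, otherwise normal approximation with continuity correction)."""
    b = np.asarray(baseline, dtype=float)
    f = np.asarray(followup, dtype=float)
    if b.shape != f.shape:
        raise ValueError("baseline and follow-up must be aligned by subject")
    n = b.size
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    diff = f - b
    common = dict(
        metric=metric,
        baseline_mean=float(b.mean()),
        baseline_sd=float(b.std(ddof=1)),
        followup_mean=float(f.mean()),
        followup_sd=float(f.std(ddof=1)),
    )
    if np.all(diff == 0):
        return TestResult(**common, test_used="degenerate", p_value=1.0)
    if np.ptp(diff) == 0:
        # constant non-zero shift: Shapiro undefined; t-test is degenerate
        # (zero variance), fall back to Wilcoxon sign logic
        sw_p = 0.0
    else:
        sw_p = float(sps.shapiro(diff).pvalue)
    if sw_p >= normality_alpha:
        p = float(sps.ttest_rel(f, b).pvalue)
        test = "paired-t"
    else:
        nonzero = diff[diff != 0]
        exact_ok = n < 25 and np.all(diff != 0) and len(np.unique(np.abs(nonzero))) == n
        if exact_ok:
            res = sps.wilcoxon(f, b, zero_method="pratt", method="exact")
        else:
            res = sps.wilcoxon(
                f, b, zero_method="pratt", correction=True, method="approx"
            )
        p = float(res.pvalue)
        test = "wilcoxon"
    return TestResult(**common, test_used=test, p_value=p, shapiro_p=sw_p)


def fdr_adjust(
    p_values: Sequence[float], family: Optional[Sequence] = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, applied within each declared
    family (``family`` gives one label per p-value; None = single family).
    Monotone in p within a family, and q >= p always."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.empty_like(p)
    if family is None:
        family = np.zeros(p.size)
    family = np.asarray(family)
    for fam in np.unique(family):
        sel = family == fam
        q[sel] = multipletests(p[sel], method="fdr_bh")[1]
    return q


def compare_all(
    cohort: pd.DataFrame,
    family_map: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Run paired_compare per metric of a cohort table and attach BH
    q-values; ``family_map`` (metric -> family label) scopes the adjustment
    to measurement blocks, defaulting to one family for all metrics."""
    results = []
    for metric, g in cohort.groupby("metric", sort=True):
        g = g.sort_values("subject_id")
        results.append(
            paired_compare(g["baseline"].to_numpy(), g["followup"].to_numpy(),
                           metric=metric)
        )
    fams = [family_map.get(r.metric, "all") if family_map else "all" for r in results]
    q = fdr_adjust([r.p_value for r in results], fams)
    rows = []
    for r, qv in zip(results, q):
        r.q_value = float(qv)
        rows.append(vars(r).copy())
    return pd.DataFrame(rows).set_index("metric")


def spearman_matrix(progressions: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise Spearman rank correlation (average-rank ties,
    pairwise-complete observations) over progression variables.

    Constant variables get NaN correlations (flagged in ``attrs``); the
    diagonal is exactly 1 for non-constant variables and the matrix is
    symmetric with entries in [-1, 1].
    """
    counts = progressions.notna().astype(int)
    pair_counts = counts.T @ counts
    if (pair_counts.to_numpy() < min_pairs).any():
        raise ValueError(
            f"fewer than {min_pairs} complete subjects for some variable pair"
        )
    corr = progressions.corr(method="spearman", min_periods=min_pairs)
    constant = [
        c for c in progressions.columns
        if progressions[c].dropna().nunique() <= 1
    ]
    for c in corr.columns:
        if c not in constant:
            corr.loc[c, c] = 1.0
    corr.attrs["constant_variables"] = constant
    corr.attrs["ties"] = "average ranks"
    corr.attrs["missing"] = "pairwise complete"
    return corr
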