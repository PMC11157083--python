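"""Replicate-aware statistics for grouped measurements.

The averaging hierarchy is the part that is easy to get wrong and is owned
here: technical replicates are averaged into their biological replicate
first, and only biological-replicate means enter group-level summaries and
tests.  The tests themselves (one-way ANOVA, Tukey HSD, Welch's t) delegate
to scipy/statsmodels-grade routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05


@dataclass
class GroupSummary:
    group: str
    mean: float
    sem: float  # NaN when only one biological replicate
    n_replicates: int


def replicate_average(
    data: pd.DataFrame,
    value: str = "value",
    technical: str = "technical_id",
    biological: str = "biological_id",
    group: str = "group",
) -> tuple[pd.DataFrame, list[GroupSummary]]:
    """Hierarchical means: technical -> biological -> group.

    Returns the per-biological-replicate means (one row per biological
    replicate and group) and per-group summaries (mean +- SEM over
    biological replicates).  A replicate with many technical values still
    counts once at group level.
    """
    required = {value, biological, group}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if data.empty:
        raise ValueError("empty data")
    bio = (
        data.groupby([group, biological], sort=True)[value]
        .mean()
        .reset_index()
        .rename(columns={value: "mean"})
    )
    summaries = []
    for g, sub in bio.groupby(group, sort=True):
        vals = sub["mean"].to_numpy()
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
        summaries.append(
            GroupSummary(group=str(g), mean=float(vals.mean()), sem=sem, n_replicates=len(vals))
        )
    return bio, summaries


def pearson_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of a features-by-observation table.

    Requires >= 3 observations; zero-variance features yield NaN entries
    (flagged, not zeroed).
    """
    numeric = table.select_dtypes(include=[np.number])
    if len(numeric) < 3:
        raise ValueError("need at least 3 observations")
    return numeric.corr(method="pearson")


@dataclass
class AnovaTukeyResult:
    f_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, p_adj, reject
    alpha: float = ALPHA


def one_way_anova_tukey(groups: dict[str, np.ndarray], alpha: float = ALPHA) -> AnovaTukeyResult:
    """One-way ANOVA F-test plus Tukey HSD via the studentized range."""
    names = list(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    f_stat, p = sps.f_oneway(*arrays)
    tukey = sps.tukey_hsd(*arrays)
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p_adj = float(tukey.pvalue[i, j])
            rows.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "p_adj": p_adj,
                    "reject": p_adj < alpha,
                }
            )
    return AnovaTukeyResult(
        f_statistic=float(f_stat), p_value=float(p), pairwise=pd.DataFrame(rows), alpha=alpha
    )


@dataclass
class WelchResult:
    t_statistic: float
    df: float
    p_value: float


def welch_t(group_a: np.ndarray, group_b: np.ndarray) -> WelchResult:
    """Welch's unequal-variance t-test with Welch-Satterthwaite df."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    res = sps.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    if va + vb == 0:
        df = float(len(a) + len(b) - 2)
    else:
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return WelchResult(t_statistic=float(res.statistic), df=float(df), p_value=float(res.pvalue))
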