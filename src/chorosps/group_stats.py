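"""Cohort comparison of the choroid metrics across diagnostic groups.

The study design compares controls against multiple sclerosis (MS) and
Parkinson disease (PD) cohorts: per-group mean +/- SD of CA, COID and CD, a
one-way ANOVA omnibus test per metric, and pairwise post hoc comparisons.
Normality of the metrics is assumed (screened upstream in the study
design, not re-tested here); the post hoc procedure is Welch's pairwise t
with Bonferroni adjustment, a conservative, assumption-light choice.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

GROUP_LABELS = ("control", "MS", "PD")
METRIC_COLUMNS = ("CA", "COID", "CD")


@dataclass(frozen=True)
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_means: dict[str, float]
    group_sds: dict[str, float]


def _validate_groups(groups: Mapping[str, Sequence[float]], min_n: int = 2) -> None:
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for name, vals in groups.items():
        if len(vals) < min_n:
            raise ValueError(f"group {name!r} has n={len(vals)} < {min_n}")


def summarize_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean and sample SD (n-1 denominator) of each metric.

    ``table`` needs columns ``group`` plus the metrics; a single-member
    group gets NaN as its undefined-SD marker.  Values are returned at
    full precision; round to 2 dp at display time.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    metrics = [c for c in METRIC_COLUMNS if c in table.columns]
    if not metrics:
        raise ValueError(f"no metric columns among {METRIC_COLUMNS} present")
    agg = table.groupby("group", sort=True)[metrics].agg(["mean", "std", "count"])
    agg.columns = [f"{m}_{s}" for m, s in agg.columns]
    return agg


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Fixed-effects one-way ANOVA across the groups.

    F = (SSB / (k-1)) / (SSW / (N-k)); the p-value is the upper tail of
    the F(k-1, N-k) distribution.  The degenerate all-identical case is
    defined as F = 0, p = 1.
    """
    _validate_groups(groups)
    arrays = {g: np.asarray(v, dtype=np.float64) for g, v in groups.items()}
    k = len(arrays)
    n_total = sum(a.size for a in arrays.values())
    grand = sum(a.sum() for a in arrays.values()) / n_total
    ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_b, df_w = k - 1, n_total - k
    if ssw == 0.0:
        f = 0.0 if ssb == 0.0 else np.inf
        p = 1.0 if ssb == 0.0 else 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(
        f=float(f),
        df_between=df_b,
        df_within=df_w,
        p=p,
        group_means={g: float(a.mean()) for g, a in arrays.items()},
        group_sds={g: float(a.std(ddof=1)) for g, a in arrays.items()},
    )


def pairwise_posthoc(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """All-pairs Welch t-tests with Bonferroni adjustment.

    Returns one row per unordered pair with the raw and adjusted p
    (``p_adj = min(1, p * m)`` over the m pairs) and a significance flag
    at ``alpha``.
    """
    _validate_groups(groups)
    arrays = {g: np.asarray(v, dtype=np.float64) for g, v in groups.items()}
    pairs = list(combinations(arrays, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        if np.ptp(arrays[a]) == 0 and np.ptp(arrays[b]) == 0:
            t, p = (0.0, 1.0) if arrays[a].mean() == arrays[b].mean() else (np.inf, 0.0)
        else:
            t, p = stats.ttest_ind(arrays[a], arrays[b], equal_var=False)
        p_adj = min(1.0, float(p) * m)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "t": float(t),
                "p_raw": float(p),
                "p_adj": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def cohort_report(table: pd.DataFrame, alpha: float = 0.05) -> dict[str, dict]:
    """Full per-metric report: group summary, omnibus ANOVA, post hoc pairs."""
    out: dict[str, dict] = {}
    for metric in (c for c in METRIC_COLUMNS if c in table.columns):
        groups = {
            g: sub[metric].to_numpy() for g, sub in table.groupby("group", sort=True)
        }
        anova = one_way_anova(groups)
        out[metric] = {
            "anova": anova,
            "posthoc": pairwise_posthoc(groups, alpha=alpha),
        }
    return out
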