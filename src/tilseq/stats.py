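"""Rank-sum statistics and the body-weight normalization formula.

The two-sided Wilcoxon rank-sum test is the workhorse for group
comparisons of per-cell scores and per-gene expression. Small tie-free
samples (n1, n2 <= 10) use the exact null distribution of the rank sum;
larger or tied samples use the normal approximation with tie-corrected
variance and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from ._util import InputError

__all__ = ["RankSumResult", "wilcoxon_rank_sum", "rank_sum_de", "relative_body_weight"]


@dataclass
class RankSumResult:
    statistic: float      # rank-sum W of sample 1 (midranks under ties)
    p_value: float
    method: str           # exact | normal_tie_corrected
    n1: int
    n2: int


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    has_ties = np.unique(np.concatenate([x, y])).size < n1 + n2
    if n1 <= 10 and n2 <= 10 and not has_ties:
        method = "exact"
        res = sstats.mannwhitneyu(x, y, alternative=alternative, method="exact")
    else:
        method = "normal_tie_corrected"
        res = sstats.mannwhitneyu(x, y, alternative=alternative,
                                  method="asymptotic", use_continuity=True)
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0   # U1 -> rank-sum of sample 1
    return RankSumResult(w, float(res.pvalue), method, n1, n2)


def rank_sum_de(norm: pd.DataFrame, group_a: list[str], group_b: list[str],
                adjust: str = "bonferroni") -> pd.DataFrame:
    """Per-gene rank-sum differential expression between two cell groups.

    ``norm`` is genes x cells of log-normalized values; effect size is
    the difference of group means on that log scale. ``adjust`` is
    "bonferroni" (default) or "bh" (Benjamini-Hochberg).
    """
    group_a, group_b = list(group_a), list(group_b)
    if not group_a or not group_b:
        raise InputError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise InputError("groups overlap")
    missing = [c for c in group_a + group_b if c not in norm.columns]
    if missing:
        raise InputError(f"cells not in matrix: {missing[:5]}")
    a = norm[group_a].values
    b = norm[group_b].values
    pvals, effects, mean_a, mean_b, stats_w = [], [], [], [], []
    for i in range(norm.shape[0]):
        xa, xb = a[i], b[i]
        if np.all(xa == xa[0]) and np.all(xb == xa[0]):
            # gene identical in both groups: no evidence either way
            r = RankSumResult(np.nan, 1.0, "degenerate", len(xa), len(xb))
        else:
            r = wilcoxon_rank_sum(xa, xb)
        pvals.append(r.p_value)
        stats_w.append(r.statistic)
        mean_a.append(xa.mean())
        mean_b.append(xb.mean())
        effects.append(xa.mean() - xb.mean())
    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}[adjust]
    adj = multipletests(pvals, method=method)[1]
    return pd.DataFrame({
        "gene": norm.index,
        "statistic": stats_w,
        "p_value": pvals,
        "p_adjusted": adj,
        "effect": effects,
        "mean_a": mean_a,
        "mean_b": mean_b,
    }).set_index("gene")


def relative_body_weight(weights: pd.DataFrame, control_animals: list[str]
                         ) -> pd.DataFrame:
    """Body-weight change relative to the control-group trajectory.

    ``weights`` has columns animal, day, weight (one row per animal-day).
    For each animal and day x,

        value = [BW(day x) / BW(day 0)] / [BWctrl(day x) / BWctrl(day 0)]

    where BWctrl is the mean weight of ``control_animals`` on that day.
    """
    required = {"animal", "day", "weight"}
    if not required.issubset(weights.columns):
        raise InputError(f"weight table must have columns {sorted(required)}")
    if (weights["weight"] <= 0).any():
        raise InputError("weights must be positive")
    wide = weights.pivot_table(index="animal", columns="day", values="weight")
    if 0 not in wide.columns or wide[0].isna().any():
        raise InputError("every animal needs a day-0 weight")
    ctrl = wide.loc[[a for a in control_animals if a in wide.index]]
    if ctrl.empty:
        raise InputError("no control animals found in the weight table")
    ctrl_traj = ctrl.mean(axis=0)
    rel = wide.div(wide[0], axis=0).div(ctrl_traj / ctrl_traj[0], axis=1)
    out = rel.reset_index().melt(id_vars="animal", var_name="day",
                                 value_name="relative_weight").dropna()
    return out.sort_values(["animal", "day"]).reset_index(drop=True)
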