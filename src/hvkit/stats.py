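"""Comparison statistics for measurement groups (mean ± SEM convention).

Two-condition comparisons use Welch's unequal-variance t-test; three or more
conditions use one-way ANOVA with Tukey's HSD post hoc correction, whose
adjusted p-values come from the studentized range distribution (evaluated
numerically by scipy, not from tables).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["GroupSummary", "WelchResult", "AnovaTukeyResult", "welch_t",
           "anova_tukey", "significance_stars"]


@dataclass
class GroupSummary:
    """Label, raw values, and the mean ± SEM summary used for reporting."""

    label: str
    values: np.ndarray
    n: int
    mean: float
    sem: float

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        if v.size < 1:
            raise ValueError("a group needs at least one observation")
        sem = float(sps.sem(v)) if v.size >= 2 else float("nan")
        return cls(label=label, values=v, n=v.size, mean=float(v.mean()), sem=sem)


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


@dataclass
class AnovaTukeyResult:
    F: float
    p: float
    pairwise: pd.DataFrame  # columns: group_a, group_b, diff, p_adj, stars


def welch_t(group_a, group_b) -> WelchResult:
    """Welch's unequal-variance t-test with Satterthwaite degrees of freedom."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2 for a Welch t-test")
    res = sps.ttest_ind(a, b, equal_var=False)
    if np.isnan(res.statistic):  # both groups constant and equal
        return WelchResult(t=0.0, df=float(res.df), p=1.0)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


def significance_stars(p: float) -> str:
    """The journal star convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def anova_tukey(groups: "dict[str, Sequence[float]]") -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD adjusted pairwise p-values.

    ``groups`` maps labels to observation lists (each n >= 2).  With exactly
    two groups this degenerates to the pooled-variance t-test (F = t^2).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if all(np.ptp(a) == 0 for a in arrays) and len({a[0] for a in arrays}) == 1:
        # all observations identical: no variance anywhere
        F, p = 0.0, 1.0
        rows = [
            (labels[i], labels[j], 0.0, 1.0, "ns")
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    else:
        F, p = sps.f_oneway(*arrays)
        hsd = sps.tukey_hsd(*arrays)
        rows = []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                p_adj = float(hsd.pvalue[i, j])
                rows.append(
                    (
                        labels[i],
                        labels[j],
                        float(arrays[i].mean() - arrays[j].mean()),
                        p_adj,
                        significance_stars(p_adj),
                    )
                )
    table = pd.DataFrame(
        rows, columns=["group_a", "group_b", "diff", "p_adj", "stars"]
    )
    return AnovaTukeyResult(F=float(F), p=float(p), pairwise=table)
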