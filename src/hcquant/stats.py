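"""Group-comparison decision tree and summary conventions.

Normality of every group is assessed with the Shapiro-Wilk test. If all
groups pass at the chosen alpha, means are compared with one-way ANOVA and
Bonferroni-adjusted pairwise two-sided t-tests (a plain t-test when there
are exactly two groups). If any group fails, the Kruskal-Wallis test is
used with Dunn's pairwise z-tests under the Sidak adjustment
p_adj = 1 - (1 - p)^m. Summaries are mean +/- s.e.m. with significance
stars at nested thresholds 0.05 / 0.005 / 0.0005.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class GroupData:
    """Labelled numeric samples, one entry per group (each n >= 3)."""

    groups: dict  # label -> 1-D array

    def __post_init__(self):
        if len(self.groups) < 2:
            raise ValueError("need at least 2 groups")
        clean = {}
        for label, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size < 3:
                raise ValueError(f"group {label!r} needs n >= 3")
            clean[label] = arr
        object.__setattr__(self, "groups", clean)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, group_col: str = "group",
                   value_col: str = "value") -> "GroupData":
        return cls({str(g): sub[value_col].to_numpy()
                    for g, sub in df.groupby(group_col)})


@dataclass
class ComparisonResult:
    omnibus_test: str
    omnibus_p: float
    pairwise: pd.DataFrame       # pair, p_adj, stars
    group_summary: pd.DataFrame  # group, mean, sem, n
    parametric: bool
    shapiro_p: dict


def star_label(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.005, *** p<0.0005."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if p < 0.0005:
        return "***"
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def sidak_adjust(p: float, m: int) -> float:
    """Dunn-Sidak multiplicity adjustment, 1 - (1-p)^m, clipped to [0, 1]."""
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


def kruskal_wallis_h(groups: list[np.ndarray]) -> float:
    """Kruskal-Wallis H with the standard tie correction."""
    data = np.concatenate(groups)
    n_total = data.size
    ranks = sps.rankdata(data)
    grand = (n_total + 1) / 2.0
    pos = 0
    h = 0.0
    for g in groups:
        r = ranks[pos:pos + g.size]
        h += g.size * (r.mean() - grand) ** 2
        pos += g.size
    h *= 12.0 / (n_total * (n_total + 1))
    _, counts = np.unique(data, return_counts=True)
    tie = 1.0 - np.sum(counts ** 3 - counts) / (n_total ** 3 - n_total)
    return h / tie


def _dunn_pairwise(groups: dict, alpha: float) -> pd.DataFrame:
    """Dunn's z-tests on the joint ranking with Sidak adjustment."""
    labels = list(groups)
    data = np.concatenate([groups[k] for k in labels])
    n_total = data.size
    ranks = sps.rankdata(data)
    mean_rank, sizes, pos = {}, {}, 0
    for k in labels:
        n = groups[k].size
        mean_rank[k] = ranks[pos:pos + n].mean()
        sizes[k] = n
        pos += n
    _, counts = np.unique(data, return_counts=True)
    tie_term = np.sum(counts ** 3 - counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = sidak_adjust(p, m)
        rows.append((a, b, p_adj, star_label(p_adj)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj", "stars"])


def _t_pairwise(groups: dict) -> pd.DataFrame:
    """Two-sided t-tests with Bonferroni adjustment."""
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        res = sps.ttest_ind(groups[a], groups[b])
        p = float(res.pvalue)
        if np.isnan(p):  # both groups constant and equal
            p = 1.0
        p_adj = min(1.0, p * m)
        rows.append((a, b, p_adj, star_label(p_adj)))
    return pd.DataFrame(rows, columns=["group_a", "group_b", "p_adj", "stars"])


def compare_groups(data: GroupData | dict, alpha: float = 0.05,
                   ) -> ComparisonResult:
    """Run the normality-gated comparison tree on labelled samples.

    All groups must pass Shapiro-Wilk at ``alpha`` for the parametric
    branch; a single failure (including a constant group, for which
    normality is undefined) routes everything to the nonparametric branch.
    """
    if not isinstance(data, GroupData):
        data = GroupData(data)
    groups = data.groups
    shapiro_p = {}
    all_normal = True
    for label, vals in groups.items():
        if np.ptp(vals) == 0:
            shapiro_p[label] = 0.0  # constant: not normal
            all_normal = False
            continue
        p = float(sps.shapiro(vals).pvalue)
        shapiro_p[label] = p
        if p < alpha:
            all_normal = False

    arrays = list(groups.values())
    if all_normal:
        if len(arrays) == 2:
            omni = sps.ttest_ind(arrays[0], arrays[1])
            name = "t-test"
        else:
            omni = sps.f_oneway(*arrays)
            name = "ANOVA"
        pairwise = _t_pairwise(groups)
    else:
        omni = sps.kruskal(*arrays)
        name = "Kruskal-Wallis"
        pairwise = _dunn_pairwise(groups, alpha)

    summary = pd.DataFrame(
        [(k, v.mean(), v.std(ddof=1) / np.sqrt(v.size), v.size)
         for k, v in groups.items()],
        columns=["group", "mean", "sem", "n"])
    return ComparisonResult(omnibus_test=name, omnibus_p=float(omni.pvalue),
                            pairwise=pairwise, group_summary=summary,
                            parametric=all_normal, shapiro_p=shapiro_p)
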