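"""Per-cluster differential gene-set testing.

For every scoring method and every cluster, each gene set's per-cell
scores in the cluster are compared against all other cells with the
two-sided Wilcoxon rank-sum (Mann–Whitney) test.  P-values are Bonferroni
adjusted within each (method, cluster) across the gene sets tested, and a
set is called significant when the adjusted p-value is <= alpha (0.05 by
default).  Direction is up when the cluster's mean score exceeds the rest.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata

from .io_core import ClusterLabels, DataError
from .scoring import ScoreMatrix

logger = logging.getLogger("rankgsea")

__all__ = ["wilcoxon_rank_sum", "differential_all", "COLUMNS", "write_differential",
           "read_differential"]

COLUMNS = ["method", "cluster", "set_name", "avg_diff", "statistic",
           "p_value", "p_adjusted", "direction", "significant"]


def wilcoxon_rank_sum(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test; returns (rank-sum W of x, p).

    ``mode='auto'`` uses exact enumeration of the rank-sum distribution
    when the combined sample has at most 25 tie-free observations, and the
    normal approximation with tie and continuity corrections otherwise.
    A combined sample with all values identical yields p = 1 exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ValueError(f"unknown mode {mode!r}")
    combined = np.concatenate([x, y])
    w = float(rankdata(combined)[: x.size].sum())
    if np.all(combined == combined[0]):
        return w, 1.0
    ties = np.unique(combined).size < combined.size
    if mode == "auto":
        mode = "exact" if (combined.size <= 25 and not ties) else "normal"
    if mode == "exact" and ties:
        raise ValueError("exact mode requires tie-free data")
    res = mannwhitneyu(x, y, alternative="two-sided",
                       method="exact" if mode == "exact" else "asymptotic")
    return w, float(min(res.pvalue, 1.0))


def differential_all(scores: list[ScoreMatrix], labels: ClusterLabels,
                     alpha: float = 0.05, mode: str = "auto") -> pd.DataFrame:
    """One-vs-rest Wilcoxon tests for every (method, cluster, gene set).

    All score matrices must share their cell universe and the labels must
    cover every cell.  Bonferroni multiplies each raw p by the number of
    gene sets tested within its (method, cluster).  Rows are ordered by
    (method, cluster, p ascending, set name).
    """
    if not scores:
        raise ValueError("no score matrices supplied")
    cell_sets = {frozenset(s.cell_ids) for s in scores}
    if len(cell_sets) != 1:
        raise DataError("score matrices do not share the same cells")
    cells = scores[0].cell_ids
    missing = [c for c in cells if c not in labels.labels]
    if missing:
        raise DataError(f"cell {missing[0]!r} has no cluster label")
    clusters = labels.clusters
    if len(clusters) < 2:
        raise DataError("differential analysis requires >= 2 clusters")
    cluster_of = labels.labels
    for cl in clusters:
        n = sum(1 for c in cells if cluster_of[c] == cl)
        if n < 3:
            raise DataError(f"cluster {cl!r} has only {n} cell(s); >= 3 required")

    rows = []
    zero_diff = 0
    for s in scores:
        frame = s.to_frame()
        mask_by_cluster = {cl: np.array([cluster_of[c] == cl for c in s.cell_ids])
                           for cl in clusters}
        n_sets = len(s.set_names)
        for cl in clusters:
            in_cl = mask_by_cluster[cl]
            for set_name in s.set_names:
                vals = frame.loc[set_name].to_numpy()
                x, y = vals[in_cl], vals[~in_cl]
                w, p = wilcoxon_rank_sum(x, y, mode=mode)
                avg_diff = float(x.mean() - y.mean())
                if avg_diff == 0:
                    zero_diff += 1
                p_adj = min(1.0, p * n_sets)
                rows.append((s.method, cl, set_name, avg_diff, w, p, p_adj,
                             "up" if avg_diff >= 0 else "down", p_adj <= alpha))
    if zero_diff:
        logger.info("differential_all: %d zero mean-difference row(s) assigned direction 'up'",
                    zero_diff)
    df = pd.DataFrame(rows, columns=COLUMNS)
    df = df.sort_values(["method", "cluster", "p_value", "set_name"],
                        kind="stable").reset_index(drop=True)
    return df


def write_differential(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_differential(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing column(s) {missing}")
    return df
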