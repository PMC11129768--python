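"""Robust rank aggregation (RRA) of per-method differential results.

For each cluster and direction, every scoring method contributes a ranked
list of its significant gene sets (most significant first).  Each set's
ranks are normalised to (0, 1], sorted ascending, and compared with the
order statistics of k independent uniforms through the binomial upper
tail

    beta_{x,k}(r_(x)) = sum_{l=x..k} C(k, l) r_(x)^l (1 - r_(x))^{k-l},

the probability that the x-th smallest of k uniforms falls at or below
the observed r_(x).  The aggregation score rho is the minimum beta over
x, and the reported p-value is rho Bonferroni-corrected by the number of
methods k.  A set that every method ranks near the top receives a tiny
rho; a set listed by no method has every normalised rank imputed to 1 and
aggregates to p = 1.

Rank normalisation dialects
---------------------------
``union`` (default): r_ij = R_ij / N with N the number of candidate sets
of the rank universe; a set absent from a method's list is imputed the
bottom rank N (hence r = 1).  ``paper``: after the same imputation, each
set's ranks are divided by that set's largest rank across the k methods,
so the worst-ranking method's entry is forced to exactly 1.  The dialect
used is recorded in every output.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from .io_core import DataError

logger = logging.getLogger("rankgsea")

__all__ = ["RankLists", "build_rank_lists", "normalize_ranks", "beta_score",
           "aggregate", "write_rra", "read_rra", "DIALECTS"]

DIALECTS = ("union", "paper")


@dataclass
class RankLists:
    """Per-method significant-set orderings for one cluster and direction.

    ``lists`` maps each method to its significant sets ordered by
    increasing p-value; methods with nothing significant contribute an
    empty list but still count toward ``k``.  ``universe`` holds every
    candidate set of the aggregation (all sets tested for the cluster),
    so its size N is the denominator of the default rank normalisation
    and the imputed rank of absent sets.
    """

    cluster: str
    direction: str
    lists: dict[str, list[str]] = field(default_factory=dict)
    universe: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.lists)

    @property
    def n(self) -> int:
        return len(self.universe)

    def is_empty(self) -> bool:
        return all(len(v) == 0 for v in self.lists.values())


def build_rank_lists(d: pd.DataFrame, cluster: str, direction: str,
                     methods: list[str] | None = None) -> RankLists:
    """Extract per-method significant-set orderings from a differential table.

    Within a method, significant sets of the requested cluster and
    direction are ordered by p-value ascending, ties broken by |avg_diff|
    descending and then set name.  The universe is every set tested for
    the cluster (significant or not), so aggregation can impute bottom
    ranks for sets a method did not call.
    """
    if d.empty:
        raise DataError("differential table is empty")
    if methods is None:
        methods = sorted(d["method"].unique())
    sub = d[d["cluster"] == cluster]
    universe = sorted(sub["set_name"].unique())
    lists: dict[str, list[str]] = {}
    for method in sorted(methods):
        rows = sub[(sub["method"] == method) & (sub["direction"] == direction)
                   & sub["significant"]].copy()
        rows["abs_diff"] = rows["avg_diff"].abs()
        rows = rows.sort_values(["p_value", "abs_diff", "set_name"],
                                ascending=[True, False, True], kind="stable")
        lists[method] = rows["set_name"].tolist()
    return RankLists(cluster=cluster, direction=direction, lists=lists, universe=universe)


def normalize_ranks(rl: RankLists, dialect: str = "union") -> pd.DataFrame:
    """Normalised rank matrix r_ij in (0, 1] (rows = universe, columns = methods)."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown RRA dialect {dialect!r}; expected one of {DIALECTS}")
    n = rl.n
    if n == 0:
        return pd.DataFrame(index=[], columns=sorted(rl.lists))
    ranks = pd.DataFrame(float(n), index=rl.universe, columns=sorted(rl.lists))
    for method, listed in rl.lists.items():
        for pos, name in enumerate(listed, start=1):
            ranks.loc[name, method] = float(pos)
    if dialect == "union":
        return ranks / n
    denom = ranks.max(axis=1)
    return ranks.div(denom, axis=0)


def beta_score(r) -> tuple[np.ndarray, float]:
    """Order-statistic beta vector and its minimum rho for one set.

    ``r`` holds the k normalised ranks in (0, 1]; they are sorted
    ascending and beta_x is the binomial upper tail P(Bin(k, r_(x)) >= x).
    """
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("expected a non-empty 1-D vector of normalised ranks")
    if np.any((r <= 0) | (r > 1)):
        raise ValueError("normalised ranks must lie in (0, 1]")
    k = r.size
    rs = np.sort(r)
    beta = binom.sf(np.arange(k), k, rs)  # sf(x-1) = P(X >= x)
    return beta, float(beta.min())


def aggregate(d: pd.DataFrame, methods: list[str] | None = None, alpha: float = 0.05,
              dialect: str = "union") -> pd.DataFrame:
    """Aggregate a differential table into one RRA row per (cluster, direction, set).

    Every cluster x direction with at least one significant set is
    aggregated over its full candidate universe; non-significant rows are
    retained (p_corrected = 1 when no method lists the set) so callers
    can filter at their own alpha.  Output is invariant to the order in
    which methods are supplied.
    """
    if methods is None:
        methods = sorted(d["method"].unique()) if not d.empty else []
    methods = sorted(methods)
    k = len(methods)
    rows = []
    clusters = sorted(d["cluster"].unique()) if not d.empty else []
    for cluster in clusters:
        for direction in ("up", "down"):
            rl = build_rank_lists(d, cluster, direction, methods=methods)
            if rl.is_empty():
                continue
            r = normalize_ranks(rl, dialect=dialect)
            for set_name in rl.universe:
                beta, rho = beta_score(r.loc[set_name].to_numpy())
                p_corr = min(1.0, rho * k)
                detected = {m: set_name in rl.lists[m] for m in methods}
                rows.append({
                    "cluster": cluster,
                    "direction": direction,
                    "set_name": set_name,
                    "rho": rho,
                    "p_corrected": p_corr,
                    "significant": p_corr <= alpha,
                    "n_methods_detected": sum(detected.values()),
                    **{f"in_{m}": detected[m] for m in methods},
                })
    cols = (["cluster", "direction", "set_name", "rho", "p_corrected", "significant",
             "n_methods_detected"] + [f"in_{m}" for m in methods])
    df = pd.DataFrame(rows, columns=cols)
    if not df.empty:
        df = df.sort_values(["p_corrected", "cluster", "direction", "set_name"],
                            kind="stable").reset_index(drop=True)
    df.attrs["rra_dialect"] = dialect
    df.attrs["k"] = k
    return df


def write_rra(df: pd.DataFrame, path) -> None:
    """Write an RRA table as TSV, recording the dialect in a header comment."""
    with open(path, "w") as fh:
        fh.write(f"# rra_dialect={df.attrs.get('rra_dialect', 'union')}"
                 f"\tk={df.attrs.get('k', '')}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_rra(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        df = pd.read_csv(fh, sep="\t")
    if header.startswith("#"):
        for token in header[1:].strip().split("\t"):
            if "=" in token:
                key, val = token.split("=", 1)
                df.attrs[f"rra_{key}" if not key.startswith("rra") else key] = val
    return df
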