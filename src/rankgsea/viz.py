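"""Summary tables behind the figures, plus minimal static renderings.

Every figure is generated from a :class:`PlotTable` — a tidy table of the
exact numbers the plot displays — and nothing else, so results can be
audited (and re-plotted elsewhere) without touching rendering code.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_core import ClusterLabels, DataError
from .scoring import ScoreMatrix

logger = logging.getLogger("rankgsea")

__all__ = ["PlotTable", "stackbar_table", "upset_table", "heatmap_table", "bubble_table",
           "local_tables", "significance_stars", "render"]

KINDS = ("stackbar", "upset", "heatmap", "bubble", "density", "ridge",
         "halfviolin", "densityheatmap")


@dataclass
class PlotTable:
    kind: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)


def significance_stars(p: float) -> str:
    """Star binning: * <= 0.05, ** <= 0.01, *** <= 0.001."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def stackbar_table(d: pd.DataFrame, r: pd.DataFrame, alpha: float = 0.05) -> PlotTable:
    """Counts of significant sets per (method or RRA, cluster, direction).

    ``meta['percent']`` carries, per (method, cluster), the percentage of
    up / down / insignificant sets among those tested.
    """
    rows = []
    if not d.empty:
        sig = d[d["significant"]]
        for (method, cluster, direction), grp in sig.groupby(
                ["method", "cluster", "direction"], sort=True):
            rows.append((method, cluster, direction, len(grp)))
    if not r.empty:
        rsig = r[r["p_corrected"] <= alpha]
        for (cluster, direction), grp in rsig.groupby(["cluster", "direction"], sort=True):
            rows.append(("RRA", cluster, direction, len(grp)))
    counts = pd.DataFrame(rows, columns=["source", "cluster", "direction", "count"])

    pct_rows = []
    if not d.empty:
        for (method, cluster), grp in d.groupby(["method", "cluster"], sort=True):
            n = grp["set_name"].nunique()
            up = int((grp["significant"] & (grp["direction"] == "up")).sum())
            down = int((grp["significant"] & (grp["direction"] == "down")).sum())
            pct_rows.append((method, cluster, n, up, down, n - up - down,
                             100 * up / n, 100 * down / n, 100 * (n - up - down) / n))
    percent = pd.DataFrame(pct_rows, columns=[
        "method", "cluster", "n_sets", "n_up", "n_down", "n_insignificant",
        "pct_up", "pct_down", "pct_insignificant"])
    return PlotTable("stackbar", counts, {"percent": percent, "alpha": alpha})


def upset_table(r: pd.DataFrame, alpha: float = 0.05) -> PlotTable:
    """Binary set x cluster membership of RRA-significant sets + intersections."""
    if r.empty:
        return PlotTable("upset", pd.DataFrame(), {"intersections": pd.DataFrame()})
    sig = r[r["p_corrected"] <= alpha]
    if sig.empty:
        return PlotTable("upset", pd.DataFrame(), {"intersections": pd.DataFrame()})
    membership = (sig.assign(flag=1)
                  .pivot_table(index="set_name", columns="cluster", values="flag",
                               aggfunc="max", fill_value=0)
                  .sort_index())
    combos = (membership.apply(lambda row: tuple(membership.columns[row.astype(bool)]), axis=1)
              .value_counts().rename_axis("clusters").reset_index(name="count"))
    return PlotTable("upset", membership, {"intersections": combos, "alpha": alpha})


def heatmap_table(r: pd.DataFrame) -> PlotTable:
    """Tidy table of signed -log10(p_corrected) with significance stars."""
    if r.empty:
        return PlotTable("heatmap", pd.DataFrame(
            columns=["cluster", "set_name", "direction", "p_corrected",
                     "neglog10_p", "signed_neglog10_p", "stars"]))
    data = r[["cluster", "set_name", "direction", "p_corrected"]].copy()
    with np.errstate(divide="ignore"):
        data["neglog10_p"] = -np.log10(data["p_corrected"])
    data["signed_neglog10_p"] = np.where(data["direction"] == "up", 1, -1) * data["neglog10_p"]
    data["stars"] = data["p_corrected"].map(significance_stars)
    return PlotTable("heatmap", data.reset_index(drop=True))


def bubble_table(r: pd.DataFrame) -> PlotTable:
    """Same numbers as the heatmap with bubble size = -log10(p_corrected)."""
    pt = heatmap_table(r)
    data = pt.data.rename(columns={"neglog10_p": "size"}) if not pt.data.empty else pt.data
    return PlotTable("bubble", data)


def local_tables(s: ScoreMatrix, set_name: str, labels: ClusterLabels,
                 embedding: pd.DataFrame | None = None) -> dict[str, PlotTable]:
    """Per-cluster score-distribution views for one gene set.

    Returns a ``distribution`` table (per-cluster quintiles and means), a
    ``density`` table (Gaussian kernel density on a common grid; a
    constant score collapses to a single point), and — when a per-cell
    2-D ``embedding`` indexed by cell id is supplied — an ``embedding``
    table joining each cell's score to its coordinates.
    """
    if set_name not in s.set_names:
        raise DataError(f"unknown gene set {set_name!r}")
    frame = s.to_frame()
    values = frame.loc[set_name]
    cluster_of = labels.labels
    per_cluster = {}
    for cell, v in values.items():
        per_cluster.setdefault(cluster_of[cell], []).append(float(v))

    q = [0.0, 0.2, 0.4, 0.6, 0.8, 1.0]
    dist_rows = []
    for cluster in sorted(per_cluster):
        vals = np.array(per_cluster[cluster])
        dist_rows.append((cluster, len(vals), float(vals.mean()),
                          *[float(x) for x in np.quantile(vals, q)]))
    distribution = pd.DataFrame(dist_rows, columns=[
        "cluster", "n_cells", "mean", "q0", "q20", "q40", "q60", "q80", "q100"])

    dens_rows = []
    for cluster in sorted(per_cluster):
        vals = np.array(per_cluster[cluster])
        if np.ptp(vals) == 0 or len(vals) < 2:
            dens_rows.append((cluster, float(vals[0]), 1.0))
            continue
        from scipy.stats import gaussian_kde
        grid = np.linspace(vals.min(), vals.max(), 64)
        dens = gaussian_kde(vals)(grid)
        dens_rows.extend((cluster, float(x), float(y)) for x, y in zip(grid, dens))
    density = pd.DataFrame(dens_rows, columns=["cluster", "score", "density"])

    out = {
        "distribution": PlotTable("halfviolin", distribution, {"set_name": set_name}),
        "density": PlotTable("ridge", density, {"set_name": set_name}),
    }
    if embedding is not None:
        emb = embedding.copy()
        emb["score"] = values.reindex(emb.index)
        emb["cluster"] = [cluster_of.get(c) for c in emb.index]
        out["embedding"] = PlotTable("densityheatmap", emb, {"set_name": set_name})
    else:
        logger.warning("no embedding supplied; density-scatter table omitted")
    return out


# ---------------------------------------------------------------------------
# renderings: pure functions of a PlotTable


def render(pt: PlotTable, path) -> None:
    """Render a PlotTable as a minimal static figure (a pure function of it)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    data = pt.data
    if pt.kind == "stackbar" and not data.empty:
        pivot = data.pivot_table(index=["source", "cluster"], columns="direction",
                                 values="count", fill_value=0)
        pivot.plot.bar(stacked=True, ax=ax)
        ax.set_ylabel("significant gene sets")
    elif pt.kind == "upset" and not data.empty:
        ax.imshow(data.to_numpy(), aspect="auto", cmap="Greys")
        ax.set_xticks(range(len(data.columns)), data.columns, rotation=90)
        ax.set_yticks(range(len(data.index)), data.index, fontsize=6)
    elif pt.kind in ("heatmap", "bubble") and not data.empty:
        col = "signed_neglog10_p" if "signed_neglog10_p" in data else "size"
        pivot = data.pivot_table(index="set_name", columns="cluster", values=col,
                                 aggfunc="max", fill_value=0.0)
        im = ax.imshow(pivot.to_numpy(), aspect="auto", cmap="RdBu_r")
        fig.colorbar(im, ax=ax, label="signed -log10 p")
        ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90)
        ax.set_yticks(range(len(pivot.index)), pivot.index, fontsize=6)
    elif pt.kind in ("ridge", "density") and not data.empty:
        for cluster, grp in data.groupby("cluster"):
            ax.plot(grp["score"], grp["density"], label=str(cluster))
        ax.legend()
        ax.set_xlabel("score")
        ax.set_ylabel("density")
    elif pt.kind == "halfviolin" and not data.empty:
        ax.errorbar(range(len(data)), data["mean"],
                    yerr=[data["mean"] - data["q20"], data["q80"] - data["mean"]],
                    fmt="o")
        ax.set_xticks(range(len(data)), data["cluster"])
        ax.set_ylabel("score")
    else:
        ax.text(0.5, 0.5, "no data", ha="center")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
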