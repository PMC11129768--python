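"""Synthetic single-cell datasets with known cluster structure and planted signal.

The generator emulates a clustered droplet scRNA-seq experiment scored
against a hallmark-like gene-set collection: gene baseline means are
log-normal, counts are negative-binomial per cell (dropout zeros arise
naturally from the NB sampling), and each *planted* gene set has its
member genes' means multiplied by a fold change in exactly one target
cluster.  Every set draws its genes from a disjoint slice of the genome,
so non-planted sets are clean negative controls.

The NB parameterisation is var = mu + mu^2 * phi with phi the
``nb_dispersion`` field (phi = 0 degenerates to Poisson); this is stated
explicitly because dispersion conventions differ between tools.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .io_core import (ClusterLabels, DataError, ExpressionMatrix, GeneSetCollection,
                      write_clusters, write_expression, write_gmt)

__all__ = ["SimConfig", "GroundTruth", "simulate", "null_simulate",
           "sample_negative_binomial", "write_dataset"]


@dataclass
class SimConfig:
    """Generator parameters.

    Defaults describe the benchmark condition used throughout the test
    suite: 3 clusters of 200 cells over 2000 genes, 20 disjoint sets of
    30 genes, 3 of them planted 4-fold up in one cluster each.
    """

    n_genes: int = 2000
    n_cells_per_cluster: int = 200
    n_clusters: int = 3
    n_sets: int = 20
    set_size: int = 30
    n_planted: int = 3
    fold_change: float = 4.0
    nb_dispersion: float = 0.3
    baseline_mean_log_mu: float = 0.5
    baseline_mean_log_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_sets:
            raise ValueError("n_planted must be <= n_sets")
        if self.fold_change <= 0:
            raise ValueError("fold_change must be > 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if self.n_sets * self.set_size > self.n_genes:
            raise DataError(
                f"{self.n_sets} disjoint sets of {self.set_size} genes do not fit "
                f"into {self.n_genes} genes"
            )


@dataclass
class GroundTruth:
    """Planted set name -> (target cluster, direction)."""

    planted: dict[str, tuple[str, str]]

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(
            {k: {"cluster": v[0], "direction": v[1]} for k, v in self.planted.items()},
            indent=2))


def sample_negative_binomial(rng: np.random.Generator, mu: np.ndarray,
                             phi: float, size) -> np.ndarray:
    """NB counts with mean mu and variance mu + mu^2 * phi (phi=0 -> Poisson)."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), size)
    if phi == 0:
        return rng.poisson(mu)
    shape = 1.0 / phi
    p = shape / (shape + mu)
    return rng.negative_binomial(shape, p, size=size)


def simulate(cfg: SimConfig) -> tuple[ExpressionMatrix, ClusterLabels, GeneSetCollection, GroundTruth]:
    """Draw one dataset; bit-identical for identical configs (incl. seed)."""
    rng = np.random.default_rng(cfg.seed)
    n_genes, n_clusters = cfg.n_genes, cfg.n_clusters
    gene_ids = np.array([f"G{i + 1:05d}" for i in range(n_genes)], dtype=object)
    clusters = [f"C{i + 1}" for i in range(n_clusters)]

    base_mu = rng.lognormal(cfg.baseline_mean_log_mu, cfg.baseline_mean_log_sigma, n_genes)

    # disjoint gene slices for every set; planted sets come first
    perm = rng.permutation(n_genes)
    set_names = [f"SET{i + 1:02d}" for i in range(cfg.n_sets)]
    sets = {}
    for i, name in enumerate(set_names):
        members = perm[i * cfg.set_size:(i + 1) * cfg.set_size]
        sets[name] = [str(g) for g in gene_ids[np.sort(members)]]
    collection = GeneSetCollection(sets, {name: "synthetic" for name in set_names})

    planted = {set_names[i]: (clusters[i % n_clusters], "up") for i in range(cfg.n_planted)}
    truth = GroundTruth(planted)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    blocks, cell_ids, labels = [], [], {}
    for ci, cluster in enumerate(clusters):
        mu = base_mu.copy()
        for set_name, (target, _) in planted.items():
            if target == cluster:
                idx = [gene_pos[g] for g in sets[set_name]]
                mu[idx] *= cfg.fold_change
        counts = sample_negative_binomial(
            rng, mu[:, None], cfg.nb_dispersion, (n_genes, cfg.n_cells_per_cluster))
        blocks.append(counts)
        for j in range(cfg.n_cells_per_cluster):
            cid = f"cell{ci * cfg.n_cells_per_cluster + j + 1:05d}"
            cell_ids.append(cid)
            labels[cid] = cluster
    values = sp.csr_matrix(np.concatenate(blocks, axis=1).astype(float))
    matrix = ExpressionMatrix(gene_ids, np.array(cell_ids, dtype=object), values)
    return matrix, ClusterLabels(labels), collection, truth


def null_simulate(cfg: SimConfig) -> tuple[ExpressionMatrix, ClusterLabels, GeneSetCollection, GroundTruth]:
    """Same generator with no planted signal (cluster structure without effects)."""
    return simulate(dataclasses.replace(cfg, n_planted=0))


def write_dataset(outdir, matrix: ExpressionMatrix, labels: ClusterLabels,
                  collection: GeneSetCollection, truth: GroundTruth) -> None:
    """Write the dataset in the exact dialects the readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression(matrix, outdir, format="mtx10x")
    write_gmt(collection, outdir / "sets.gmt")
    write_clusters(labels, outdir / "clusters.tsv")
    truth.write(outdir / "ground_truth.json")
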