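"""Within-cell gene ranking: the shared primitive of every scoring method.

All six enrichment scores are functions of each cell's gene ranks alone.
Ranking a cell never looks at any other cell, which is what makes the
scores invariant to cohort composition: appending or removing cells from
the matrix cannot change an existing cell's score.

Zeros (dropouts) are ranked, not dropped: they form one tie group at the
least-expressed end.  Methods that restrict attention to expressed genes
(JASMINE) or cap uninformative tails (UCell) build that on top of these
ranks.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["CellRanks", "rank_cell", "rank_matrix", "quantile_positions", "TIE_METHODS"]

TIE_METHODS = ("average", "min", "dense", "random")


@dataclass
class CellRanks:
    """Descending and ascending within-cell ranks for one cell.

    ``rank_desc`` assigns 1 to the highest expression value, ``rank_asc``
    assigns 1 to the lowest.  With integer-resolved ties the two satisfy
    ``rank_desc + rank_asc = n_genes + 1`` per gene; with average ties the
    identity holds for tie-group means.
    """

    cell_id: str
    rank_desc: np.ndarray
    rank_asc: np.ndarray
    n_genes: int
    n_expressed: int


def _cell_rng(seed: int | None, cell_id: str) -> np.random.Generator:
    # reproducible per-cell stream: mix the global seed with a stable digest
    # of the cell id so results do not depend on the cell's column position
    digest = hashlib.blake2b(cell_id.encode(), digest_size=4).digest()
    return np.random.default_rng([0 if seed is None else int(seed), int.from_bytes(digest, "big")])


def _rank_vector(values: np.ndarray, ties: str, seed: int | None, cell_id: str):
    if ties == "random":
        rng = _cell_rng(seed, cell_id)
        perm = rng.permutation(len(values))
        order = np.lexsort((perm, -values))
        rank_desc = np.empty(len(values), dtype=float)
        rank_desc[order] = np.arange(1, len(values) + 1)
        rank_asc = len(values) + 1 - rank_desc
        return rank_desc, rank_asc
    rank_desc = rankdata(-values, method=ties)
    rank_asc = rankdata(values, method=ties)
    return rank_desc.astype(float), rank_asc.astype(float)


def rank_cell(values: np.ndarray, ties: str = "average", seed: int | None = None,
              cell_id: str = "") -> CellRanks:
    """Rank one cell's expression vector.

    ``ties`` is one of ``average`` (default), ``min``, ``dense`` or
    ``random``; random tie-breaking is reproducible from ``seed`` and
    ``cell_id`` only, not from the cell's position in any matrix.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot rank an empty expression vector")
    if not np.all(np.isfinite(values)) or values.min() < 0:
        raise ValueError("expression values must be finite and >= 0")
    if ties not in TIE_METHODS:
        raise ValueError(f"unknown tie policy {ties!r}; expected one of {TIE_METHODS}")
    rank_desc, rank_asc = _rank_vector(values, ties, seed, cell_id)
    return CellRanks(
        cell_id=cell_id,
        rank_desc=rank_desc,
        rank_asc=rank_asc,
        n_genes=values.size,
        n_expressed=int(np.count_nonzero(values)),
    )


def rank_matrix(X: np.ndarray, ties: str = "average", seed: int | None = None,
                cell_ids=None):
    """Column-wise ranks of a dense genes x cells matrix.

    Returns ``(rank_desc, rank_asc, n_expressed)`` with the two rank arrays
    of the same shape as ``X``.  Equivalent to calling :func:`rank_cell`
    per column (and tested to be); vectorised for the deterministic tie
    policies.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("expected a non-empty genes x cells matrix")
    if ties not in TIE_METHODS:
        raise ValueError(f"unknown tie policy {ties!r}; expected one of {TIE_METHODS}")
    n_expressed = np.count_nonzero(X, axis=0)
    if ties == "random":
        if cell_ids is None:
            cell_ids = [str(j) for j in range(X.shape[1])]
        rank_desc = np.empty_like(X)
        rank_asc = np.empty_like(X)
        for j, cid in enumerate(cell_ids):
            rank_desc[:, j], rank_asc[:, j] = _rank_vector(X[:, j], ties, seed, str(cid))
        return rank_desc, rank_asc, n_expressed
    rank_desc = rankdata(-X, method=ties, axis=0).astype(float)
    rank_asc = rankdata(X, method=ties, axis=0).astype(float)
    return rank_desc, rank_asc, n_expressed


def quantile_positions(r: CellRanks) -> np.ndarray:
    """Map ascending ranks to strictly interior quantiles (r - 0.5) / n."""
    return (r.rank_asc - 0.5) / r.n_genes
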