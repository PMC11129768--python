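"""Readers, writers and the shared containers of the package.

Three containers flow through every analysis: :class:`ExpressionMatrix`
(genes x cells, non-negative, sparse-friendly), :class:`GeneSetCollection`
(named gene signatures, typically read from GMT) and :class:`ClusterLabels`
(a cell -> cluster assignment).  The readers accept the common plain-text
dialects: 10x-style MatrixMarket triplets with features/barcodes sidecars,
dense CSV/TSV matrices, GMT signature files and two-column cluster tables.
"""
from __future__ import annotations

import gzip
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger("rankgsea")

__all__ = [
    "DataError",
    "ExpressionMatrix",
    "GeneSetCollection",
    "ClusterLabels",
    "read_expression",
    "read_mtx",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clusters",
    "write_clusters",
    "filter_zero_genes",
    "restrict_collection",
]


class DataError(ValueError):
    """Raised for malformed or inconsistent input data (CLI exit code 1)."""


def _first_duplicate(ids: Sequence[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


@dataclass
class ExpressionMatrix:
    """A genes x cells matrix of non-negative expression values.

    Raw or normalised counts are both acceptable: every downstream score
    depends only on within-cell ranks, so any per-cell monotone rescaling
    of the values leaves all results unchanged.
    """

    gene_ids: np.ndarray
    cell_ids: np.ndarray
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        if not sp.issparse(self.values):
            self.values = sp.csr_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsr().astype(float)
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise DataError(f"duplicate {name} identifier: {dup!r}")
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise DataError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        data = self.values.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise DataError("expression values must be finite and >= 0")
        zero_cells = int(np.sum(np.diff(self.values.tocsc().indptr) == 0))
        if zero_cells:
            logger.warning("%d cell(s) have zero total expression; they are retained", zero_cells)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def dense(self) -> np.ndarray:
        return self.values.toarray()

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def subset_genes(self, keep: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(self.gene_ids[keep], self.cell_ids, self.values[keep])


@dataclass
class GeneSetCollection:
    """An ordered mapping of signature name -> ordered list of gene ids."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            dup = _first_duplicate(genes)
            if dup is not None:
                raise DataError(f"duplicate gene {dup!r} in set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}


@dataclass
class ClusterLabels:
    """A categorical cell -> cluster assignment."""

    labels: dict[str, str]

    @property
    def cells(self) -> list[str]:
        return list(self.labels)

    @property
    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.labels.values():
            seen.setdefault(c, None)
        return list(seen)

    def members(self, cluster: str) -> list[str]:
        return [cell for cell, c in self.labels.items() if c == cluster]

    def validate_against(self, m: ExpressionMatrix) -> None:
        known = set(m.cell_ids)
        missing = [c for c in self.labels if c not in known]
        if missing:
            raise DataError(f"labelled cell {missing[0]!r} not present in the expression matrix")


# ---------------------------------------------------------------------------
# expression matrix I/O


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_column(path: Path) -> list[str]:
    ids = []
    with _open_maybe_gzip(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def _resolve_sidecar(directory: Path, names: Sequence[str]) -> Path:
    for name in names:
        for cand in (directory / name, directory / (name + ".gz")):
            if cand.exists():
                return cand
    raise FileNotFoundError(f"none of {names} found in {directory}")


def read_mtx(matrix_path: os.PathLike | str, features_path: os.PathLike | str,
             barcodes_path: os.PathLike | str, transpose: bool = False) -> ExpressionMatrix:
    """Read a MatrixMarket triplet plus features/barcodes sidecars.

    The on-disk 1-based coordinates become 0-based internal positions.  With
    ``transpose=True`` the triplet is interpreted as cells x genes.
    """
    matrix_path = Path(matrix_path)
    if not matrix_path.exists():
        raise FileNotFoundError(str(matrix_path))
    mat = sp.coo_matrix(mmread(_open_maybe_gzip(matrix_path)))
    if transpose:
        mat = mat.T
    genes = _read_id_column(Path(features_path))
    cells = _read_id_column(Path(barcodes_path))
    if mat.shape != (len(genes), len(cells)):
        raise DataError(
            f"MTX header declares shape {mat.shape} but sidecars list "
            f"{len(genes)} features and {len(cells)} barcodes"
        )
    return ExpressionMatrix(np.array(genes, dtype=object), np.array(cells, dtype=object), mat.tocsr())


def read_expression(path: os.PathLike | str, format: str = "auto",
                    transpose: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from ``mtx10x`` (a directory), CSV or TSV.

    CSV/TSV files carry gene ids in the first column and cell ids in the
    header.  ``transpose=True`` flips a cells x genes file into the internal
    genes x cells orientation.
    """
    path = Path(path)
    if format == "auto":
        if path.is_dir():
            format = "mtx10x"
        elif path.suffix in (".csv",):
            format = "csv"
        else:
            format = "tsv"
    if format == "mtx10x":
        directory = path if path.is_dir() else path.parent
        matrix = path if path.is_file() else _resolve_sidecar(directory, ["matrix.mtx"])
        features = _resolve_sidecar(directory, ["features.tsv", "genes.tsv"])
        barcodes = _resolve_sidecar(directory, ["barcodes.tsv"])
        return read_mtx(matrix, features, barcodes, transpose=transpose)
    if format in ("csv", "tsv"):
        if not path.exists():
            raise FileNotFoundError(str(path))
        df = pd.read_csv(path, sep="," if format == "csv" else "\t", index_col=0)
        if transpose:
            df = df.T
        return ExpressionMatrix(
            np.array(df.index.astype(str), dtype=object),
            np.array(df.columns.astype(str), dtype=object),
            sp.csr_matrix(df.to_numpy(dtype=float)),
        )
    raise ValueError(f"unknown expression format {format!r}; expected mtx10x, csv or tsv")


def write_expression(m: ExpressionMatrix, path: os.PathLike | str, format: str = "mtx10x") -> None:
    """Write a matrix back out in one of the dialects :func:`read_expression` reads."""
    path = Path(path)
    if format == "mtx10x":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(m.values))
        (path / "features.tsv").write_text("".join(f"{g}\n" for g in m.gene_ids))
        (path / "barcodes.tsv").write_text("".join(f"{c}\n" for c in m.cell_ids))
    elif format in ("csv", "tsv"):
        df = pd.DataFrame(m.dense(), index=m.gene_ids, columns=m.cell_ids)
        df.to_csv(path, sep="," if format == "csv" else "\t")
    else:
        raise ValueError(f"unknown expression format {format!r}")


# ---------------------------------------------------------------------------
# gene sets


def read_gmt(path: os.PathLike | str) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name description gene gene ...``.

    Set order and within-set gene order follow the file.  Duplicate genes
    within a set are dropped (first occurrence kept) with a warning; a
    duplicate set name or a line with fewer than three fields is an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with _open_maybe_gzip(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has {len(fields)} field(s), expected >= 3")
            name, desc, *genes = fields
            if name in sets:
                raise DataError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            genes = [g for g in genes if g]
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning("set %r: dropped %d duplicate gene(s)", name, len(genes) - len(unique))
            sets[name] = unique
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(c: GeneSetCollection, path: os.PathLike | str) -> None:
    with open(path, "w") as fh:
        for name, genes in c.sets.items():
            desc = c.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *genes]) + "\n")


# ---------------------------------------------------------------------------
# cluster labels


def read_clusters(path: os.PathLike | str) -> ClusterLabels:
    """Read a two-column TSV with header ``cell<TAB>cluster``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["cell", "cluster"]:
        raise DataError(f"{path}: expected header 'cell\\tcluster', got {list(df.columns[:2])}")
    dup = _first_duplicate(df["cell"].tolist())
    if dup is not None:
        raise DataError(f"{path}: duplicate cell id {dup!r}")
    return ClusterLabels(dict(zip(df["cell"], df["cluster"])))


def write_clusters(labels: ClusterLabels, path: os.PathLike | str) -> None:
    pd.DataFrame({"cell": list(labels.labels), "cluster": list(labels.labels.values())}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# cleaning


def filter_zero_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Drop genes that are zero in every cell; gene order otherwise preserved."""
    per_gene = np.asarray(np.diff(m.values.indptr))  # csr: nonzeros per gene row
    keep = per_gene > 0
    if not keep.any():
        raise DataError("matrix empty after filtering")
    if keep.all():
        return m
    logger.info("filter_zero_genes: removed %d all-zero gene(s)", int((~keep).sum()))
    return m.subset_genes(keep)


def restrict_collection(c: GeneSetCollection, m: ExpressionMatrix,
                        min_size: int = 5, max_size: int = 500) -> GeneSetCollection:
    """Intersect each set with the matrix genes and apply size bounds.

    Sets whose intersection falls outside ``[min_size, max_size]`` are
    dropped; matching is exact case-sensitive string equality.
    """
    present = set(m.gene_ids)
    kept: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    dropped = 0
    for name, genes in c.sets.items():
        inter = [g for g in genes if g in present]
        if min_size <= len(inter) <= max_size:
            kept[name] = inter
            descriptions[name] = c.descriptions.get(name, "na")
        else:
            dropped += 1
    if dropped:
        logger.info("restrict_collection: dropped %d of %d set(s) outside [%d, %d]",
                    dropped, len(c), min_size, max_size)
    if not kept:
        raise DataError("no gene set survives restriction to the matrix")
    return GeneSetCollection(kept, descriptions)
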