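"""Six rank-based per-cell gene-set scoring methods.

Each scorer maps an expression matrix and a gene-set collection to a
gene-set x cell :class:`ScoreMatrix`.  All six depend only on each cell's
within-cell expression ranks:

* **AUCell** — normalised area under the recovery curve restricted to the
  top fraction (default 5%) of each cell's ranked genes.
* **UCell** — Mann–Whitney U statistic on ranks capped at a maximum
  (default 1500) to discount the uninformative dropout tail.
* **singscore** — min–max normalised mean rank of the set's genes.
* **ssGSEA** — single-sample running-sum enrichment (weighted in-set vs
  uniform out-of-set empirical CDF), without any across-cell range
  normalisation so that each cell's score stands on its own.
* **JASMINE** — mean of a scaled rank-mean component (computed among
  expressed genes only) and a scaled odds-ratio component contrasting
  the set's expression detection against the background.
* **Viper-style aREA** — mean standard-normal quantile of the set genes'
  rank positions, scaled by sqrt(set size) into a normalised enrichment
  score.  With unsigned gene sets (every member mode +1, weight 1) the
  three-tailed combination degenerates to this two-tailed term.

AUCell, UCell, singscore and JASMINE scores lie in [0, 1]; ssGSEA and
Viper scores are unbounded reals.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .io_core import DataError, ExpressionMatrix, GeneSetCollection
from .ranking import rank_matrix

logger = logging.getLogger("rankgsea")

METHODS = ("AUCell", "UCell", "singscore", "ssgsea", "jasmine", "viper")

__all__ = ["METHODS", "ScoringParams", "ScoreMatrix", "score_all", "write_scores", "read_scores",
           "score_aucell", "score_ucell", "score_singscore", "score_ssgsea",
           "score_jasmine", "score_viper"]


@dataclass
class ScoringParams:
    """Method parameters, recorded alongside every score matrix.

    ``aucell_top_fraction``: fraction of each cell's ranked genes that the
    AUCell recovery curve integrates over (0 < f <= 1).
    ``ucell_max_rank``: rank cap for UCell (ranks beyond it collapse to
    cap + 1).
    ``ssgsea_alpha``: weight exponent on the rank value in the ssGSEA
    running sum (alpha = 0 weights all positions equally).
    ``jasmine_enrichment``: enrichment component of JASMINE, ``oddsratio``
    or ``likelihood``.
    ``ties``: tie policy handed to the ranking layer; ``seed`` feeds the
    ``random`` tie policy only.
    """

    aucell_top_fraction: float = 0.05
    ucell_max_rank: int = 1500
    ssgsea_alpha: float = 0.25
    jasmine_enrichment: str = "oddsratio"
    ties: str = "average"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.aucell_top_fraction <= 1:
            raise ValueError("aucell_top_fraction must be in (0, 1]")
        if self.ucell_max_rank < 2:
            raise ValueError("ucell_max_rank must be >= 2")
        if self.ssgsea_alpha < 0:
            raise ValueError("ssgsea_alpha must be >= 0")
        if self.jasmine_enrichment not in ("oddsratio", "likelihood"):
            raise ValueError("jasmine_enrichment must be 'oddsratio' or 'likelihood'")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScoreMatrix:
    """Per-method gene-set x cell score matrix with provenance params."""

    method: str
    set_names: list[str]
    cell_ids: list[str]
    scores: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (len(self.set_names), len(self.cell_ids)):
            raise ValueError("score matrix shape does not match set/cell names")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError(f"{self.method}: non-finite score produced")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.set_names, columns=self.cell_ids)


# ---------------------------------------------------------------------------
# shared plumbing


def _set_index(m: ExpressionMatrix, c: GeneSetCollection) -> dict[str, np.ndarray]:
    gpos = m.gene_index()
    out: dict[str, np.ndarray] = {}
    for name, genes in c.sets.items():
        missing = [g for g in genes if g not in gpos]
        if missing:
            raise DataError(
                f"set {name!r} contains gene {missing[0]!r} absent from the matrix; "
                "restrict the collection first"
            )
        if not genes:
            raise DataError(f"set {name!r} is empty")
        out[name] = np.fromiter((gpos[g] for g in genes), dtype=int, count=len(genes))
    return out


class _RankCache:
    """Compute the dense matrix and its ranks once per score_all call."""

    def __init__(self, m: ExpressionMatrix, p: ScoringParams):
        self.X = m.dense()
        self.cell_ids = [str(c) for c in m.cell_ids]
        self.rank_desc, self.rank_asc, self.n_expressed = rank_matrix(
            self.X, ties=p.ties, seed=p.seed, cell_ids=self.cell_ids
        )
        self.n_genes = self.X.shape[0]


def _get_cache(m: ExpressionMatrix, p: ScoringParams, cache: _RankCache | None) -> _RankCache:
    return cache if cache is not None else _RankCache(m, p)


# ---------------------------------------------------------------------------
# the six scorers


def score_aucell(m: ExpressionMatrix, c: GeneSetCollection, p: ScoringParams | None = None,
                 _cache: _RankCache | None = None) -> ScoreMatrix:
    """Recovery-curve AUC over the top ``aucell_top_fraction`` of each cell's ranks.

    The raw score is the cumulative count of set genes recovered at list
    depths 1..L (L = ceil(fraction * n_genes)); it is divided by its
    maximum attainable value (the set packing the top ranks), pinning the
    score to [0, 1] with 1 = perfect enrichment.
    """
    p = p or ScoringParams()
    rc = _get_cache(m, p, _cache)
    idx = _set_index(m, c)
    L = ceil(p.aucell_top_fraction * rc.n_genes)
    if L < 1:
        raise DataError("top fraction too small for n_genes")
    scores = np.empty((len(idx), len(rc.cell_ids)))
    depths = np.arange(1, L + 1)
    for i, (name, gi) in enumerate(idx.items()):
        r = rc.rank_desc[gi]  # n_set x cells
        # a gene at rank r is recovered at depths ceil(r)..L
        contrib = np.clip(L - np.ceil(r) + 1, 0, None)
        raw = contrib.sum(axis=0)
        max_raw = np.minimum(depths, len(gi)).sum()
        scores[i] = raw / max_raw
    return ScoreMatrix("AUCell", list(idx), rc.cell_ids, scores, p.as_dict())


def score_ucell(m: ExpressionMatrix, c: GeneSetCollection, p: ScoringParams | None = None,
                _cache: _RankCache | None = None) -> ScoreMatrix:
    """Mann–Whitney U score on descending ranks capped at ``ucell_max_rank``."""
    p = p or ScoringParams()
    rc = _get_cache(m, p, _cache)
    idx = _set_index(m, c)
    r_max = p.ucell_max_rank
    scores = np.empty((len(idx), len(rc.cell_ids)))
    clamped = False
    for i, (name, gi) in enumerate(idx.items()):
        n_s = len(gi)
        r_star = np.minimum(rc.rank_desc[gi], r_max + 1)
        u = r_star.sum(axis=0) - n_s * (n_s + 1) / 2
        s = 1.0 - u / (n_s * r_max)
        clamped = clamped or bool((s < 0).any())
        scores[i] = np.maximum(s, 0.0)
    if clamped:
        logger.info("UCell: scores below 0 clamped (set size close to the rank cap)")
    return ScoreMatrix("UCell", list(idx), rc.cell_ids, scores, p.as_dict())


def score_singscore(m: ExpressionMatrix, c: GeneSetCollection, p: ScoringParams | None = None,
                    _cache: _RankCache | None = None) -> ScoreMatrix:
    """Min–max normalised mean ascending rank of the set genes (1 = most expressed)."""
    p = p or ScoringParams()
    rc = _get_cache(m, p, _cache)
    idx = _set_index(m, c)
    n = rc.n_genes
    scores = np.empty((len(idx), len(rc.cell_ids)))
    for i, (name, gi) in enumerate(idx.items()):
        n_s = len(gi)
        if n_s == n:
            raise DataError(f"set {name!r} covers the whole genome; singscore undefined")
        meanrank = rc.rank_asc[gi].mean(axis=0)
        min_pos = (n_s + 1) / 2
        max_pos = (2 * n - n_s + 1) / 2
        scores[i] = (meanrank - min_pos) / (max_pos - min_pos)
    return ScoreMatrix("singscore", list(idx), rc.cell_ids, scores, p.as_dict())


def score_ssgsea(m: ExpressionMatrix, c: GeneSetCollection, p: ScoringParams | None = None,
                 _cache: _RankCache | None = None) -> ScoreMatrix:
    """Single-sample running-sum enrichment without across-cell normalisation.

    Genes are ordered per cell by descending expression (ties broken by
    gene order, deterministically).  At list position i the in-set CDF is
    weighted by the rank value raised to ``ssgsea_alpha``; the enrichment
    score is the sum over all positions of (in-set CDF - out-of-set CDF).
    No division by the across-cell score range is applied, so each cell's
    score is independent of the cohort.
    """
    p = p or ScoringParams()
    rc = _get_cache(m, p, _cache)
    idx = _set_index(m, c)
    n, n_cells = rc.X.shape
    # work on cells x genes rows: each cell's running sum is computed over
    # contiguous memory, so a cell's score is bit-identical in any cohort
    order = np.argsort(-np.ascontiguousarray(rc.X.T), axis=1, kind="stable")
    w = (n - np.arange(n, dtype=float)) ** p.ssgsea_alpha  # weight at position i
    scores = np.empty((len(idx), n_cells))
    member = np.zeros(n, dtype=bool)
    for i, (name, gi) in enumerate(idx.items()):
        n_s = len(gi)
        if n_s == n:
            raise DataError(f"set {name!r} covers the whole genome; ssGSEA undefined")
        member[:] = False
        member[gi] = True
        in_mask = member[order]  # cells x positions
        win = w * in_mask
        p_in = np.cumsum(win, axis=1) / win.sum(axis=1, keepdims=True)
        p_out = np.cumsum(~in_mask, axis=1) / (n - n_s)
        scores[i] = (p_in - p_out).sum(axis=1)
    return ScoreMatrix("ssgsea", list(idx), rc.cell_ids, scores, p.as_dict())


def jasmine_components(m: ExpressionMatrix, c: GeneSetCollection, p: ScoringParams | None = None,
                       _cache: _RankCache | None = None):
    """Unscaled JASMINE components, independent of the cell cohort.

    Returns ``(set_names, cell_ids, rank_mean, enrichment)`` where
    ``rank_mean`` is the mean descending rank of the expressed set genes
    divided by the number of expressed genes (0.5, the null value, when no
    set gene is expressed) and ``enrichment`` is the odds ratio (or
    likelihood ratio) of the set's detection contingency table, with a
    Haldane correction of +0.5 per contingency cell whenever any count is
    zero.
    """
    p = p or ScoringParams()
    rc = _get_cache(m, p, _cache)
    idx = _set_index(m, c)
    n = rc.n_genes
    n_expr = rc.n_expressed.astype(float)
    empty_cells = n_expr == 0
    if empty_cells.any():
        logger.warning("jasmine: %d cell(s) express no genes; components set to null values",
                       int(empty_cells.sum()))
    rank_mean = np.empty((len(idx), len(rc.cell_ids)))
    enrich = np.empty_like(rank_mean)
    for i, (name, gi) in enumerate(idx.items()):
        n_s = len(gi)
        expressed = rc.X[gi] > 0  # n_set x cells
        a = expressed.sum(axis=0).astype(float)  # set genes detected
        # zeros tie at the bottom, so an expressed gene's descending rank among
        # expressed genes equals its descending rank among all genes
        rank_sum = (rc.rank_desc[gi] * expressed).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rm = rank_sum / a / n_expr
        rm = np.where((a == 0) | empty_cells, 0.5, rm)
        b = n_s - a            # set genes not detected
        cc = n_expr - a        # detected background genes
        d = (n - n_s) - cc     # undetected background genes
        table = np.stack([a, b, cc, d])
        haldane = (table == 0).any(axis=0)
        table = table + 0.5 * haldane
        if p.jasmine_enrichment == "oddsratio":
            enrich[i] = (table[0] * table[3]) / (table[1] * table[2])
        else:  # likelihood ratio of detection given set membership
            enrich[i] = (table[0] * (table[2] + table[3])) / (table[2] * (table[0] + table[1]))
        rank_mean[i] = rm
    return list(idx), rc.cell_ids, rank_mean, enrich


def _minmax(x: np.ndarray) -> np.ndarray:
    lo = x.min(axis=1, keepdims=True)
    hi = x.max(axis=1, keepdims=True)
    span = hi - lo
    out = np.full_like(x, 0.5)  # no variation across cells -> neutral value
    np.divide(x - lo, span, out=out, where=span > 0)
    return out


def score_jasmine(m: ExpressionMatrix, c: GeneSetCollection, p: ScoringParams | None = None,
                  _cache: _RankCache | None = None) -> ScoreMatrix:
    """JASMINE score: mean of the min–max scaled rank-mean and enrichment components.

    The final min–max scaling runs across the scored cells, so unlike the
    other five methods the *final* JASMINE score depends on the cohort;
    :func:`jasmine_components` exposes the cohort-independent parts.
    """
    p = p or ScoringParams()
    set_names, cell_ids, rank_mean, enrich = jasmine_components(m, c, p, _cache=_cache)
    scaled_rm = _minmax(1.0 - rank_mean)  # high score = set ranked high
    scaled_or = _minmax(enrich)
    return ScoreMatrix("jasmine", set_names, cell_ids, (scaled_rm + scaled_or) / 2, p.as_dict())


def score_viper(m: ExpressionMatrix, c: GeneSetCollection, p: ScoringParams | None = None,
                _cache: _RankCache | None = None) -> ScoreMatrix:
    """aREA-style normalised enrichment score from within-cell rank quantiles.

    Each gene's ascending rank maps to the interior quantile
    (rank - 0.5)/n and then through the standard-normal quantile function;
    the set's enrichment is the mean of these values times sqrt(set size).
    With unsigned sets (all modes +1, unit weight) the three-tailed aREA
    combination reduces to this two-tailed term.
    """
    p = p or ScoringParams()
    rc = _get_cache(m, p, _cache)
    idx = _set_index(m, c)
    q = (rc.rank_asc - 0.5) / rc.n_genes
    t2 = np.ascontiguousarray(ndtri(q).T)  # cells x genes: per-cell contiguous
    scores = np.empty((len(idx), len(rc.cell_ids)))
    for i, (name, gi) in enumerate(idx.items()):
        # reduce along a contiguous axis so each cell's mean is computed by
        # the same arithmetic stream in any cohort (bit-identical scores);
        # note t2[:, gi] alone would be F-ordered and reduce differently
        sub = np.ascontiguousarray(t2[:, gi])
        scores[i] = sub.mean(axis=1) * np.sqrt(len(gi))
    return ScoreMatrix("viper", list(idx), rc.cell_ids, scores, p.as_dict())


_DISPATCH = {
    "AUCell": score_aucell,
    "UCell": score_ucell,
    "singscore": score_singscore,
    "ssgsea": score_ssgsea,
    "jasmine": score_jasmine,
    "viper": score_viper,
}
_ALIASES = {name.lower(): name for name in METHODS}


def resolve_method(name: str) -> str:
    canonical = _ALIASES.get(name.lower())
    if canonical is None:
        raise ValueError(f"unknown scoring method {name!r}; valid: {', '.join(METHODS)}")
    return canonical


def score_all(m: ExpressionMatrix, c: GeneSetCollection, p: ScoringParams | None = None,
              methods=METHODS) -> list[ScoreMatrix]:
    """Run the requested scorers; all outputs share set and cell ordering."""
    p = p or ScoringParams()
    if not methods:
        raise ValueError("no scoring method requested")
    resolved = [resolve_method(name) for name in methods]
    cache = _RankCache(m, p)
    return [_DISPATCH[name](m, c, p, _cache=cache) for name in resolved]


# ---------------------------------------------------------------------------
# persistence


def write_scores(scores: list[ScoreMatrix], outdir) -> None:
    """One TSV per method (rows = gene sets, columns = cells) + params sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = {}
    for s in scores:
        s.to_frame().to_csv(outdir / f"scores_{s.method}.tsv", sep="\t")
        params[s.method] = s.params
    (outdir / "scoring_params.json").write_text(json.dumps(params, indent=2))


def read_scores(outdir) -> list[ScoreMatrix]:
    outdir = Path(outdir)
    params_path = outdir / "scoring_params.json"
    params = json.loads(params_path.read_text()) if params_path.exists() else {}
    out = []
    for path in sorted(outdir.glob("scores_*.tsv")):
        method = path.stem.removeprefix("scores_")
        df = pd.read_csv(path, sep="\t", index_col=0)
        out.append(ScoreMatrix(method, [str(i) for i in df.index],
                               [str(c) for c in df.columns], df.to_numpy(),
                               params.get(method, {})))
    if not out:
        raise FileNotFoundError(f"no scores_*.tsv found in {outdir}")
    return out
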