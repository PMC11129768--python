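import numpy as np
import pytest

from rankgsea import ScoringParams, restrict_collection, score_all
from rankgsea.synthetic import SimConfig, simulate

SMALL_CFG = SimConfig(n_genes=300, n_cells_per_cluster=30, n_clusters=3,
                      n_sets=8, set_size=15, n_planted=2, fold_change=4.0, seed=7)


@pytest.fixture(scope="session")
def small_sim():
    """A small planted dataset shared by the module tests (module-scale speed)."""
    return simulate(SMALL_CFG)


@pytest.fixture(scope="session")
def small_scores(small_sim):
    m, labels, sets, truth = small_sim
    collection = restrict_collection(sets, m, min_size=5, max_size=500)
    return score_all(m, collection, ScoringParams())


@pytest.fixture(scope="session")
def small_diff(small_sim, small_scores):
    from rankgsea import differential_all
    _, labels, _, _ = small_sim
    return differential_all(small_scores, labels)


def descending_matrix(n_genes: int, n_cells: int = 1) -> np.ndarray:
    """Distinct values so that gene i has rank_desc i+1 in every cell."""
    return np.tile(np.arange(n_genes, 0, -1, dtype=float)[:, None], (1, n_cells))
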