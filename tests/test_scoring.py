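"""The six scorers: worked micro-examples, brute-force oracles, invariants."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtri

from rankgsea.io_core import DataError, ExpressionMatrix, GeneSetCollection
from rankgsea.scoring import (METHODS, ScoringParams, jasmine_components, score_all,
                              score_aucell, score_jasmine, score_singscore,
                              score_ssgsea, score_ucell, score_viper)
from conftest import descending_matrix


def make_matrix(values):
    values = np.asarray(values, dtype=float)
    genes = [f"g{i}" for i in range(values.shape[0])]
    cells = [f"c{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes, cells, values)


def sets_at_desc_ranks(ranks):
    """On a descending_matrix, gene g{i} has rank_desc i+1."""
    return GeneSetCollection({"S": [f"g{r - 1}" for r in ranks]})


class TestAUCell:
    @pytest.mark.parametrize("ranks,expected", [
        ({1, 2}, 1.0),           # set fills the top ranks -> maximal recovery
        ({4, 5}, 3.0 / 9.0),     # brute-force recovery-curve sum: H=(0,0,0,1,2)
        ({50, 60}, 0.0),         # set entirely below the top 5%
    ])
    def test_worked_examples(self, ranks, expected):
        m = make_matrix(descending_matrix(100))
        s = score_aucell(m, sets_at_desc_ranks(ranks), ScoringParams())
        assert s.scores[0, 0] == pytest.approx(expected)

    def test_matches_bruteforce_recovery_curve(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.integers(1, 1000, size=(200, 1)).astype(float))
        genes = list(rng.choice(200, size=12, replace=False))
        c = GeneSetCollection({"S": [f"g{i}" for i in genes]})
        p = ScoringParams(aucell_top_fraction=0.1)
        s = score_aucell(m, c, p)
        # straight-line oracle: walk the ranked list, count recovered set genes
        order = np.argsort(-m.dense()[:, 0], kind="stable")
        member = np.isin(order, genes)
        L = 20
        raw = sum(int(member[:x].sum()) for x in range(1, L + 1))
        max_raw = sum(min(x, 12) for x in range(1, L + 1))
        assert s.scores[0, 0] == pytest.approx(raw / max_raw)


class TestUCell:
    @pytest.mark.parametrize("ranks,expected", [
        ({1, 2, 3}, 1.0),
        ({10, 20, 30}, 1 - 54 / 4500),       # U = 54 on the capped ranks
        ({1600, 1700, 1800}, 1 - 4497 / 4500),  # all ranks beyond the cap -> r* = 1501
    ])
    def test_worked_examples(self, ranks, expected):
        m = make_matrix(descending_matrix(2000))
        s = score_ucell(m, sets_at_desc_ranks(ranks), ScoringParams())
        assert s.scores[0, 0] == pytest.approx(expected)

    def test_cross_check_against_mannwhitney_u(self):
        """U recomputed independently from the capped rank definition."""
        rng = np.random.default_rng(1)
        m = make_matrix(rng.integers(0, 50, size=(400, 1)).astype(float))
        genes = list(rng.choice(400, size=10, replace=False))
        c = GeneSetCollection({"S": [f"g{i}" for i in genes]})
        p = ScoringParams(ucell_max_rank=100)
        s = score_ucell(m, c, p)
        from scipy.stats import rankdata
        capped = np.minimum(rankdata(-m.dense()[:, 0]), 101)[genes]
        u = capped.sum() - 10 * 11 / 2
        assert s.scores[0, 0] == pytest.approx(max(0.0, 1 - u / (10 * 100)))


class TestSingscore:
    @pytest.mark.parametrize("asc_ranks,expected", [
        ({9, 10}, 1.0), ({1, 2}, 0.0), ({3, 8}, 0.5),
    ])
    def test_worked_examples(self, asc_ranks, expected):
        # values ascending: gene g{i} has rank_asc i+1
        m = make_matrix(np.arange(1, 11, dtype=float)[:, None])
        c = GeneSetCollection({"S": [f"g{r - 1}" for r in asc_ranks]})
        s = score_singscore(m, c, ScoringParams())
        assert s.scores[0, 0] == pytest.approx(expected)

    def test_whole_genome_set_rejected(self):
        m = make_matrix(np.arange(1, 5, dtype=float)[:, None])
        c = GeneSetCollection({"S": [f"g{i}" for i in range(4)]})
        with pytest.raises(DataError, match="whole genome"):
            score_singscore(m, c, ScoringParams())


def ssgsea_oracle(values, members, alpha):
    """Straight-line running sum over the descending-ordered gene list."""
    order = sorted(range(len(values)), key=lambda i: (-values[i], i))
    n, n_s = len(values), len(members)
    weights = {g: (n - pos) ** alpha for pos, g in enumerate(order)}
    total_in = sum(weights[g] for g in members)
    es, p_in, p_out = 0.0, 0.0, 0.0
    for g in order:
        if g in members:
            p_in += weights[g] / total_in
        else:
            p_out += 1.0 / (n - n_s)
        es += p_in - p_out
    return es


class TestSsgsea:
    def test_single_top_gene_gives_es_two(self):
        m = make_matrix(np.array([[9.0], [3.0], [2.0], [1.0]]))
        s = score_ssgsea(m, GeneSetCollection({"S": ["g0"]}), ScoringParams())
        assert s.scores[0, 0] == pytest.approx(2.0)  # diffs (1, 2/3, 1/3, 0)

    def test_interleaved_alpha_zero(self):
        # set at descending positions {2, 4} of n=4 with alpha=0
        m = make_matrix(np.array([[4.0], [3.0], [2.0], [1.0]]))
        c = GeneSetCollection({"S": ["g1", "g3"]})
        s = score_ssgsea(m, c, ScoringParams(ssgsea_alpha=0.0))
        assert s.scores[0, 0] == pytest.approx(-1.0)

    def test_matches_bruteforce_running_sum(self):
        m = make_matrix(np.array([[4.0], [3.0], [2.0], [1.0]]))
        c = GeneSetCollection({"S": ["g1", "g2", "g3"]})  # positions {2,3,4}
        s = score_ssgsea(m, c, ScoringParams())
        assert s.scores[0, 0] == pytest.approx(ssgsea_oracle([4, 3, 2, 1], {1, 2, 3}, 0.25))

    def test_bruteforce_oracle_on_random_cells(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 30, size=(50, 3)).astype(float)
        m = make_matrix(X)
        genes = list(rng.choice(50, size=8, replace=False))
        c = GeneSetCollection({"S": [f"g{i}" for i in genes]})
        s = score_ssgsea(m, c, ScoringParams())
        for j in range(3):
            assert s.scores[0, j] == pytest.approx(
                ssgsea_oracle(list(X[:, j]), set(genes), 0.25))


def jasmine_oracle(X, members):
    """Independent straight-line rank-mean and contingency computation."""
    n, n_cells = X.shape
    rm, oddsratio = [], []
    for j in range(n_cells):
        col = X[:, j]
        expressed = [i for i in range(n) if col[i] > 0]
        in_expr = [i for i in expressed if i in members]
        if in_expr:
            # descending rank among expressed genes, average ties
            from scipy.stats import rankdata
            sub_ranks = rankdata([-col[i] for i in expressed])
            rank_of = dict(zip(expressed, sub_ranks))
            rm.append(np.mean([rank_of[i] for i in in_expr]) / len(expressed))
        else:
            rm.append(0.5)
        a = len(in_expr)
        b = len(members) - a
        cexp = len(expressed) - a
        d = (n - len(members)) - cexp
        if min(a, b, cexp, d) == 0:
            a, b, cexp, d = a + 0.5, b + 0.5, cexp + 0.5, d + 0.5
        oddsratio.append(a * d / (b * cexp))
    return np.array(rm), np.array(oddsratio)


class TestJasmine:
    def three_cell_toy(self):
        X = np.array([
            [5.0, 0.0, 1.0],
            [3.0, 2.0, 0.0],
            [0.0, 4.0, 0.0],
            [1.0, 1.0, 2.0],
            [2.0, 0.0, 3.0],
            [0.0, 6.0, 4.0],
        ])
        return make_matrix(X), GeneSetCollection({"S": ["g0", "g1"]}), {0, 1}

    def test_components_match_straightline_oracle(self):
        m, c, members = self.three_cell_toy()
        _, _, rank_mean, enrich = jasmine_components(m, c, ScoringParams())
        rm_oracle, or_oracle = jasmine_oracle(m.dense(), members)
        assert rank_mean[0] == pytest.approx(rm_oracle)
        assert enrich[0] == pytest.approx(or_oracle)

    def test_final_score_is_mean_of_scaled_components(self):
        m, c, members = self.three_cell_toy()
        s = score_jasmine(m, c, ScoringParams())
        rm, orr = jasmine_oracle(m.dense(), members)
        def minmax(x):
            return (x - x.min()) / (x.max() - x.min())
        expected = (minmax(1 - rm) + minmax(orr)) / 2
        assert s.scores[0] == pytest.approx(expected)
        assert np.all((s.scores >= 0) & (s.scores <= 1))

    def test_identical_cells_get_identical_scores(self):
        X = np.array([[3.0, 3.0, 1.0], [1.0, 1.0, 0.0], [0.0, 0.0, 5.0], [2.0, 2.0, 2.0]])
        m = make_matrix(X)
        s = score_jasmine(m, GeneSetCollection({"S": ["g0", "g1"]}), ScoringParams())
        assert s.scores[0, 0] == s.scores[0, 1]

    def test_fully_detected_set_has_top_odds_ratio(self):
        # cell 0: every set gene expressed, every other gene not
        X = np.array([[2.0, 1.0], [3.0, 0.0], [0.0, 2.0], [0.0, 3.0]])
        m = make_matrix(X)
        _, _, _, enrich = jasmine_components(
            m, GeneSetCollection({"S": ["g0", "g1"]}), ScoringParams())
        assert enrich[0, 0] == enrich[0].max()

    def test_empty_cell_gets_null_components(self, caplog):
        X = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 0.0]])
        with caplog.at_level("WARNING", logger="rankgsea"):
            _, _, rank_mean, _ = jasmine_components(
                make_matrix(X), GeneSetCollection({"S": ["g0"]}), ScoringParams())
        assert rank_mean[0, 1] == 0.5
        assert any("express no genes" in r.message for r in caplog.records)


class TestViper:
    def test_symmetric_set_scores_zero(self):
        m = make_matrix(np.arange(1, 101, dtype=float)[:, None])
        # rank_asc pairs summing to n+1: quantiles mirror around 0.5
        c = GeneSetCollection({"S": ["g0", "g99", "g9", "g90"]})
        s = score_viper(m, c, ScoringParams())
        assert s.scores[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_single_top_gene_hits_normal_quantile(self):
        m = make_matrix(np.arange(1, 101, dtype=float)[:, None])
        s = score_viper(m, GeneSetCollection({"S": ["g99"]}), ScoringParams())
        assert s.scores[0, 0] == pytest.approx(2.576, abs=1e-3)  # Phi^-1(0.995)

    def test_identical_cells_identical_scores(self):
        m = make_matrix(np.tile(np.array([4.0, 1.0, 3.0, 2.0])[:, None], (1, 5)))
        s = score_viper(m, GeneSetCollection({"S": ["g0", "g2"]}), ScoringParams())
        assert np.ptp(s.scores[0]) == 0

    def test_null_mean_zero_variance_one(self):
        """NES over random sets on noise: mean ~ 0, variance ~ 1 by construction."""
        rng = np.random.default_rng(8)
        m = make_matrix(rng.random((500, 40)))
        sets = {f"S{k}": [f"g{i}" for i in rng.choice(500, 20, replace=False)]
                for k in range(30)}
        s = score_viper(m, GeneSetCollection(sets), ScoringParams())
        assert abs(s.scores.mean()) < 0.05
        assert 0.8 < s.scores.var() < 1.05


class TestScoreAll:
    def test_all_methods_share_shape_and_order(self, small_sim, small_scores):
        assert [s.method for s in small_scores] == list(METHODS)
        shapes = {s.scores.shape for s in small_scores}
        assert len(shapes) == 1
        names = {tuple(s.set_names) for s in small_scores}
        cells = {tuple(s.cell_ids) for s in small_scores}
        assert len(names) == 1 and len(cells) == 1

    def test_single_method_and_aliases(self, small_sim):
        m, _, sets, _ = small_sim
        from rankgsea import restrict_collection
        c = restrict_collection(sets, m)
        out = score_all(m, c, ScoringParams(), methods=["ucell"])
        assert len(out) == 1 and out[0].method == "UCell"

    def test_empty_and_unknown_methods_rejected(self, small_sim):
        m, _, sets, _ = small_sim
        from rankgsea import restrict_collection
        c = restrict_collection(sets, m)
        with pytest.raises(ValueError):
            score_all(m, c, methods=[])
        with pytest.raises(ValueError, match="AUCell"):
            score_all(m, c, methods=["gsva"])

    def test_bounded_methods_stay_in_unit_interval(self, small_scores):
        for s in small_scores:
            if s.method in ("AUCell", "UCell", "singscore", "jasmine"):
                assert s.scores.min() >= 0 and s.scores.max() <= 1, s.method

    def test_planted_set_discriminates_in_every_method(self, small_sim, small_scores):
        """Mean score of a planted set is highest in its target cluster."""
        _, labels, _, truth = small_sim
        for s in small_scores:
            frame = s.to_frame()
            for set_name, (target, _) in truth.planted.items():
                means = {cl: frame.loc[set_name, labels.members(cl)].mean()
                         for cl in labels.clusters}
                assert max(means, key=means.get) == target, (s.method, set_name)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_bounded_score_range_property(seed):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 10, size=(40, 6)).astype(float)
    X[rng.random(X.shape) < 0.3] = 0.0
    X[0] = 1.0  # keep at least one gene expressed everywhere
    m = make_matrix(X)
    genes = rng.choice(40, size=8, replace=False)
    c = GeneSetCollection({"S": [f"g{i}" for i in genes]})
    for scorer in (score_aucell, score_ucell, score_singscore, score_jasmine):
        s = scorer(m, c, ScoringParams())
        assert s.scores.min() >= 0 and s.scores.max() <= 1, scorer.__name__
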