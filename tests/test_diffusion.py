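import math

import numpy as np
import pytest

from helpers import random_connected_graph, solve_rwr
from lion import (DiffusionParams, DiseaseSubnetwork, ScoreVector,
                  column_normalize, diffuse, diffuse_closed_form,
                  rank_lncrnas, uniform_restart)
from lion.exceptions import ConvergenceError, NormalizationError

PATH = frozenset({("A", "B"), ("B", "C")})
PATH_ORDER = ("A", "B", "C")


class TestColumnNormalize:
    def test_path_columns(self):
        W = column_normalize(PATH, PATH_ORDER).W.toarray()
        np.testing.assert_allclose(W[:, 0], [0, 1, 0])
        np.testing.assert_allclose(W[:, 1], [0.5, 0, 0.5])
        np.testing.assert_allclose(W[:, 2], [0, 1, 0])

    def test_single_edge(self):
        W = column_normalize(frozenset({("A", "B")}), ("A", "B")).W.toarray()
        np.testing.assert_allclose(W, [[0, 1], [1, 0]])

    def test_isolated_node_rejected(self):
        with pytest.raises(NormalizationError, match="C"):
            column_normalize(frozenset({("A", "B")}), ("A", "B", "C"))

    def test_columns_stochastic_and_structurally_symmetric(self):
        rng = np.random.default_rng(3)
        edges, order, _ = random_connected_graph(rng, n_max=30)
        W = column_normalize(edges, order).W.toarray()
        np.testing.assert_allclose(W.sum(axis=0), 1.0, atol=1e-12)
        assert ((W > 0) == (W.T > 0)).all()
        assert W.min() >= 0 and W.max() <= 1


class TestUniformRestart:
    def test_two_seeds_of_five(self):
        p0 = uniform_restart({"N1", "N2"}, ("N1", "N2", "N3", "N4", "N5")).p0
        np.testing.assert_allclose(p0, [0.5, 0.5, 0, 0, 0])

    def test_single_seed_is_indicator(self):
        p0 = uniform_restart({"B"}, ("A", "B", "C")).p0
        np.testing.assert_allclose(p0, [0, 1, 0])

    def test_all_nodes_seeded_is_uniform(self):
        p0 = uniform_restart({"A", "B", "C"}, ("A", "B", "C")).p0
        np.testing.assert_allclose(p0, [1 / 3] * 3)

    def test_errors(self):
        with pytest.raises(ValueError):
            uniform_restart(set(), ("A",))
        with pytest.raises(ValueError):
            uniform_restart({"Z"}, ("A", "B"))


# exact fixed points of p = (1-r) W p + r p0 worked out by hand
HAND_CASES = [
    (frozenset({("A", "B")}), ("A", "B"), {"A"}, [2 / 3, 1 / 3]),
    (PATH, PATH_ORDER, {"A"}, [7 / 12, 1 / 3, 1 / 12]),
    # star, center seeded: c = 1.5 l + 1/2 and l = c/6 give c = 2/3, l = 1/9
    (frozenset({("C", "L1"), ("C", "L2"), ("C", "L3")}),
     ("C", "L1", "L2", "L3"), {"C"}, [2 / 3, 1 / 9, 1 / 9, 1 / 9]),
]


class TestDiffuse:
    @pytest.mark.parametrize("edges,order,seeds,expected", HAND_CASES)
    def test_hand_computed_fixed_points(self, edges, order, seeds, expected):
        W = column_normalize(edges, order)
        p0 = uniform_restart(seeds, order)
        tight = DiffusionParams(r=0.5, tol=1e-12)
        assert np.abs(diffuse(W, p0, tight).p - expected).max() < 1e-10
        assert np.abs(diffuse_closed_form(W, p0, 0.5).p - expected).max() < 1e-12

    def test_restart_only_limit_returns_p0(self):
        W = column_normalize(PATH, PATH_ORDER)
        p0 = uniform_restart({"B"}, PATH_ORDER)
        out = diffuse(W, p0, DiffusionParams(r=1.0))
        assert out.iterations == 1
        np.testing.assert_array_equal(out.p, p0.p0)
        np.testing.assert_array_equal(diffuse_closed_form(W, p0, 1.0).p, p0.p0)

    def test_max_iter_exhaustion_raises(self):
        W = column_normalize(PATH, PATH_ORDER)
        p0 = uniform_restart({"A"}, PATH_ORDER)
        with pytest.raises(ConvergenceError):
            diffuse(W, p0, DiffusionParams(tol=1e-15, max_iter=3))

    def test_conservation_every_iteration(self):
        rng = np.random.default_rng(11)
        edges, order, seeds = random_connected_graph(rng, n_max=40)
        W = column_normalize(edges, order)
        p0 = uniform_restart(seeds, order)
        mat = W.W.toarray()
        p = p0.p0.copy()
        for _ in range(50):
            p = 0.5 * (mat @ p) + 0.5 * p0.p0
            assert abs(p.sum() - 1.0) < 1e-12
        out = diffuse(W, p0)
        assert abs(out.p.sum() - 1.0) < 1e-9

    def test_contraction_and_iteration_bound(self):
        params = DiffusionParams(r=0.5, tol=1e-6)
        rng = np.random.default_rng(17)
        edges, order, seeds = random_connected_graph(rng, n_max=40)
        W = column_normalize(edges, order)
        p0 = uniform_restart(seeds, order)
        out = diffuse(W, p0, params)
        for a, b in zip(out.residuals, out.residuals[1:]):
            assert b <= (1 - params.r) * a * (1 + 1e-9)
        bound = math.ceil(math.log(params.tol / 2) / math.log(1 - params.r))
        assert out.iterations <= bound
        # distance to the fixed point also contracts by (1 - r)
        p_inf = diffuse_closed_form(W, p0, params.r).p
        p = p0.p0.copy()
        mat = W.W.toarray()
        for _ in range(30):
            p_next = 0.5 * (mat @ p) + 0.5 * p0.p0
            d_now = np.abs(p - p_inf).sum()
            d_next = np.abs(p_next - p_inf).sum()
            assert d_next <= (1 - params.r) * d_now + 1e-15
            p = p_next

    def test_unreachable_nodes_score_zero_and_seeds_keep_restart_mass(self):
        # two components; diffusion itself runs on any degree>=1 graph
        edges = frozenset({("A", "B"), ("X", "Y")})
        order = ("A", "B", "X", "Y")
        W = column_normalize(edges, order)
        p0 = uniform_restart({"A"}, order)
        out = diffuse(W, p0, DiffusionParams(tol=1e-12))
        assert out.p[2] == 0 and out.p[3] == 0
        assert out.p[0] >= 0.5 * p0.p0[0]

    def test_order_invariance_under_permutation(self):
        rng = np.random.default_rng(23)
        edges, order, seeds = random_connected_graph(rng, n_max=30)
        perm = tuple(np.array(order)[rng.permutation(len(order))])
        params = DiffusionParams(tol=1e-12)
        out1 = diffuse(column_normalize(edges, order),
                       uniform_restart(seeds, order), params)
        out2 = diffuse(column_normalize(edges, perm),
                       uniform_restart(seeds, perm), params)
        lookup = dict(zip(out2.node_order, out2.p))
        reordered = np.array([lookup[n] for n in order])
        np.testing.assert_allclose(out1.p, reordered, atol=1e-12)

    def test_dense_and_sparse_paths_agree(self):
        rng = np.random.default_rng(29)
        edges, order, seeds = random_connected_graph(rng, n_max=50)
        W = column_normalize(edges, order)
        p0 = uniform_restart(seeds, order)
        dense = diffuse(W, p0, dense_threshold=10**6)
        sparse = diffuse(W, p0, dense_threshold=0)
        assert np.abs(dense.p - sparse.p).max() < 1e-12

    def test_any_start_reaches_the_same_fixed_point(self):
        W = column_normalize(PATH, PATH_ORDER)
        p0 = uniform_restart({"A"}, PATH_ORDER)
        p_inf = diffuse_closed_form(W, p0, 0.5).p
        p = np.full(3, 1 / 3)  # uniform start instead of p0
        mat = W.W.toarray()
        for _ in range(60):
            p = 0.5 * (mat @ p) + 0.5 * p0.p0
        np.testing.assert_allclose(p, p_inf, atol=1e-12)


def test_oracle_equivalence_against_independent_solver():
    """Package closed form vs a longhand dense solve written in the tests."""
    rng = np.random.default_rng(31)
    for _ in range(25):
        edges, order, seeds = random_connected_graph(rng, n_max=30)
        W = column_normalize(edges, order)
        p0 = uniform_restart(seeds, order)
        expected = solve_rwr(edges, order, seeds, 0.5)
        got = diffuse_closed_form(W, p0, 0.5).p
        assert np.abs(got - expected).max() < 1e-10


class TestRankLncrnas:
    def make_sub(self, lncrnas, proteins, edges):
        lncs, prots = sorted(lncrnas), sorted(proteins)
        return DiseaseSubnetwork(
            disease_id="D1", seeds=frozenset({prots[0]}),
            proteins=frozenset(prots), lncrnas=frozenset(lncs),
            walk_edges=frozenset(edges), node_order=tuple(lncs + prots),
        )

    def scores(self, sub, mapping):
        p = np.array([mapping[n] for n in sub.node_order])
        return ScoreVector(p=p, node_order=sub.node_order,
                           iterations=1, final_residual=0.0)

    def test_proteins_excluded_and_sorted_descending(self):
        sub = self.make_sub(["L1", "L2"], ["G1"],
                            [("L1", "G1"), ("L2", "G1")])
        ranked = rank_lncrnas(
            self.scores(sub, {"L1": 0.2, "L2": 0.5, "G1": 0.3}), sub)
        assert ranked == [("L2", 0.5, 1), ("L1", 0.2, 2)]

    def test_ties_break_by_identifier(self):
        sub = self.make_sub(["L2", "L1"], ["G1"],
                            [("L1", "G1"), ("L2", "G1")])
        ranked = rank_lncrnas(
            self.scores(sub, {"L1": 0.1, "L2": 0.1, "G1": 0.8}), sub)
        assert [l for l, _, _ in ranked] == ["L1", "L2"]
        assert [r for _, _, r in ranked] == [1, 2]

    def test_misaligned_scores_rejected(self):
        sub = self.make_sub(["L1"], ["G1"], [("L1", "G1")])
        bad = ScoreVector(p=np.array([1.0]), node_order=("L1",),
                          iterations=1, final_residual=0.0)
        with pytest.raises(ValueError):
            rank_lncrnas(bad, sub)


@pytest.mark.parametrize("kwargs", [
    {"r": 0.0}, {"r": 1.5}, {"tol": 0.0}, {"max_iter": 0},
])
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        DiffusionParams(**kwargs)
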