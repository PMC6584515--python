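"""Smoothing solvers: system assembly, iteration, direct oracle, variants."""

import numpy as np
import pytest

from pdprank import (
    LabelAssignment,
    WeightedGraph,
    build_system,
    iterate,
    pseudo_sinksource_plus,
    sinksource,
    sinksource_plus,
    solve_direct,
)

from conftest import random_labeled_graph


def labels_of(g, pos, neg):
    return LabelAssignment(frozenset(pos), frozenset(neg), g)


class TestBuildSystem:
    def test_path_midpoint_system(self, path_pun):
        """P(+)-u-N(-), unit weights, lam=0: M is 1x1 zero, c = [1/2]."""
        g, pos, neg = path_pun
        sys = build_system(g, labels_of(g, pos, neg), lam=0.0)
        assert sys.unlabeled == ("u",)
        assert sys.M.toarray() == pytest.approx(np.array([[0.0]]))
        assert sys.c == pytest.approx([0.5])

    def test_single_edge_with_sink(self):
        """P(+)-u weight 1, lam=1, negatives ignored: c = [1/(1+1)]."""
        g = WeightedGraph([("P", "u", 1.0)])
        sys = build_system(
            g, labels_of(g, {"P"}, set()), lam=1.0, use_negatives=False
        )
        assert sys.c == pytest.approx([0.5])

    def test_chain_system(self, chain_pabn):
        """P-a-b-N at lam=0: M = [[0,1/2],[1/2,0]], c = [1/2, 0]."""
        g, pos, neg = chain_pabn
        sys = build_system(g, labels_of(g, pos, neg), lam=0.0)
        order = list(sys.unlabeled)
        M = sys.M.toarray()
        ia, ib = order.index("a"), order.index("b")
        assert M[ia, ib] == pytest.approx(0.5)
        assert M[ib, ia] == pytest.approx(0.5)
        assert M[ia, ia] == M[ib, ib] == 0.0
        assert sys.c[ia] == pytest.approx(0.5)
        assert sys.c[ib] == pytest.approx(0.0)

    def test_row_normalization_identity(self):
        """Row of M plus labeled-mass and sink shares sums to 1."""
        g, pos, neg = random_labeled_graph(seed=5)
        labels = labels_of(g, pos, neg)
        for lam in (0.0, 1.0):
            sys = build_system(g, labels, lam=lam)
            for i, u in enumerate(sys.unlabeled):
                d = g.weighted_degree(u)
                if d == 0 and lam == 0:
                    continue
                labeled_mass = sum(
                    w for _, v, w in [(u, v, g.weight(u, v)) for v in g.neighbors(u)]
                    if v in labels.labeled
                ) / (lam + d)
                total = sys.M[[i], :].sum() + labeled_mass + lam / (lam + d)
                assert total == pytest.approx(1.0)

    def test_eq8_count_matches_weighted_on_unit_graph(self, chain_pabn):
        g, pos, neg = chain_pabn
        labels = labels_of(g, pos, neg)
        a = build_system(g, labels, lam=0.0, eq8_count=False)
        b = build_system(g, labels, lam=0.0, eq8_count=True)
        assert a.c == pytest.approx(b.c)

    def test_eq8_count_differs_on_weighted_graph(self):
        g = WeightedGraph([("P", "u", 0.3), ("u", "x", 0.7)])
        labels = labels_of(g, {"P"}, {"x"})
        weighted = build_system(g, labels, lam=0.0)
        counted = build_system(g, labels, lam=0.0, eq8_count=True)
        assert weighted.c == pytest.approx([0.3])
        assert counted.c == pytest.approx([1.0])

    def test_negative_lambda_rejected(self, path_pun):
        g, pos, neg = path_pun
        with pytest.raises(ValueError):
            build_system(g, labels_of(g, pos, neg), lam=-0.1)

    def test_isolated_unlabeled_node_frozen_at_lambda_zero(self):
        g = WeightedGraph([("P", "N", 1.0)], nodes=["P", "N", "lonely"])
        sys = build_system(g, labels_of(g, {"P"}, {"N"}), lam=0.0)
        assert sys.frozen == {"lonely"}
        f = iterate(sys)
        assert f["lonely"] == 0.5
        assert solve_direct(sys)["lonely"] == 0.5


class TestIterate:
    def test_degree_one_neighbor_of_positive_scores_one(self):
        """Sole-neighbor-positive nodes converge to exactly 1 at lam=0."""
        g = WeightedGraph(
            [("P", "u", 1.0), ("P", "N", 0.5)]
        )
        f = sinksource(g, {"P"}, {"N"})
        assert f["u"] == pytest.approx(1.0, abs=1e-3)

    def test_path_midpoint_is_half(self, path_pun):
        g, pos, neg = path_pun
        f = sinksource(g, pos, neg)
        assert f["u"] == pytest.approx(0.5)
        assert f.iterations <= 2

    def test_chain_exact_solution(self, chain_pabn):
        g, pos, neg = chain_pabn
        f = sinksource(g, pos, neg, epsilon=1e-9)
        assert f["a"] == pytest.approx(2 / 3, abs=1e-6)
        assert f["b"] == pytest.approx(1 / 3, abs=1e-6)

    def test_labeled_values_reattached(self, chain_pabn):
        g, pos, neg = chain_pabn
        f = sinksource(g, pos, neg)
        assert f["P"] == 1.0 and f["N"] == 0.0

    def test_scores_in_unit_interval_at_every_iteration(self, default_fixture):
        """The update is a convex combination plus sink mass: range holds
        not only at convergence but after every single step."""
        fx = default_fixture
        labels = labels_of(fx.graph, fx.positives, fx.negatives)
        sys = build_system(fx.graph, labels, lam=1.0)
        for t in (1, 2, 3, 5, 10):
            f = iterate(sys, epsilon=1e-300, max_iter=t)
            assert f.values.min() >= 0.0 and f.values.max() <= 1.0

    def test_residual_nonincreasing(self, default_fixture):
        fx = default_fixture
        labels = labels_of(fx.graph, fx.positives, fx.negatives)
        sys = build_system(fx.graph, labels, lam=0.0)
        resids = [
            iterate(sys, epsilon=1e-300, max_iter=t).residual
            for t in range(1, 12)
        ]
        assert all(b <= a + 1e-12 for a, b in zip(resids, resids[1:]))


class TestSolveDirect:
    def test_chain_oracle(self, chain_pabn):
        g, pos, neg = chain_pabn
        f = sinksource(g, pos, neg, solver="direct")
        assert f["a"] == pytest.approx(2 / 3)
        assert f["b"] == pytest.approx(1 / 3)

    def test_one_by_one_system(self, path_pun):
        g, pos, neg = path_pun
        sys = build_system(g, labels_of(g, pos, neg), lam=0.0)
        assert solve_direct(sys)["u"] == pytest.approx(0.5)

    def test_no_positives_reachable_gives_zero_with_sink(self):
        """lam>0 and no positive neighbors anywhere: c=0 so f=0."""
        g = WeightedGraph([("P", "x", 1.0)], nodes=["P", "x", "y"])
        f = sinksource_plus(g, {"P"}, lam=5.0, solver="direct")
        assert f["y"] == pytest.approx(0.0)


class TestMethodFronts:
    def test_all_positive_neighbors_scores_one(self):
        g = WeightedGraph([("p1", "u", 1.0), ("p2", "u", 1.0), ("p1", "n", 1.0)])
        f = sinksource(g, {"p1", "p2"}, {"n"}, epsilon=1e-9)
        assert f["u"] == pytest.approx(1.0, abs=1e-6)

    def test_sinksource_requires_negatives(self, path_pun):
        g, pos, _ = path_pun
        with pytest.raises(ValueError, match="negative"):
            sinksource(g, pos, set())

    def test_sinksource_plus_requires_positive_lambda(self, path_pun):
        g, pos, _ = path_pun
        with pytest.raises(ValueError, match="lambda"):
            sinksource_plus(g, pos, lam=0.0)

    def test_sinksource_plus_closed_form(self):
        """Single edge P-u weight w: f(u) = w/(lam+w)."""
        for w, lam in [(1.0, 1.0), (0.5, 0.1), (0.9, 10.0)]:
            g = WeightedGraph([("P", "u", w)])
            f = sinksource_plus(g, {"P"}, lam=lam, epsilon=1e-12)
            assert f["u"] == pytest.approx(w / (lam + w), abs=1e-9)

    def test_sinksource_plus_large_lambda_kills_scores(self, default_fixture):
        fx = default_fixture
        f = sinksource_plus(fx.graph, fx.positives, lam=1e6, solver="direct")
        unl = [v for v in f.nodes if v not in fx.positives]
        assert max(f[v] for v in unl) < 1e-3

    def test_sinksource_plus_scores_former_negatives(self, path_pun):
        g, pos, neg = path_pun
        f = sinksource_plus(g, pos, lam=0.5)
        assert 0.0 < f["N"] < 1.0

    def test_pseudo_at_lambda_zero_equals_sinksource(self, default_fixture):
        """PSEUDO-SINKSOURCE+ with lam=0 is SINKSOURCE exactly."""
        fx = default_fixture
        a = sinksource(fx.graph, fx.positives, fx.negatives, epsilon=1e-9)
        b = pseudo_sinksource_plus(
            fx.graph, fx.positives, fx.negatives, lam=0.0, epsilon=1e-9
        )
        np.testing.assert_allclose(a.values, b.reindex(a.nodes), atol=1e-12)

    def test_pseudo_single_edge_closed_form(self):
        g = WeightedGraph([("P", "u", 1.0)], nodes=["P", "u", "N"])
        f = pseudo_sinksource_plus(g, {"P"}, {"N"}, lam=1.0, epsilon=1e-12)
        assert f["u"] == pytest.approx(0.5)


class TestProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_iterative_matches_direct_oracle(self, seed):
        """Jacobi iteration at tight epsilon agrees with the exact solve."""
        g, pos, neg = random_labeled_graph(seed, n_hi=80)
        labels = labels_of(g, pos, neg)
        for lam in (0.0, 0.01, 1.0, 10.0):
            sys = build_system(g, labels, lam=lam)
            fi = iterate(sys, epsilon=1e-11, max_iter=100_000)
            fd = solve_direct(sys)
            np.testing.assert_allclose(
                fi.values, fd.values, atol=1e-6,
                err_msg=f"seed={seed} lam={lam}",
            )

    @pytest.mark.parametrize("seed", range(6))
    def test_harmonicity_at_convergence(self, seed):
        """At lam=0 each unlabeled score is the weighted neighbor average."""
        g, pos, neg = random_labeled_graph(seed, n_hi=60)
        f = sinksource(g, pos, neg, solver="direct")
        for v in g.nodes:
            if v in pos or v in neg or v in f.frozen:
                continue
            d = g.weighted_degree(v)
            if d == 0:
                continue
            avg = sum(g.weight(v, u) * f[u] for u in g.neighbors(v)) / d
            assert f[v] == pytest.approx(avg, abs=1e-8)

    @pytest.mark.parametrize("seed", range(6))
    def test_scores_nonincreasing_in_lambda(self, seed):
        g, pos, neg = random_labeled_graph(seed, n_hi=60)
        labels = labels_of(g, pos, neg)
        lams = [0.0, 0.01, 1.0, 10.0, 50.0]
        prev = None
        for lam in lams:
            f = solve_direct(build_system(g, labels, lam=lam))
            if prev is not None:
                assert (f.values <= prev.reindex(f.nodes) + 1e-9).all()
            prev = f

    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_in_labels(self, seed):
        """Adding a positive never lowers a score; adding a negative never
        raises one (checked with the exact solver)."""
        g, pos, neg = random_labeled_graph(seed, n_hi=60)
        unl = sorted(set(g.nodes) - pos - neg)
        if len(unl) < 2:
            return
        base = solve_direct(build_system(g, labels_of(g, pos, neg), lam=1.0))
        promoted = unl[0]
        fp = solve_direct(
            build_system(g, labels_of(g, pos | {promoted}, neg), lam=1.0)
        )
        fn = solve_direct(
            build_system(g, labels_of(g, pos, neg | {promoted}), lam=1.0)
        )
        rest = [v for v in unl[1:]]
        b = np.array([base[v] for v in rest])
        assert (np.array([fp[v] for v in rest]) >= b - 1e-9).all()
        assert (np.array([fn[v] for v in rest]) <= b + 1e-9).all()

    def test_convergence_within_default_budget(self, default_fixture):
        """epsilon=0.001 is reached before 500 iterations on the fixture."""
        fx = default_fixture
        for lam in (0.0, 1.0, 10.0):
            f = pseudo_sinksource_plus(fx.graph, fx.positives, fx.negatives, lam=lam)
            assert f.converged and f.iterations < 500
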