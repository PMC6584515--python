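"""Shared fixtures: tiny hand-checkable graphs and random instances."""

import numpy as np
import pytest

from pdprank import FixtureSpec, LabelAssignment, WeightedGraph, make_fixture


@pytest.fixture
def path_pun():
    """P(+) - u - N(-) with unit weights: the symmetric midpoint case."""
    g = WeightedGraph([("P", "u", 1.0), ("u", "N", 1.0)])
    return g, frozenset({"P"}), frozenset({"N"})


@pytest.fixture
def chain_pabn():
    """P(+) - a - b - N(-), unit weights: exact solution f(a)=2/3, f(b)=1/3."""
    g = WeightedGraph(
        [("P", "a", 1.0), ("a", "b", 1.0), ("b", "N", 1.0)]
    )
    return g, frozenset({"P"}), frozenset({"N"})


@pytest.fixture(scope="session")
def default_fixture():
    """The standard planted-community world (decoys included)."""
    return make_fixture(FixtureSpec())


@pytest.fixture(scope="session")
def default_labels(default_fixture):
    fx = default_fixture
    return LabelAssignment(fx.positives, fx.negatives, fx.graph)


@pytest.fixture(scope="session")
def disease_fixture():
    """Fixture with informative negatives clustered near the positives."""
    return make_fixture(FixtureSpec.disease_like(seed=3))


def random_labeled_graph(seed, n_lo=10, n_hi=120, p=0.12, frac_pos=0.15,
                         frac_neg=0.15):
    """Random weighted G(n, p) with random positive/negative labels.

    Used wherever a battery of unstructured instances is needed (oracle
    equivalence, monotonicity).  At least one positive and one negative are
    guaranteed; disconnected unlabeled regions are legal (the solvers
    freeze them).
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_lo, n_hi + 1))
    names = [f"n{i:03d}" for i in range(n)]
    iu, jv = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < p
    ws = rng.uniform(0.05, 1.0, size=int(mask.sum()))
    edges = [
        (names[i], names[j], float(w))
        for i, j, w in zip(iu[mask], jv[mask], ws)
    ]
    perm = rng.permutation(n)
    n_pos = max(1, int(frac_pos * n))
    n_neg = max(1, int(frac_neg * n))
    pos = frozenset(names[i] for i in perm[:n_pos])
    neg = frozenset(names[i] for i in perm[n_pos:n_pos + n_neg])
    return WeightedGraph(edges, nodes=names), pos, neg
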