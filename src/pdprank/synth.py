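"""Synthetic networks and label sets for testing and benchmarking.

The generator emulates the structural situation the smoothing methods
exploit on real functional interaction networks: disease genes cluster in
a densely connected module, confident negatives sit elsewhere, and a
handful of degree-1 "decoy" genes hang off positives (the mechanism behind
the low-degree ranking bias of plain harmonic smoothing).

Graphs are stochastic block models: declared communities with
within-density ``p_in``, background nodes and cross-community pairs with
density ``p_out`` (optionally a stronger coupling ``p_cross`` between the
first two communities), and i.i.d. uniform edge weights.  All randomness
derives from one master seed via ``numpy.random.SeedSequence`` spawning
(graph topology, weights, label draws and decoy wiring each get their own
stream), so fixtures are bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import NamedTuple

import networkx as nx
import numpy as np

from .network import WeightedGraph

__all__ = [
    "FixtureSpec",
    "Fixture",
    "planted_partition_graph",
    "sample_label_sets",
    "make_fixture",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic planted-community fixture.

    Defaults describe the standard test world: 500 nodes with one planted
    community of 100, within-density 0.15 against background density 0.01,
    weights uniform on (0.15, 1.0] (mirroring a posterior-probability
    cutoff at 0.15), 40 positives drawn from the community, 80 negatives
    from the background, and 20 unit-weight degree-1 decoys attached to
    positives.  Sized so that full repeated CV runs in seconds.
    """

    n_nodes: int = 500
    community_sizes: tuple[int, ...] = (100,)
    p_in: float = 0.15
    p_out: float = 0.01
    #: optional denser coupling between communities 0 and 1 (else p_out)
    p_cross: float | None = None
    w_lo: float = 0.15
    w_hi: float = 1.0
    n_positives: int = 40
    n_negatives: int = 80
    #: community index negatives are drawn from; None = background
    negatives_from: int | None = None
    n_decoys: int = 20
    seed: int = 0

    def __post_init__(self):
        if sum(self.community_sizes) > self.n_nodes:
            raise ValueError("community sizes exceed n_nodes")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("need 0 <= p_out < p_in <= 1")
        if not (0 < self.w_lo <= self.w_hi <= 1):
            raise ValueError("weights must lie in (0, 1]")
        if self.n_positives > self.community_sizes[0]:
            raise ValueError("more positives than planted community members")
        neg_pool = (
            self.n_nodes - sum(self.community_sizes)
            if self.negatives_from is None
            else self.community_sizes[self.negatives_from]
        )
        if self.n_negatives > neg_pool:
            raise ValueError("more negatives than eligible nodes")

    def with_seed(self, seed: int) -> "FixtureSpec":
        return replace(self, seed=seed)

    @classmethod
    def disease_like(cls, seed: int = 0) -> "FixtureSpec":
        """Fixture where negatives carry signal: a negative community of
        100 nodes coupled to the positive community (p_cross = 0.10), so
        informative negatives sit near the positives — the regime where
        curated negatives matter and large lambda blurs the classes."""
        return cls(
            community_sizes=(100, 100),
            p_cross=0.10,
            negatives_from=1,
            seed=seed,
        )


class Fixture(NamedTuple):
    """A generated world: graph (decoys included) plus label sets."""

    graph: WeightedGraph
    positives: frozenset[str]
    negatives: frozenset[str]


def _streams(seed: int, n: int):
    return np.random.SeedSequence(seed).spawn(n)


def planted_partition_graph(spec: FixtureSpec) -> WeightedGraph:
    """Weighted stochastic block graph with planted communities.

    Community membership is stored in ``graph.meta["communities"]`` (a list
    of frozensets, one per declared community; remaining nodes are
    background).  Node ids are ``g0000``-style strings.
    """
    ss_topo, ss_w = _streams(spec.seed, 4)[:2]
    sizes = list(spec.community_sizes)
    bg = spec.n_nodes - sum(sizes)
    if bg:
        sizes.append(bg)
    k = len(sizes)
    p = np.full((k, k), spec.p_out)
    for i, _ in enumerate(spec.community_sizes):
        p[i, i] = spec.p_in
    if bg:
        p[k - 1, k - 1] = spec.p_out
    if spec.p_cross is not None:
        if len(spec.community_sizes) < 2:
            raise ValueError("p_cross requires at least two communities")
        p[0, 1] = p[1, 0] = spec.p_cross
    topo_seed = int(ss_topo.generate_state(1)[0] % (2**31 - 1))
    sbm = nx.stochastic_block_model(sizes, p.tolist(), seed=topo_seed)
    names = [f"g{i:04d}" for i in range(spec.n_nodes)]
    rng_w = np.random.default_rng(ss_w)
    edges = [
        (names[u], names[v], float(rng_w.uniform(spec.w_lo, spec.w_hi)))
        for u, v in sbm.edges()
    ]
    start = np.cumsum([0] + list(spec.community_sizes))
    communities = [
        frozenset(names[start[i]:start[i + 1]])
        for i in range(len(spec.community_sizes))
    ]
    return WeightedGraph(edges, nodes=names, meta={"communities": communities})


def sample_label_sets(g: WeightedGraph, spec: FixtureSpec) -> Fixture:
    """Draw positives from the planted community, negatives per spec, and
    wire degree-1 decoys to random positives with weight 1.

    Requires community metadata on ``g`` (set by
    :func:`planted_partition_graph`).  Decoy nodes are new nodes named
    ``decoy000``..; the returned :class:`Fixture` carries the graph with
    decoys attached (the input graph is unchanged).
    """
    if "communities" not in g.meta:
        raise ValueError("graph lacks community metadata; use planted_partition_graph")
    _, _, ss_lab, ss_decoy = _streams(spec.seed, 4)
    rng = np.random.default_rng(ss_lab)
    communities = g.meta["communities"]
    pos_pool = sorted(communities[0])
    positives = frozenset(rng.choice(pos_pool, spec.n_positives, replace=False))
    if spec.negatives_from is None:
        neg_pool = sorted(
            set(g.nodes) - frozenset().union(*communities)
        )
    else:
        neg_pool = sorted(communities[spec.negatives_from] - positives)
    negatives = frozenset(rng.choice(neg_pool, spec.n_negatives, replace=False))
    assert not (positives & negatives)

    rng_d = np.random.default_rng(ss_decoy)
    pos_sorted = sorted(positives)
    decoys = [f"decoy{i:03d}" for i in range(spec.n_decoys)]
    spokes = [
        (d, str(rng_d.choice(pos_sorted)), 1.0) for d in decoys
    ]
    graph = g.with_added(spokes, nodes=decoys) if decoys else g
    return Fixture(graph=graph, positives=positives, negatives=negatives)


def make_fixture(spec: FixtureSpec | None = None) -> Fixture:
    """Generate graph and labels in one call (the usual entry point)."""
    spec = spec or FixtureSpec()
    return sample_label_sets(planted_partition_graph(spec), spec)
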