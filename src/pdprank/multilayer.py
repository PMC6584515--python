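"""Multi-layer smoothing: label splitting across graph copies.

The multi-layer construction lets distantly labeled nodes influence a
node's score even when an adjacent labeled node would otherwise dominate
it.  The base graph G is copied l times; the labeled nodes are partitioned
across the l layers (each label lives in exactly one layer, the node's
other copies are unlabeled); every base node v additionally gets a
supernode v_0 connected to its copies v_1..v_l with weight omega.  Running
PSEUDO-SINKSOURCE+ on this expanded graph and reading f(v_0) — the
(omega-)weighted average of v's copies — gives the final score of v.

Copy nodes are named ``v@k`` (layer k, 1-based) and supernodes ``v@0``;
base node ids must therefore not contain ``@``.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np

from .labels import LabelAssignment
from .network import WeightedGraph
from .smoothing import (
    DEFAULT_EPSILON,
    DEFAULT_MAX_ITER,
    ScoreVector,
    _solve,
    build_system,
)

__all__ = ["MultiLayerGraph", "build_multilayer_graph", "multilayer_pss"]

log = logging.getLogger(__name__)

_SEP = "@"


def _copy(v: str, k: int) -> str:
    return f"{v}{_SEP}{k}"


@dataclass(frozen=True)
class MultiLayerGraph:
    """Expanded graph of the multi-layer construction.

    ``graph`` holds l exact copies of the base edge set plus supernode
    spokes; ``layer_positives``/``layer_negatives`` record which layer each
    label was assigned to (a stratified, seeded random partition).
    """

    base: WeightedGraph = field(repr=False)
    graph: WeightedGraph = field(repr=False)
    layers: int
    omega: float
    layer_positives: tuple[frozenset[str], ...]
    layer_negatives: tuple[frozenset[str], ...]

    @property
    def positives(self) -> frozenset[str]:
        """Positive labels on the expanded graph (copy-node ids)."""
        return frozenset(
            _copy(v, k + 1)
            for k, part in enumerate(self.layer_positives)
            for v in part
        )

    @property
    def negatives(self) -> frozenset[str]:
        return frozenset(
            _copy(v, k + 1)
            for k, part in enumerate(self.layer_negatives)
            for v in part
        )

    def supernode(self, v: str) -> str:
        return _copy(str(v), 0)

    def copies(self, v: str) -> list[str]:
        return [_copy(str(v), k) for k in range(1, self.layers + 1)]


def _partition(items: Iterable[str], l: int, rng: np.random.Generator):
    """Seeded near-equal random split into l parts."""
    items = sorted(map(str, items))
    perm = rng.permutation(len(items))
    parts = np.array_split(perm, l)
    return tuple(frozenset(items[i] for i in part) for part in parts)


def build_multilayer_graph(
    g: WeightedGraph,
    labels: LabelAssignment,
    l: int,
    omega: float = 1.0,
    seed: int = 0,
) -> MultiLayerGraph:
    """Copy the graph l times, partition labels across layers, add supernodes.

    Positives and negatives are partitioned independently (so each layer
    receives a proportional share of each class) using a seeded RNG.  The
    result has (l+1)·|V| nodes and l·|E| + l·|V| edges.

    Raises
    ------
    ValueError
        If l < 2, omega <= 0, l exceeds the size of either label class, or
        a base node id contains the reserved ``@`` separator.
    """
    if l < 2:
        raise ValueError(f"multilayer requires l >= 2 layers, got {l}")
    if omega <= 0:
        raise ValueError(f"supernode weight omega must be > 0, got {omega}")
    if l > len(labels.positives):
        raise ValueError(
            f"l={l} layers but only {len(labels.positives)} positives: "
            "a layer would carry no positive label"
        )
    if l > len(labels.negatives):
        raise ValueError(
            f"l={l} layers but only {len(labels.negatives)} negatives: "
            "a layer would carry no negative label"
        )
    bad = [v for v in g.nodes if _SEP in v]
    if bad:
        raise ValueError(f"base node ids must not contain '@': {bad[:3]}")

    rng = np.random.default_rng(seed)
    layer_pos = _partition(labels.positives, l, rng)
    layer_neg = _partition(labels.negatives, l, rng)

    edges: list[tuple[str, str, float]] = []
    for u, v, w in g.edges():
        for k in range(1, l + 1):
            edges.append((_copy(u, k), _copy(v, k), w))
    for v in g.nodes:
        s = _copy(v, 0)
        for k in range(1, l + 1):
            edges.append((s, _copy(v, k), float(omega)))
    nodes = [_copy(v, k) for v in g.nodes for k in range(l + 1)]
    expanded = WeightedGraph(edges, nodes=nodes)
    return MultiLayerGraph(
        base=g, graph=expanded, layers=l, omega=float(omega),
        layer_positives=layer_pos, layer_negatives=layer_neg,
    )


def multilayer_pss(
    g: WeightedGraph,
    positives: Iterable[str],
    negatives: Iterable[str],
    lam: float,
    l: int = 2,
    omega: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
    solver: str = "iterative",
    sink_on_supernodes: bool = False,
) -> ScoreVector:
    """MULTI-LAYER PSEUDO-SINKSOURCE+: smooth the expanded graph, read f(v_0).

    The lambda sink attaches to the copy nodes; supernodes are left
    sink-free by default so that f(v_0) is exactly the omega-weighted
    average of the copies (with uniform omega, their mean) at the fixed
    point.  ``sink_on_supernodes=True`` applies the sink uniformly instead,
    which damps the supernode average by a factor omega*l/(lambda+omega*l).
    """
    base_labels = LabelAssignment(frozenset(positives), frozenset(negatives), g)
    mlg = build_multilayer_graph(g, base_labels, l=l, omega=omega, seed=seed)
    ml_labels = LabelAssignment(mlg.positives, mlg.negatives, mlg.graph)
    sink = None
    if not sink_on_supernodes and lam > 0:
        sink = [v for v in mlg.graph.nodes if not v.endswith(f"{_SEP}0")]
    sys = build_system(
        mlg.graph, ml_labels, lam=lam, use_negatives=True, sink_nodes=sink
    )
    full = _solve(sys, epsilon, max_iter, "multilayer-pss", solver)
    vals = full.reindex([mlg.supernode(v) for v in g.nodes])
    return ScoreVector(
        nodes=g.nodes, values=vals, method="multilayer-pss", lam=float(lam),
        iterations=full.iterations, residual=full.residual,
        converged=full.converged,
        frozen=frozenset(
            v for v in g.nodes if mlg.supernode(v) in full.frozen
        ),
    )
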