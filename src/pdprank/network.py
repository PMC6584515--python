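"""Weighted undirected gene networks.

Edge-list I/O, weight filtering, and degree queries for functional
interaction networks: nodes are gene identifiers (opaque strings; integer
Entrez IDs in practice) and edge weights are posterior probabilities in
(0, 1] that two genes functionally interact in a tissue.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from pathlib import Path

import numpy as np
from scipy import sparse

__all__ = [
    "WeightedGraph",
    "NetworkFormatError",
    "read_edge_list",
    "weighted_degree",
    "restrict_to_graph",
]

log = logging.getLogger(__name__)


class NetworkFormatError(ValueError):
    """Raised when an edge-list file cannot be parsed into a valid network."""


class WeightedGraph:
    """Undirected weighted graph G = (V, E, w) backed by a symmetric CSR matrix.

    Invariants enforced at construction: no self-loops, no duplicate edges
    (duplicates collapse to the maximum weight), all weights strictly
    positive, and the node set covers every edge endpoint.  Isolated nodes
    are permitted when declared explicitly via ``nodes``.

    Parameters
    ----------
    edges
        Iterable of ``(u, v, weight)`` triples; ``(u, v)`` and ``(v, u)``
        denote the same edge.
    nodes
        Optional iterable of node ids declaring the node universe; endpoints
        of ``edges`` are always included.  Order of first appearance fixes
        the internal node order.
    meta
        Free-form metadata dictionary (e.g. planted-community membership for
        synthetic fixtures).
    """

    __slots__ = ("_nodes", "_index", "_adj", "meta")

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]] = (),
        nodes: Iterable[str] | None = None,
        meta: dict | None = None,
    ):
        order: dict[str, int] = {}
        if nodes is not None:
            for v in nodes:
                order.setdefault(str(v), len(order))
        best: dict[tuple[int, int], float] = {}
        for u, v, w in edges:
            u, v = str(u), str(v)
            if u == v:
                raise ValueError(f"self-loop on node {u!r} is not allowed")
            w = float(w)
            if not w > 0:
                raise ValueError(f"edge ({u}, {v}) has non-positive weight {w}")
            iu = order.setdefault(u, len(order))
            iv = order.setdefault(v, len(order))
            key = (iu, iv) if iu < iv else (iv, iu)
            prev = best.get(key)
            if prev is None or w > prev:
                best[key] = w
        self._nodes: tuple[str, ...] = tuple(order)
        self._index: dict[str, int] = order
        n = len(order)
        if best:
            keys = np.array(list(best), dtype=np.int64)
            ws = np.fromiter(best.values(), dtype=np.float64, count=len(best))
            rows = np.concatenate([keys[:, 0], keys[:, 1]])
            cols = np.concatenate([keys[:, 1], keys[:, 0]])
            data = np.concatenate([ws, ws])
            self._adj = sparse.csr_array(
                (data, (rows, cols)), shape=(n, n), dtype=np.float64
            )
        else:
            self._adj = sparse.csr_array((n, n), dtype=np.float64)
        self.meta: dict = dict(meta) if meta else {}

    # -- basic queries ----------------------------------------------------

    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    def __contains__(self, v) -> bool:
        return str(v) in self._index

    def __len__(self) -> int:
        return len(self._nodes)

    @property
    def number_of_nodes(self) -> int:
        return len(self._nodes)

    @property
    def number_of_edges(self) -> int:
        return int(self._adj.nnz) // 2

    def index(self, v) -> int:
        try:
            return self._index[str(v)]
        except KeyError:
            raise KeyError(f"node {v!r} is not in the graph") from None

    def edges(self):
        """Yield ``(u, v, weight)`` once per unordered pair."""
        coo = sparse.triu(self._adj, k=1).tocoo()
        for i, j, w in zip(coo.row, coo.col, coo.data):
            yield self._nodes[i], self._nodes[j], float(w)

    def weight(self, u, v) -> float:
        return float(self._adj[self.index(u), self.index(v)])

    def neighbors(self, v) -> list[str]:
        i = self.index(v)
        row = self._adj[[i], :].tocoo()
        return [self._nodes[j] for j in row.col]

    def degree(self, v) -> int:
        """Unweighted degree (neighbor count)."""
        i = self.index(v)
        return int(self._adj.indptr[i + 1] - self._adj.indptr[i])

    def weighted_degree(self, v) -> float:
        """d_v = sum of incident edge weights; 0 for isolated nodes."""
        i = self.index(v)
        return float(self._adj[[i], :].sum())

    def degrees(self) -> np.ndarray:
        """Unweighted degrees aligned with ``self.nodes``."""
        return np.diff(self._adj.indptr)

    def weighted_degrees(self) -> np.ndarray:
        """Weighted degrees d_v aligned with ``self.nodes``."""
        return np.asarray(self._adj.sum(axis=1)).ravel()

    def isolated_nodes(self) -> frozenset[str]:
        deg = self.degrees()
        return frozenset(self._nodes[i] for i in np.flatnonzero(deg == 0))

    def adjacency(self) -> sparse.csr_array:
        """Symmetric adjacency matrix in ``self.nodes`` order (a view)."""
        return self._adj

    # -- derived graphs ---------------------------------------------------

    def with_added(
        self,
        edges: Iterable[tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "WeightedGraph":
        """New graph with extra nodes/edges appended (original untouched)."""
        all_edges = list(self.edges()) + [(str(u), str(v), float(w)) for u, v, w in edges]
        all_nodes = list(self._nodes) + [str(v) for v in nodes]
        return WeightedGraph(all_edges, nodes=all_nodes, meta=self.meta)

    # -- I/O ---------------------------------------------------------------

    def write_edge_list(self, path) -> None:
        """Write a tab-separated edge list (node, node, weight)."""
        with open(path, "w") as fh:
            fh.write("# node\tnode\tweight\n")
            for u, v, w in self.edges():
                fh.write(f"{u}\t{v}\t{w:.6g}\n")

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"WeightedGraph(|V|={self.number_of_nodes}, "
            f"|E|={self.number_of_edges})"
        )


def read_edge_list(
    path,
    min_weight: float = 0.0,
    drop_isolated: bool = False,
) -> WeightedGraph:
    """Read a weighted edge list, keeping only edges with weight >= min_weight.

    The file is tab- or whitespace-separated with at least three columns
    (node, node, weight); lines starting with ``#`` and blank lines are
    skipped.  Duplicate ``(u, v)``/``(v, u)`` lines collapse to a single edge
    with the maximum weight; self-loop lines are dropped (count logged).
    HumanBase "top edges" files filtered at posterior probability >= 0.15 are
    the motivating input.

    Parameters
    ----------
    path
        Edge-list file path.
    min_weight
        Weight threshold in [0, 1]; edges strictly below it are removed.
    drop_isolated
        If True, nodes left with no surviving edge are dropped from V;
        otherwise they are retained (and reported by
        :meth:`WeightedGraph.isolated_nodes`).

    Raises
    ------
    NetworkFormatError
        On an unparseable line (named by line number), a weight outside
        [0, 1], or an empty file.
    """
    if not 0.0 <= min_weight <= 1.0:
        raise ValueError(f"min_weight must be in [0, 1], got {min_weight}")
    path = Path(path)
    kept: list[tuple[str, str, float]] = []
    universe: list[str] = []
    seen: set[str] = set()
    n_self, n_lines = 0, 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected >= 3 columns (node, node, "
                    f"weight), got {len(parts)}"
                )
            u, v = parts[0], parts[1]
            try:
                w = float(parts[2])
            except ValueError:
                raise NetworkFormatError(
                    f"{path}:{lineno}: weight {parts[2]!r} is not a number"
                ) from None
            if not 0.0 <= w <= 1.0:
                raise NetworkFormatError(
                    f"{path}:{lineno}: weight {w} outside [0, 1]"
                )
            n_lines += 1
            if u == v:
                n_self += 1
                continue
            for x in (u, v):
                if x not in seen:
                    seen.add(x)
                    universe.append(x)
            if w >= min_weight and w > 0:
                kept.append((u, v, w))
    if n_lines == 0:
        raise NetworkFormatError(f"{path}: no edges found")
    if n_self:
        log.info("%s: dropped %d self-loop line(s)", path, n_self)
    if drop_isolated:
        touched = {u for u, _, _ in kept} | {v for _, v, _ in kept}
        universe = [v for v in universe if v in touched]
    g = WeightedGraph(kept, nodes=universe)
    log.info(
        "%s: %d nodes, %d edges after filtering at weight >= %g",
        path, g.number_of_nodes, g.number_of_edges, min_weight,
    )
    return g


def weighted_degree(g: WeightedGraph, v) -> float:
    """Weighted degree d_v = sum over neighbors of w_uv (0 if isolated)."""
    return g.weighted_degree(v)


def restrict_to_graph(genes: Iterable[str], g: WeightedGraph) -> set[str]:
    """Intersect a gene set with the network's node set (removals logged)."""
    genes = {str(x) for x in genes}
    present = {x for x in genes if x in g}
    removed = len(genes) - len(present)
    if removed:
        log.info("restrict_to_graph: removed %d gene(s) absent from network", removed)
    return present
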