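"""Curated positive/negative gene sets and control negative sets.

A :class:`LabelAssignment` partitions the network's nodes into curated
positives C, curated negatives C-bar, and unlabeled nodes U = V \\ (C u C-bar).
Construction enforces the curation rules used for disease gene sets: both
sets are intersected with the network, and any gene that is a positive in
the target set or in any other positive set is removed from the negatives
(never the other way around).

Control negative sets for benchmarking come in two flavours: uniform random
draws from the network, and draws that preserve the (log2-binned) unweighted
degree distribution of a template set.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .network import WeightedGraph, restrict_to_graph

__all__ = [
    "LabelAssignment",
    "build_label_assignment",
    "read_gene_set",
    "write_gene_set",
    "random_negatives",
    "degree_matched_negatives",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LabelAssignment:
    """Positives C, negatives C-bar, and the implied unlabeled set U.

    Invariants checked at construction: C and C-bar are disjoint subsets of
    the graph's nodes, and C is nonempty (smoothing with zero positives is
    refused).  C-bar may be empty; methods that require negatives raise at
    call time.
    """

    positives: frozenset[str]
    negatives: frozenset[str]
    graph: WeightedGraph = field(repr=False)

    def __post_init__(self):
        object.__setattr__(self, "positives", frozenset(map(str, self.positives)))
        object.__setattr__(self, "negatives", frozenset(map(str, self.negatives)))
        if not self.positives:
            raise ValueError("label assignment requires at least one positive")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(
                f"{len(overlap)} gene(s) labeled both positive and negative, "
                f"e.g. {sorted(overlap)[:3]}"
            )
        missing = [v for v in self.positives | self.negatives if v not in self.graph]
        if missing:
            raise ValueError(
                f"{len(missing)} labeled gene(s) not in the network, "
                f"e.g. {sorted(missing)[:3]}"
            )

    @property
    def labeled(self) -> frozenset[str]:
        """L = C u C-bar."""
        return self.positives | self.negatives

    @property
    def unlabeled(self) -> frozenset[str]:
        """U = V \\ L."""
        return frozenset(self.graph.nodes) - self.labeled

    def relabel(self, positives, negatives) -> "LabelAssignment":
        """Same graph, different label sets (used by CV fold hiding)."""
        return LabelAssignment(frozenset(positives), frozenset(negatives), self.graph)


def build_label_assignment(
    positives: Iterable[str],
    negatives: Iterable[str],
    g: WeightedGraph,
    extra_positive_sets: Sequence[Iterable[str]] = (),
) -> LabelAssignment:
    """Intersect curated sets with the network and resolve overlaps.

    Genes absent from the network are dropped from both sets.  A gene in
    ``negatives`` that also appears in ``positives`` or in any of
    ``extra_positive_sets`` is removed from the negatives: conflicted genes
    always stay positive.  Removal counts are logged.

    Raises
    ------
    ValueError
        If no positives survive the restriction.
    """
    pos = restrict_to_graph(positives, g)
    neg = restrict_to_graph(negatives, g)
    forbidden = set(pos)
    for extra in extra_positive_sets:
        forbidden |= {str(x) for x in extra}
    conflicted = neg & forbidden
    if conflicted:
        log.info(
            "build_label_assignment: removed %d negative(s) overlapping a "
            "positive set", len(conflicted),
        )
        neg -= conflicted
    if not pos:
        raise ValueError("no positives remain after restriction to the network")
    return LabelAssignment(frozenset(pos), frozenset(neg), g)


def read_gene_set(path) -> set[str]:
    """Read a gene set: one identifier per line, '#' comments allowed.

    Duplicate identifiers collapse silently (count logged).
    """
    out: set[str] = set()
    n = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            n += 1
            out.add(line.split()[0])
    if n > len(out):
        log.info("%s: collapsed %d duplicate gene id(s)", path, n - len(out))
    return out


def write_gene_set(genes: Iterable[str], path) -> None:
    with open(path, "w") as fh:
        for gid in sorted(map(str, genes)):
            fh.write(gid + "\n")


def random_negatives(
    g: WeightedGraph, n: int, exclude: Iterable[str] = (), seed: int = 0
) -> set[str]:
    """Uniform sample without replacement of n nodes from V \\ exclude."""
    exclude = {str(x) for x in exclude}
    pool = sorted(v for v in g.nodes if v not in exclude)
    if n > len(pool):
        raise ValueError(
            f"cannot sample {n} negatives from {len(pool)} eligible nodes"
        )
    rng = np.random.default_rng(seed)
    return set(rng.choice(pool, size=n, replace=False)) if n else set()


def _log2_bin(deg: int) -> int:
    """Degree bin: {0}, {1}, {2,3}, {4..7}, ... (log2 width)."""
    return -1 if deg == 0 else int(math.floor(math.log2(deg)))


def degree_matched_negatives(
    g: WeightedGraph,
    template: Iterable[str],
    exclude: Iterable[str] = (),
    seed: int = 0,
) -> set[str]:
    """Sample a control set preserving the template's degree distribution.

    Unweighted degrees are binned logarithmically (base 2: {1}, {2,3},
    {4..7}, ...); within each bin the same number of nodes as the template
    holds there is drawn uniformly without replacement from the non-excluded
    nodes of that bin.  The binned degree histogram of the output therefore
    equals the template's exactly.

    Raises
    ------
    ValueError
        If some bin has fewer eligible candidates than the template demands
        (the bin is named in the message).
    """
    template = {str(x) for x in template}
    exclude = {str(x) for x in exclude}
    missing = [v for v in template if v not in g]
    if missing:
        raise KeyError(f"template node(s) not in graph: {sorted(missing)[:3]}")
    need: dict[int, int] = {}
    for v in template:
        b = _log2_bin(g.degree(v))
        need[b] = need.get(b, 0) + 1
    pools: dict[int, list[str]] = {b: [] for b in need}
    for v in g.nodes:
        if v in exclude:
            continue
        b = _log2_bin(g.degree(v))
        if b in pools:
            pools[b].append(v)
    rng = np.random.default_rng(seed)
    out: set[str] = set()
    for b in sorted(need):
        pool = sorted(pools[b])
        if len(pool) < need[b]:
            lo = 0 if b == -1 else 2**b
            hi = 0 if b == -1 else 2 ** (b + 1) - 1
            raise ValueError(
                f"degree bin [{lo}, {hi}] needs {need[b]} node(s) but only "
                f"{len(pool)} candidate(s) are available"
            )
        out |= set(rng.choice(pool, size=need[b], replace=False))
    return out
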