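"""Gaussian smoothing (label propagation) on weighted gene networks.

Given curated positives C (fixed at 1) and negatives C-bar (fixed at 0),
the score of every unlabeled node is the harmonic extension of the labels:
the minimizer of

    (1/2) * sum_{(u,v) in E} w_uv (f(u) - f(v))^2

subject to the labeled values being fixed.  At the optimum each unlabeled
score is the weighted average of its neighbors' scores.  Three variants are
provided:

* ``sinksource``          — positives and negatives, no sink (lambda = 0);
* ``sinksource_plus``     — positives only, plus a lambda-weighted virtual
                            negative ("sink") attached to every node,
                            realised by adding lambda to each denominator;
* ``pseudo_sinksource_plus`` — both the curated negatives and the lambda
                            sink.  With lambda = 0 it coincides with
                            ``sinksource``.

The fixed point is computed either by the classical Jacobi-style iteration
f_t = M f_{t-1} + c from the all-0.5 initialization (the field-standard
procedure, epsilon = 0.001, at most 500 iterations) or by a direct sparse
solve of (I - M) f = c, which serves as the exact oracle.

Over the unlabeled nodes u, v:

    M_uv = w_uv / (lambda + d_u)          (0 unless (u,v) in E)
    c_u  = sum_{v in N_u ^ C} w_uv / (lambda + d_u)

where d_u is the weighted degree.  The numerator of c is the weighted sum
of edges to positives — on a 0/1-weighted graph this equals the positive
neighbor count; ``eq8_count=True`` selects the literal count instead.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse import linalg as spla

from .labels import LabelAssignment
from .network import WeightedGraph

__all__ = [
    "LinearSystem",
    "ScoreVector",
    "SingularSystemError",
    "build_system",
    "iterate",
    "solve_direct",
    "sinksource",
    "sinksource_plus",
    "pseudo_sinksource_plus",
    "DEFAULT_EPSILON",
    "DEFAULT_MAX_ITER",
]

log = logging.getLogger(__name__)

DEFAULT_EPSILON = 1e-3
DEFAULT_MAX_ITER = 500


class SingularSystemError(np.linalg.LinAlgError):
    """(I - M) is singular: some unlabeled block receives no label mass."""


@dataclass(frozen=True)
class ScoreVector:
    """Node scores f: V -> [0, 1] with solver metadata.

    Labeled nodes carry their fixed values (1 for positives, 0 for
    negatives); under SINKSOURCE+ the curated negatives are scored as
    unlabeled.  ``frozen`` lists nodes held at the 0.5 initialization
    because no labeled node can reach them (lambda = 0 only).
    """

    nodes: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    method: str = ""
    lam: float = 0.0
    iterations: int = 0
    residual: float = 0.0
    converged: bool = True
    frozen: frozenset[str] = frozenset()

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=np.float64)
        if vals.shape != (len(self.nodes),):
            raise ValueError("values must align with nodes")
        object.__setattr__(self, "values", vals)

    def __getitem__(self, node) -> float:
        return float(self.values[self.nodes.index(str(node))])

    def __len__(self) -> int:
        return len(self.nodes)

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.nodes), name=self.method)

    def reindex(self, nodes: Iterable[str]) -> np.ndarray:
        """Values in the given node order."""
        pos = {v: i for i, v in enumerate(self.nodes)}
        return self.values[[pos[str(v)] for v in nodes]]

    def replace(self, **kw) -> "ScoreVector":
        d = {
            "nodes": self.nodes, "values": self.values, "method": self.method,
            "lam": self.lam, "iterations": self.iterations,
            "residual": self.residual, "converged": self.converged,
            "frozen": self.frozen,
        }
        d.update(kw)
        return ScoreVector(**d)


@dataclass(frozen=True)
class LinearSystem:
    """Sparse system f = M f + c over the unlabeled nodes.

    ``unlabeled`` lists the solved-for nodes in matrix order; ``frozen``
    nodes (unreachable from any label at lambda = 0) are excluded from the
    system and held at 0.5.  Positives/negatives record the fixed boundary.
    """

    nodes: tuple[str, ...]
    unlabeled: tuple[str, ...]
    M: sparse.csr_array = field(repr=False)
    c: np.ndarray = field(repr=False)
    lam: float
    positives: frozenset[str]
    negatives: frozenset[str]
    frozen: frozenset[str] = frozenset()

    def _assemble(self, f_u: np.ndarray, meta: dict) -> ScoreVector:
        idx = {v: i for i, v in enumerate(self.nodes)}
        vals = np.empty(len(self.nodes), dtype=np.float64)
        vals[:] = np.nan
        for v in self.positives:
            vals[idx[v]] = 1.0
        for v in self.negatives:
            vals[idx[v]] = 0.0
        for v in self.frozen:
            vals[idx[v]] = 0.5
        for v, x in zip(self.unlabeled, f_u):
            vals[idx[v]] = x
        return ScoreVector(
            nodes=self.nodes, values=vals, lam=self.lam,
            frozen=self.frozen, **meta,
        )


def build_system(
    g: WeightedGraph,
    labels: LabelAssignment,
    lam: float = 0.0,
    use_negatives: bool = True,
    eq8_count: bool = False,
    sink_nodes: Iterable[str] | None = None,
) -> LinearSystem:
    """Assemble M and c for a smoothing run.

    Parameters
    ----------
    lam
        Weight of the edge to the virtual negative sink, added to every
        denominator; 0 recovers plain harmonic smoothing.
    use_negatives
        If False the curated negatives are re-classed as unlabeled
        (SINKSOURCE+ ignores negative labels).
    eq8_count
        Use the raw count of positive neighbors as c's numerator instead of
        the weighted sum (the two coincide on unit-weight graphs).
    sink_nodes
        Restrict the lambda sink to these nodes (used by the multilayer
        construction); default attaches it to every node.

    Notes
    -----
    At lambda = 0, unlabeled nodes in a connected component containing no
    labeled node (isolated nodes included) can never receive label mass:
    they are excluded from the system, held at the 0.5 initialization, and
    reported via ``frozen``.  This keeps (I - M) nonsingular.
    """
    if lam < 0:
        raise ValueError(f"lambda must be >= 0, got {lam}")
    pos = labels.positives
    neg = labels.negatives if use_negatives else frozenset()
    nodes = g.nodes
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    labeled_mask = np.zeros(n, dtype=bool)
    pos_mask = np.zeros(n, dtype=bool)
    for v in pos:
        pos_mask[idx[v]] = True
        labeled_mask[idx[v]] = True
    for v in neg:
        labeled_mask[idx[v]] = True

    W = g.adjacency()
    d = g.weighted_degrees()
    lam_vec = np.zeros(n) if lam == 0 else np.full(n, float(lam))
    if sink_nodes is not None:
        mask = np.zeros(n, dtype=bool)
        for v in sink_nodes:
            mask[idx[str(v)]] = True
        lam_vec = np.where(mask, float(lam), 0.0)

    unlab = ~labeled_mask
    # nodes with zero denominator can never draw label mass: freeze at 0.5
    frozen_mask = np.zeros(n, dtype=bool)
    no_sink = unlab & (lam_vec == 0)
    if no_sink.any():
        _, comp = csgraph.connected_components(W, directed=False)
        comp_has_label = np.zeros(comp.max() + 1, dtype=bool)
        np.logical_or.at(comp_has_label, comp[labeled_mask], True)
        frozen_mask = no_sink & ~comp_has_label[comp]
    active = unlab & ~frozen_mask
    rows = np.flatnonzero(active)
    denom = lam_vec[rows] + d[rows]
    if len(rows) and not (denom > 0).all():
        raise SingularSystemError(
            "zero denominator for an active unlabeled node (should be frozen)"
        )
    sub = W[rows, :]
    inv = 1.0 / denom if len(rows) else denom
    M = sparse.csr_array(sparse.diags(inv) @ sub[:, rows])
    pos_cols = sub[:, np.flatnonzero(pos_mask)]
    if eq8_count:
        numer = np.diff(pos_cols.tocsr().indptr).astype(np.float64)
    else:
        numer = np.asarray(pos_cols.sum(axis=1)).ravel()
    c = numer * inv
    return LinearSystem(
        nodes=nodes,
        unlabeled=tuple(nodes[i] for i in rows),
        M=M,
        c=np.asarray(c, dtype=np.float64),
        lam=float(lam),
        positives=frozenset(pos),
        negatives=frozenset(neg),
        frozen=frozenset(nodes[i] for i in np.flatnonzero(frozen_mask)),
    )


def iterate(
    sys: LinearSystem,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
    method: str = "iterate",
) -> ScoreVector:
    """Run f_t = M f_{t-1} + c from f_0 = 0.5 until the L1 change <= epsilon.

    The residual is sum_v |f_t(v) - f_{t-1}(v)| over the unlabeled nodes
    (labeled nodes are constant, so summing over V is equivalent).  Stops
    after ``max_iter`` iterations regardless; ``converged`` records which.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    f = np.full(len(sys.unlabeled), 0.5)
    it, resid, converged = 0, 0.0, True
    if len(f):
        for it in range(1, max_iter + 1):
            f_new = sys.M @ f + sys.c
            if not np.isfinite(f_new).all():
                raise FloatingPointError(
                    "non-finite scores during iteration (malformed system)"
                )
            resid = float(np.abs(f_new - f).sum())
            f = f_new
            if resid <= epsilon:
                break
        converged = resid <= epsilon
    if not converged:
        log.warning("iteration stopped at max_iter=%d, residual %.3g", max_iter, resid)
    return sys._assemble(
        f,
        {"method": method, "iterations": it, "residual": resid,
         "converged": converged},
    )


def solve_direct(sys: LinearSystem, method: str = "direct") -> ScoreVector:
    """Exact fixed point of the smoothing iteration: solve (I - M) f = c.

    Used as the oracle for the iterative solver and available as an exact
    backend.  Raises :class:`SingularSystemError` when (I - M) is singular
    (an unlabeled block disconnected from every label at lambda = 0; such
    nodes are normally frozen at system-build time).
    """
    m = len(sys.unlabeled)
    if m == 0:
        return sys._assemble(np.empty(0), {"method": method})
    A = sparse.identity(m, format="csc") - sparse.csc_array(sys.M)
    try:
        f = spla.spsolve(A, sys.c)
    except RuntimeError as exc:  # umfpack/superlu singularity
        raise SingularSystemError(str(exc)) from exc
    f = np.atleast_1d(np.asarray(f, dtype=np.float64))
    if not np.isfinite(f).all():
        bad = [sys.unlabeled[i] for i in np.flatnonzero(~np.isfinite(f))[:5]]
        raise SingularSystemError(
            f"singular system: nodes {bad} receive no label mass"
        )
    return sys._assemble(f, {"method": method})


def _solve(sys, epsilon, max_iter, method, solver):
    if solver == "iterative":
        return iterate(sys, epsilon=epsilon, max_iter=max_iter, method=method)
    if solver == "direct":
        return solve_direct(sys, method=method)
    raise ValueError(f"unknown solver {solver!r}")


def sinksource(
    g: WeightedGraph,
    positives: Iterable[str],
    negatives: Iterable[str],
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
    solver: str = "iterative",
    eq8_count: bool = False,
) -> ScoreVector:
    """Harmonic smoothing with positives fixed at 1 and negatives at 0."""
    labels = LabelAssignment(frozenset(positives), frozenset(negatives), g)
    if not labels.negatives:
        raise ValueError("sinksource requires at least one negative")
    sys = build_system(g, labels, lam=0.0, use_negatives=True, eq8_count=eq8_count)
    return _solve(sys, epsilon, max_iter, "sinksource", solver)


def sinksource_plus(
    g: WeightedGraph,
    positives: Iterable[str],
    lam: float,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
    solver: str = "iterative",
    eq8_count: bool = False,
) -> ScoreVector:
    """Positives-only smoothing with a lambda-weighted negative sink.

    Curated negative labels, if any exist upstream, are ignored (the nodes
    are scored as unlabeled); the only negative influence is the sink.
    """
    if lam <= 0:
        raise ValueError("sinksource+ requires lambda > 0")
    labels = LabelAssignment(frozenset(positives), frozenset(), g)
    sys = build_system(g, labels, lam=lam, use_negatives=False, eq8_count=eq8_count)
    return _solve(sys, epsilon, max_iter, "sinksource+", solver)


def pseudo_sinksource_plus(
    g: WeightedGraph,
    positives: Iterable[str],
    negatives: Iterable[str],
    lam: float,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
    solver: str = "iterative",
    eq8_count: bool = False,
) -> ScoreVector:
    """Smoothing with curated negatives AND the lambda sink.

    With lambda = 0 this is exactly ``sinksource``.
    """
    labels = LabelAssignment(frozenset(positives), frozenset(negatives), g)
    sys = build_system(g, labels, lam=lam, use_negatives=True, eq8_count=eq8_count)
    return _solve(sys, epsilon, max_iter, "pseudo-sinksource+", solver)
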