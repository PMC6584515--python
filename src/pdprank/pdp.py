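"""Polygenic Disease Phenotype (PDP) scoring.

Given a disease with curated positives C_D and negatives Cbar_D, and a
biological process with curated positives C_P, two smoothing runs share
the disease negatives:

    f_D = learn(G, lambda, C_D, Cbar_D)
    f_P = learn(G, lambda, C_P, Cbar_D)

and the combined score is the product g(v) = f_D(v) * f_P(v): a node ranks
highly only if it is close to both the disease genes and the process genes.
At lambda = 0, nodes in C_D ^ C_P get g = 1 automatically, nodes labeled
only with the disease get g = f_P, and vice versa.

The union baseline runs a single smoothing with positives C_D u C_P and is
dominated by label membership: every labeled positive is fixed at 1 and
therefore outranks every unlabeled node.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd

from .labels import LabelAssignment, build_label_assignment
from .network import WeightedGraph
from .smoothing import (
    DEFAULT_EPSILON,
    DEFAULT_MAX_ITER,
    ScoreVector,
    pseudo_sinksource_plus,
)

__all__ = [
    "combined_score",
    "union_predictor",
    "normalize_scores",
    "rank_candidates",
    "filter_candidates",
    "pdp_scores",
]

log = logging.getLogger(__name__)

#: Columns of a candidate table, in order (Table-1 style schema).
CANDIDATE_COLUMNS = [
    "gene", "rank", "degree", "f_D", "f_P", "f_union", "g",
    "label_D", "label_P",
]


def combined_score(f_D: ScoreVector, f_P: ScoreVector) -> ScoreVector:
    """g(v) = f_D(v) * f_P(v) over a shared node universe."""
    if set(f_D.nodes) != set(f_P.nodes):
        raise ValueError("combined_score: score vectors cover different node sets")
    vals = f_D.values * f_P.reindex(f_D.nodes)
    return ScoreVector(
        nodes=f_D.nodes, values=vals, method="pdp-combined", lam=f_D.lam,
        frozen=f_D.frozen | f_P.frozen,
    )


def union_predictor(
    g: WeightedGraph,
    disease_positives: Iterable[str],
    process_positives: Iterable[str],
    disease_negatives: Iterable[str],
    lam: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
    solver: str = "iterative",
) -> ScoreVector:
    """f_{D u P}: one smoothing run with the pooled positive sets.

    Negatives that collide with the pooled positives are dropped from the
    negative side (curation rule: conflicted genes stay positive).
    """
    pos = {str(v) for v in disease_positives} | {str(v) for v in process_positives}
    neg = {str(v) for v in disease_negatives} - pos
    out = pseudo_sinksource_plus(
        g, pos, neg, lam=lam, epsilon=epsilon, max_iter=max_iter, solver=solver
    )
    return out.replace(method="union")


def normalize_scores(
    f: ScoreVector, reference: Iterable[str] | None = None
) -> ScoreVector:
    """Divide all scores by the maximum score over ``reference`` nodes.

    The reference defaults to all nodes, so output stays in [0, 1] with a
    maximum of exactly 1; with a narrower reference, scores outside it may
    exceed 1 (no clipping is applied).
    """
    if reference is None:
        ref_vals = f.values
    else:
        ref_vals = f.reindex([str(v) for v in reference])
        if ref_vals.size == 0:
            raise ValueError("normalize_scores: empty reference set")
    m = float(np.max(ref_vals))
    if m <= 0:
        raise ValueError("normalize_scores: maximum reference score is zero")
    return f.replace(values=f.values / m)


def _label_of(v: str, labels: LabelAssignment | None, classes: str) -> str:
    if labels is None:
        return "U"
    if v in labels.positives:
        return "P"
    if "N" in classes and v in labels.negatives:
        return "N"
    return "U"


def rank_candidates(
    g_scores: ScoreVector,
    f_D: ScoreVector,
    f_P: ScoreVector,
    f_union: ScoreVector | None,
    labels_D: LabelAssignment,
    process_positives: Iterable[str],
    graph: WeightedGraph,
) -> pd.DataFrame:
    """Build the full candidate table, ranked by g descending.

    Ties in g break by f_D descending, then f_P descending, then gene id
    ascending — fully deterministic.  Degree is the unweighted neighbor
    count.  ``label_D`` is P/N/U against the disease assignment; ``label_P``
    is P/U against the process positives.
    """
    nodes = list(g_scores.nodes)
    if set(nodes) != set(graph.nodes):
        raise ValueError("rank_candidates: scores do not cover the graph")
    proc_pos = {str(v) for v in process_positives}
    df = pd.DataFrame(
        {
            "gene": nodes,
            "degree": [graph.degree(v) for v in nodes],
            "f_D": f_D.reindex(nodes),
            "f_P": f_P.reindex(nodes),
            "f_union": f_union.reindex(nodes) if f_union is not None else np.nan,
            "g": g_scores.values,
            "label_D": [_label_of(v, labels_D, "PN") for v in nodes],
            "label_P": ["P" if v in proc_pos else "U" for v in nodes],
        }
    )
    df = df.sort_values(
        ["g", "f_D", "f_P", "gene"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df[CANDIDATE_COLUMNS]


def filter_candidates(
    table: pd.DataFrame, mode: str = "all", top: int | None = None
) -> pd.DataFrame:
    """Views of a candidate table.

    mode ``"unlabeled-any"`` keeps genes unlabeled in at least one of the
    two positive sets (the Table-1 view); ``"unlabeled-both"`` keeps genes
    unlabeled in both; ``"all"`` keeps everything.  ``top`` truncates after
    filtering by original rank.
    """
    if mode == "all":
        out = table
    elif mode == "unlabeled-any":
        out = table[(table["label_D"] != "P") | (table["label_P"] != "P")]
    elif mode == "unlabeled-both":
        out = table[(table["label_D"] != "P") & (table["label_P"] != "P")]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    out = out.copy()
    if top is not None:
        out = out.head(top)
    return out


def pdp_scores(
    graph: WeightedGraph,
    disease_positives: Iterable[str],
    disease_negatives: Iterable[str],
    process_positives: Iterable[str],
    lam: float = 1.0,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
    solver: str = "iterative",
    normalize: bool = True,
    with_union: bool = True,
) -> pd.DataFrame:
    """End-to-end PDP run: two smoothing passes, g, union baseline, table.

    Both passes use PSEUDO-SINKSOURCE+ with the SAME disease negatives (the
    process run borrows them so that candidates near process genes but
    likely unrelated to the disease are dampened).  f_D and f_P are
    optionally max-normalized (reference = all nodes); g is never
    normalized, and ranking uses full precision.
    """
    labels_D = build_label_assignment(
        disease_positives, disease_negatives, graph,
        extra_positive_sets=[process_positives],
    )
    labels_P = build_label_assignment(
        process_positives, labels_D.negatives, graph
    )
    kw = dict(lam=lam, epsilon=epsilon, max_iter=max_iter, solver=solver)
    f_D = pseudo_sinksource_plus(
        graph, labels_D.positives, labels_D.negatives, **kw
    )
    f_P = pseudo_sinksource_plus(
        graph, labels_P.positives, labels_P.negatives, **kw
    )
    if normalize:
        f_D = normalize_scores(f_D)
        f_P = normalize_scores(f_P)
    g = combined_score(f_D, f_P)
    f_u = None
    if with_union:
        f_u = union_predictor(
            graph, labels_D.positives, labels_P.positives, labels_D.negatives,
            lam=lam, epsilon=epsilon, max_iter=max_iter, solver=solver,
        )
    return rank_candidates(
        g, f_D, f_P, f_u, labels_D, labels_P.positives, graph
    )
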