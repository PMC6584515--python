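"""Evaluation harness: repeated k-fold CV, ROC/AUC, Welch's t-test, and
degree-bias diagnostics.

Cross-validation hides one k-th of the positives and one k-th of the
negatives per fold (stratified), refits the smoother on the remaining
labels, and scores the hidden nodes; AUC is the probability that a random
hidden positive outscores a random hidden negative, ties half-credited
(Mann-Whitney convention — exact score ties are common at lambda = 0).
Ten repeats of 5-fold CV give the standard 50 AUC values per experiment.

The degree-rank profile diagnoses the low-degree bias of plain harmonic
smoothing: nodes sorted by score, each with its unweighted degree, a
centered moving average (default window 15), and the mean degree of the
first m unlabeled nodes (default m = 100).
"""

from __future__ import annotations

import logging
from collections.abc import Callable, Iterable
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .labels import LabelAssignment
from .multilayer import multilayer_pss
from .network import WeightedGraph
from .smoothing import (
    DEFAULT_EPSILON,
    DEFAULT_MAX_ITER,
    ScoreVector,
    pseudo_sinksource_plus,
    sinksource,
    sinksource_plus,
)

__all__ = [
    "CVResult",
    "DegreeRankProfile",
    "kfold_split",
    "roc_auc",
    "cross_validate",
    "welch_t_test",
    "degree_rank_profile",
    "make_smoother",
]

log = logging.getLogger(__name__)

#: A smoother maps (graph, train labels) -> ScoreVector.
Smoother = Callable[[WeightedGraph, LabelAssignment], ScoreVector]


@dataclass(frozen=True)
class CVResult:
    """AUCs from repeated k-fold cross-validation.

    ``table`` is long-format with columns (repeat, fold, auc); there are
    exactly repeats x k rows.
    """

    table: pd.DataFrame = field(repr=False)
    method: str
    k: int
    repeats: int
    seed: int

    @property
    def aucs(self) -> np.ndarray:
        return self.table["auc"].to_numpy()

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def std_auc(self) -> float:
        return float(self.aucs.std(ddof=1))


def kfold_split(
    labels: LabelAssignment, k: int = 5, seed: int = 0
) -> list[tuple[LabelAssignment, frozenset[str], frozenset[str]]]:
    """Stratified k-fold split of the labeled nodes.

    Positives and negatives are independently partitioned into k near-equal
    folds; each element is ``(train, hidden_pos, hidden_neg)`` where the
    hidden nodes are unlabeled in ``train``.  The union of test folds is
    exactly the labeled set, pairwise disjoint.
    """
    n_pos, n_neg = len(labels.positives), len(labels.negatives)
    if n_pos < k or n_neg < k:
        raise ValueError(
            f"k={k} folds need >= {k} nodes per class "
            f"(have {n_pos} positives, {n_neg} negatives)"
        )
    nodes = np.array(sorted(labels.positives) + sorted(labels.negatives))
    y = np.array([1] * n_pos + [0] * n_neg)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    out = []
    for _, test_idx in skf.split(nodes, y):
        test = set(nodes[test_idx])
        hidden_pos = frozenset(labels.positives & test)
        hidden_neg = frozenset(labels.negatives & test)
        train = labels.relabel(
            labels.positives - hidden_pos, labels.negatives - hidden_neg
        )
        out.append((train, hidden_pos, hidden_neg))
    return out


def roc_auc(
    scores: ScoreVector, hidden_pos: Iterable[str], hidden_neg: Iterable[str]
) -> float:
    """AUC over the hidden labels: P(pos score > neg score) + 0.5 P(tie)."""
    hidden_pos = [str(v) for v in hidden_pos]
    hidden_neg = [str(v) for v in hidden_neg]
    if not hidden_pos or not hidden_neg:
        raise ValueError("roc_auc requires nonempty hidden positive and negative sets")
    if set(hidden_pos) & set(hidden_neg):
        raise ValueError("hidden positive and negative sets overlap")
    y_true = np.array([1] * len(hidden_pos) + [0] * len(hidden_neg))
    y_score = scores.reindex(hidden_pos + hidden_neg)
    return float(roc_auc_score(y_true, y_score))


def cross_validate(
    method: Smoother,
    labels: LabelAssignment,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> CVResult:
    """Repeated stratified k-fold CV of a smoother; returns repeats*k AUCs.

    Each repeat reshuffles the folds with a seed derived from ``seed``.
    The train assignment passed to the smoother contains no test-fold
    label, so scores of hidden nodes are genuine predictions.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(repeats):
        fold_seed = int(rng.integers(2**31 - 1))
        for fold, (train, hpos, hneg) in enumerate(
            kfold_split(labels, k=k, seed=fold_seed)
        ):
            f = method(labels.graph, train)
            rows.append(
                {"repeat": rep, "fold": fold, "auc": roc_auc(f, hpos, hneg)}
            )
    name = getattr(method, "__name__", repr(method))
    return CVResult(
        table=pd.DataFrame(rows), method=name, k=k, repeats=repeats, seed=seed
    )


def welch_t_test(
    a: Iterable[float], b: Iterable[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Welch's unequal-variance t-test comparing two AUC samples.

    Returns ``(t, p)`` with t = (mean_a - mean_b)/sqrt(s_a^2/n_a + s_b^2/n_b)
    and Welch-Satterthwaite degrees of freedom.  ``alternative`` is
    ``"two-sided"`` or ``"greater"`` (mean_a > mean_b).
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("welch_t_test needs at least two values per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("welch_t_test: both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class DegreeRankProfile:
    """Nodes by score rank with degrees and a centered moving average.

    ``table`` columns: rank (1..|V|), node, score, degree, label
    (P/N/U), moving_avg.
    """

    table: pd.DataFrame = field(repr=False)
    window: int

    def mean_degree_top_unlabeled(self, m: int = 100) -> float:
        """Mean unweighted degree of the first m unlabeled nodes by rank."""
        unl = self.table[self.table["label"] == "U"].head(m)
        if unl.empty:
            raise ValueError("no unlabeled nodes in the profile")
        return float(unl["degree"].mean())


def degree_rank_profile(
    scores: ScoreVector,
    graph: WeightedGraph,
    labels: LabelAssignment | None = None,
    window: int = 15,
) -> DegreeRankProfile:
    """Rank all nodes by score and report degree versus rank.

    Ties break by node id ascending (deterministic).  The moving average is
    centered with width ``window`` (shrunk at the boundaries).  ``labels``
    classifies each node P/N/U for the profile; without it every node is U.
    """
    if window < 1 or window > len(graph.nodes):
        raise ValueError(f"window must be in [1, |V|], got {window}")
    nodes = list(scores.nodes)
    if set(nodes) != set(graph.nodes):
        raise ValueError("degree_rank_profile: scores do not cover the graph")
    df = pd.DataFrame(
        {
            "node": nodes,
            "score": scores.values,
            "degree": [graph.degree(v) for v in nodes],
        }
    )
    if labels is None:
        df["label"] = "U"
    else:
        df["label"] = [
            "P" if v in labels.positives
            else "N" if v in labels.negatives
            else "U"
            for v in nodes
        ]
    df = df.sort_values(
        ["score", "node"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df["moving_avg"] = (
        df["degree"].rolling(window, center=True, min_periods=1).mean()
    )
    return DegreeRankProfile(table=df, window=window)


def make_smoother(
    name: str,
    lam: float = 0.0,
    epsilon: float = DEFAULT_EPSILON,
    max_iter: int = DEFAULT_MAX_ITER,
    solver: str = "iterative",
    layers: int = 2,
    omega: float = 1.0,
    seed: int = 0,
) -> Smoother:
    """Factory of smoothers usable with :func:`cross_validate`.

    ``name`` is one of ``"sinksource"``, ``"sinksource+"``,
    ``"pseudo-sinksource+"``, ``"multilayer"``.  The returned callable takes
    ``(graph, labels)`` and ignores whatever a given method ignores (e.g.
    SINKSOURCE+ discards the negative labels).
    """
    kw = dict(epsilon=epsilon, max_iter=max_iter, solver=solver)

    if name == "sinksource":
        def fit(g, labels):
            return sinksource(g, labels.positives, labels.negatives, **kw)
    elif name == "sinksource+":
        def fit(g, labels):
            return sinksource_plus(g, labels.positives, lam=lam, **kw)
    elif name == "pseudo-sinksource+":
        def fit(g, labels):
            return pseudo_sinksource_plus(
                g, labels.positives, labels.negatives, lam=lam, **kw
            )
    elif name == "multilayer":
        def fit(g, labels):
            return multilayer_pss(
                g, labels.positives, labels.negatives, lam=lam,
                l=layers, omega=omega, seed=seed, **kw,
            )
    else:
        raise ValueError(f"unknown method {name!r}")
    fit.__name__ = name if lam == 0 else f"{name}(lam={lam:g})"
    return fit
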