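"""Score aggregation over signed graphs and evaluation against pruned signs.

The aggregate of nodal scores X_n over a graph G is

    X_G = sum_n S_{n->REF}(G) * X_n

with S the effective weights — exact signs on a balanced graph, a
spanning-tree average otherwise.  Equivalently X_G is the mean over
(enumerated or sampled) spanning trees of the per-tree aggregates X(t);
both routes are provided and coincide when fed the same trees.

The per-tree score distribution also yields the "most representative
spanning tree" t*, the tree whose aggregate is closest to X_G, and the
balanced subgraph G* obtained by augmenting t* with every sign-consistent
non-tree edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .exact import SpanningTree, tree_score, tree_signs
from .graph import SignedGraph, check_balance, resolve_scores
from .sampler import SampledTreeRecord, WalkConfig, estimate_effective_weights
from .weights import EffectiveWeights


@dataclass
class AggregationResult:
    """An aggregated score with provenance and optional tree-level detail."""

    x_g: float
    method: str  # balanced-exact | enumeration-exact | sst-sampled
    per_tree_scores: list[float] | None = None
    representative_tree: SpanningTree | None = None
    representative_subgraph_edges: tuple[int, ...] | None = None


@dataclass
class ComparisonResult:
    """Classification metrics of effective weights against reference signs.

    ``mislabel_rate`` is the zero-threshold sign disagreement (an exactly
    zero weight counts as mislabeled: it carries no direction).  The ROC
    treats the reference sign +1 as the positive class and the weight S as
    the score; ``auroc`` is None when only one class is present.
    """

    mislabel_rate: float
    roc_points: list[tuple[float, float]]
    auroc: float | None
    per_node_table: "object" = None  # pandas.DataFrame: node, S, s, agree


def aggregate(
    weights: EffectiveWeights,
    scores: Mapping[str, float],
    impute_zero: bool = False,
) -> AggregationResult:
    """X_G = sum_n S_n * X_n, identically for exact or sampled weights."""
    total = 0.0
    for n in weights.nodes:
        if n in scores:
            x = float(scores[n])
        elif impute_zero:
            x = 0.0
        else:
            from .errors import MissingScoreError

            raise MissingScoreError(
                f"node {n!r} has no score; pass impute_zero=True to treat it as 0"
            )
        total += weights[n] * x
    method = "enumeration-exact" if weights.exact else "sst-sampled"
    return AggregationResult(x_g=float(total), method=method)


def per_tree_distribution(
    trees: Sequence[SampledTreeRecord | SpanningTree],
    scores: Mapping[str, float],
    impute_zero: bool = False,
) -> AggregationResult:
    """Aggregate via the per-tree score distribution (mean of X(t)).

    Also identifies the most representative spanning tree t* minimizing
    |X(t) - X_G| (first in input order on ties) and the balanced subgraph
    G*: t* plus every non-tree edge (u, v, sigma) of the parent graph whose
    endpoint signs under t* satisfy s_u * s_v = sigma.
    """
    if len(trees) == 0:
        raise ValueError("per_tree_distribution needs at least one tree")
    plain: list[SpanningTree] = [
        t.tree if isinstance(t, SampledTreeRecord) else t for t in trees
    ]
    sampled = any(isinstance(t, SampledTreeRecord) for t in trees)
    per_tree = [tree_score(t, scores, impute_zero) for t in plain]
    x_g = float(np.mean(per_tree))
    best = min(range(len(per_tree)), key=lambda i: abs(per_tree[i] - x_g))
    t_star = plain[best]
    g_star = _consistent_subgraph_edges(t_star)
    return AggregationResult(
        x_g=x_g,
        method="sst-sampled" if sampled else "enumeration-exact",
        per_tree_scores=per_tree,
        representative_tree=t_star,
        representative_subgraph_edges=g_star,
    )


def _consistent_subgraph_edges(tree: SpanningTree) -> tuple[int, ...]:
    """Edge indices of G* = tree + all sign-consistent non-tree edges."""
    g = tree.parent
    s = tree_signs(tree)
    in_tree = set(tree.edge_indices)
    keep = list(tree.edge_indices)
    for k, e in enumerate(g.edges):
        if k in in_tree:
            continue
        if s[e.source] * s[e.target] == e.sign:
            keep.append(k)
    return tuple(sorted(keep))


def aggregate_scores(
    graph: SignedGraph,
    scores: Mapping[str, float],
    method: str = "auto",
    cfg: WalkConfig | None = None,
    cap: int = 10**6,
    impute_zero: bool = False,
) -> AggregationResult:
    """High-level aggregation pipeline choosing the appropriate route.

    ``method='auto'`` uses the balanced closed form when the graph is
    balanced and the sampler otherwise; ``'exact'`` forces enumeration
    (small graphs), ``'sample'`` forces the Monte-Carlo route.  The exact
    and sampled routes return the per-tree distribution and t*/G*.
    """
    if method not in ("auto", "exact", "sample"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        report = check_balance(graph)
        if report.balanced:
            x = resolve_scores(graph, scores, impute_zero)
            x_g = float(sum(report.node_signs[n] * x[n] for n in graph.nodes))
            return AggregationResult(x_g=x_g, method="balanced-exact")
        method = "sample"
    if method == "exact":
        from .exact import enumerate_spanning_trees

        trees = list(enumerate_spanning_trees(graph, cap=cap))
        return per_tree_distribution(trees, scores, impute_zero)
    _, records = estimate_effective_weights(graph, cfg, return_records=True)
    return per_tree_distribution(records, scores, impute_zero)


def compare_to_reference_signs(
    weights: EffectiveWeights | Mapping[str, float],
    reference_signs: Mapping[str, int],
) -> ComparisonResult:
    """Score the effective weights against pruned-network nodal signs.

    ``mislabel_rate`` is the fraction of shared nodes whose weight sign
    disagrees with the reference sign at zero threshold.  The ROC curve is a
    threshold sweep over the weight values with s = +1 as the positive class;
    the AUROC is its trapezoidal integral.
    """
    import pandas as pd
    from sklearn.metrics import roc_curve

    s_map = dict(weights.weights) if isinstance(weights, EffectiveWeights) else dict(weights)
    nodes = [n for n in s_map if n in reference_signs]
    if not nodes:
        raise ValueError("no shared nodes between weights and reference signs")
    for n in nodes:
        if reference_signs[n] not in (-1, 1):
            raise ValueError(
                f"reference sign of node {n!r} must be -1 or +1, "
                f"got {reference_signs[n]!r}"
            )
    s_vals = np.array([s_map[n] for n in nodes], dtype=float)
    ref = np.array([reference_signs[n] for n in nodes], dtype=int)

    agree = np.sign(s_vals) == ref  # sign() of 0 is 0: zero weights mislabeled
    mislabel_rate = float(1.0 - np.mean(agree))

    labels = (ref > 0).astype(int)
    if labels.min() == labels.max():
        roc_points: list[tuple[float, float]] = []
        auroc = None
    else:
        fpr, tpr, _ = roc_curve(labels, s_vals)
        roc_points = list(zip(fpr.tolist(), tpr.tolist()))
        auroc = float(np.trapezoid(tpr, fpr))

    table = pd.DataFrame(
        {"node": nodes, "S": s_vals, "s": ref, "agree": agree}
    )
    return ComparisonResult(
        mislabel_rate=mislabel_rate,
        roc_points=roc_points,
        auroc=auroc,
        per_node_table=table,
    )
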