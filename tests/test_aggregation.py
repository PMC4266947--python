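"""Aggregation over effective weights, per-tree distribution, t*/G*, evaluation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sstagg import (
    MissingScoreError,
    SignedEdge,
    SignedGraph,
    WalkConfig,
    aggregate,
    aggregate_balanced,
    aggregate_scores,
    compare_to_reference_signs,
    enumerate_spanning_trees,
    estimate_effective_weights,
    exact_effective_weights,
    per_tree_distribution,
    random_scores,
    tree_signs,
)
from conftest import make_balanced, small_random_graphs


# ---------------------------------------------------------------------------
# aggregate = sum_n S_n X_n
# ---------------------------------------------------------------------------

def test_iffl_aggregate_is_five_thirds(iffl_graph):
    ew = exact_effective_weights(iffl_graph)
    res = aggregate(ew, {"A": 1, "B": 1, "C": 1})
    assert res.x_g == pytest.approx(5 / 3, abs=1e-12)
    assert res.method == "enumeration-exact"


def test_aggregate_zero_scores(iffl_graph):
    ew = exact_effective_weights(iffl_graph)
    assert aggregate(ew, {"A": 0, "B": 0, "C": 0}).x_g == 0.0


def test_aggregate_matches_balanced_route(chain_graph):
    ew = exact_effective_weights(chain_graph)
    x = {"A": 1, "B": 1, "C": 1}
    assert aggregate(ew, x).x_g == aggregate_balanced(chain_graph, x) == 1.0


def test_aggregate_missing_score(iffl_graph):
    ew = exact_effective_weights(iffl_graph)
    with pytest.raises(MissingScoreError):
        aggregate(ew, {"A": 1})
    assert aggregate(ew, {"A": 1}, impute_zero=True).x_g == 1.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(
    alpha=st.floats(-5, 5, allow_nan=False),
    seed=st.integers(0, 20),
)
def test_aggregate_linearity(alpha, seed):
    """aggregate(S, a*X + Y) == a*aggregate(S, X) + aggregate(S, Y)."""
    g = small_random_graphs(1, force_unbalanced=True, seed0=2000 + seed)[0]
    ew = exact_effective_weights(g)
    x = random_scores(g.nodes, "gaussian", seed=seed)
    y = random_scores(g.nodes, "gaussian", seed=seed + 999)
    combo = {n: alpha * x[n] + y[n] for n in g.nodes}
    lhs = aggregate(ew, combo).x_g
    rhs = alpha * aggregate(ew, x).x_g + aggregate(ew, y).x_g
    assert lhs == pytest.approx(rhs, abs=1e-9 * (1 + abs(rhs)))


def test_aggregate_bounded_by_score_mass():
    """|X_G| <= sum_n |X_n| since |S_n| <= 1."""
    for i, g in enumerate(small_random_graphs(10, force_unbalanced=True, seed0=2100)):
        x = random_scores(g.nodes, "gaussian", seed=i)
        ew = exact_effective_weights(g)
        assert abs(aggregate(ew, x).x_g) <= sum(abs(v) for v in x.values()) + 1e-12


# ---------------------------------------------------------------------------
# per-tree distribution, t* and G*
# ---------------------------------------------------------------------------

def test_iffl_per_tree_distribution(iffl_graph):
    trees = list(enumerate_spanning_trees(iffl_graph))
    res = per_tree_distribution(trees, {"A": 1, "B": 1, "C": 1})
    assert res.per_tree_scores == [3.0, 1.0, 1.0]
    assert res.x_g == pytest.approx(5 / 3)
    # |1 - 5/3| < |3 - 5/3|: t* is the first of the two score-1 trees
    assert res.representative_tree.edge_indices == trees[1].edge_indices
    assert res.method == "enumeration-exact"


def test_single_tree_distribution(chain_graph):
    trees = list(enumerate_spanning_trees(chain_graph))
    res = per_tree_distribution(trees, {"A": 2, "B": 1, "C": 1})
    assert res.x_g == res.per_tree_scores[0]
    assert res.representative_tree is trees[0]


def test_per_tree_distribution_empty_errors():
    with pytest.raises(ValueError, match="at least one"):
        per_tree_distribution([], {})


def test_iffl_mixed_scores_brute_force(iffl_graph):
    """X = (1, 1, -1): hand computation over the three trees.

    t1={A->B,A->C}: 1+1-1=1; t2={A->B,B-|C}: 1+1+1=3; t3={A->C,B-|C}: 1-1-1=-1.
    Mean = 1; t* = t1 (|1-1| = 0).
    """
    trees = list(enumerate_spanning_trees(iffl_graph))
    res = per_tree_distribution(trees, {"A": 1, "B": 1, "C": -1})
    assert res.per_tree_scores == [1.0, 3.0, -1.0]
    assert res.x_g == pytest.approx(1.0)
    assert res.representative_tree.edge_indices == trees[0].edge_indices


def test_estimator_identity_on_sampled_trees():
    """mean of per-tree scores == sum_n S_n X_n for the same sampled tree set."""
    for i, g in enumerate(small_random_graphs(5, force_unbalanced=True, seed0=2200)):
        x = random_scores(g.nodes, "gaussian", seed=i)
        cfg = WalkConfig(n_trees=300, seed=i)
        ew, records = estimate_effective_weights(g, cfg, return_records=True)
        res = per_tree_distribution(records, x)
        assert res.method == "sst-sampled"
        node_sum = sum(ew[n] * x[n] for n in g.nodes)
        assert res.x_g == pytest.approx(node_sum, abs=1e-9)


def test_representative_subgraph_contains_tree_and_is_balanced(iffl_graph):
    """G* contains t* plus exactly the sign-consistent non-tree edges; under
    t*'s sign vector every retained edge is consistent (G* is balanced)."""
    for i, g in enumerate(
        [iffl_graph] + small_random_graphs(5, force_unbalanced=True, seed0=2300)
    ):
        x = random_scores(g.nodes, "gaussian", seed=i)
        res = per_tree_distribution(list(enumerate_spanning_trees(g)), x)
        t_star = res.representative_tree
        keep = set(res.representative_subgraph_edges)
        assert set(t_star.edge_indices) <= keep
        s = tree_signs(t_star)
        for k, e in enumerate(g.edges):
            consistent = s[e.source] * s[e.target] == e.sign
            assert (k in keep) == (consistent or k in t_star.edge_indices)
            if k in keep:
                assert consistent


def test_iffl_g_star_excludes_discrepant_edge(iffl_graph):
    """With unit scores the representative tree omits the inhibiting edge's
    contradiction: G* = t* plus the one consistent non-tree edge."""
    res = per_tree_distribution(
        list(enumerate_spanning_trees(iffl_graph)), {"A": 1, "B": 1, "C": 1}
    )
    # t* = {A->B, B-|C}; A->C (index 1) is inconsistent with signs (+1,+1,-1)
    assert res.representative_subgraph_edges == (0, 2)


def test_aggregate_scores_pipeline_routes(iffl_graph, chain_graph):
    x3 = {"A": 1, "B": 1, "C": 1}
    balanced = aggregate_scores(chain_graph, x3)
    assert balanced.method == "balanced-exact" and balanced.x_g == 1.0
    exact = aggregate_scores(iffl_graph, x3, method="exact")
    assert exact.method == "enumeration-exact"
    assert exact.x_g == pytest.approx(5 / 3)
    sampled = aggregate_scores(iffl_graph, x3, cfg=WalkConfig(n_trees=2000, seed=4))
    assert sampled.method == "sst-sampled"
    assert abs(sampled.x_g - 5 / 3) < 0.1


# ---------------------------------------------------------------------------
# comparison against pruned-network signs
# ---------------------------------------------------------------------------

def test_perfect_agreement():
    s = {"A": 1.0, "B": 0.4, "C": -0.9}
    ref = {"A": 1, "B": 1, "C": -1}
    res = compare_to_reference_signs(s, ref)
    assert res.mislabel_rate == 0.0
    assert res.auroc == 1.0


def test_perfect_disagreement():
    s = {"A": -1.0, "B": -0.4, "C": 0.9}
    ref = {"A": 1, "B": 1, "C": -1}
    res = compare_to_reference_signs(s, ref)
    assert res.mislabel_rate == 1.0
    assert res.auroc == 0.0


def test_zero_weight_counts_as_mislabeled():
    res = compare_to_reference_signs({"A": 0.0, "B": 1.0}, {"A": 1, "B": 1})
    assert res.mislabel_rate == pytest.approx(0.5)


def test_invalid_reference_signs_rejected():
    with pytest.raises(ValueError, match="-1 or \\+1"):
        compare_to_reference_signs({"A": 0.5}, {"A": 0})


def test_single_class_auroc_undefined():
    res = compare_to_reference_signs({"A": 0.5, "B": 0.9}, {"A": 1, "B": 1})
    assert res.auroc is None and res.roc_points == []


def _brute_force_roc(scores, labels):
    """Threshold sweep oracle: for every threshold between distinct scores,
    predict positive when score >= threshold; integrate TPR over FPR."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels.sum()
    neg = len(labels) - pos
    thresholds = np.concatenate([[np.inf], np.unique(scores)[::-1]])
    pts = []
    for th in thresholds:
        pred = scores >= th
        tpr = (pred & (labels == 1)).sum() / pos
        fpr = (pred & (labels == 0)).sum() / neg
        pts.append((fpr, tpr))
    pts.sort()
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return np.trapezoid(ys, xs)


def test_four_node_case_against_threshold_sweep_oracle():
    s = {"A": 1.0, "B": 0.5, "C": -0.2, "D": 0.1}
    ref = {"A": 1, "B": 1, "C": 1, "D": -1}
    res = compare_to_reference_signs(s, ref)
    # mislabels: C (negative weight, ref +1) and D (positive weight, ref -1)
    assert res.mislabel_rate == pytest.approx(0.5)
    oracle = _brute_force_roc([1.0, 0.5, -0.2, 0.1], [1, 1, 1, 0])
    assert res.auroc == pytest.approx(oracle)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_random_roc_against_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 40
    scores = rng.uniform(-1, 1, n)
    labels = rng.choice([(-1), 1], n)
    if labels.min() == labels.max():  # pragma: no cover
        labels[0] = -labels[0]
    s_map = {f"n{i}": float(scores[i]) for i in range(n)}
    ref = {f"n{i}": int(labels[i]) for i in range(n)}
    res = compare_to_reference_signs(s_map, ref)
    oracle = _brute_force_roc(scores, (labels > 0).astype(int))
    assert res.auroc == pytest.approx(oracle, abs=1e-12)
    # AUROC equals the trapezoid integral of the reported ROC points
    xs = [p[0] for p in res.roc_points]
    ys = [p[1] for p in res.roc_points]
    assert res.auroc == pytest.approx(float(np.trapezoid(ys, xs)), abs=1e-12)


def test_recovering_pruned_signs_on_synthetic_ground_truth():
    """Build a balanced graph (known signs), add one discrepant edge, and check
    the effective weights still classify the original signs well."""
    base = make_balanced(
        small_random_graphs(1, max_nodes=8, force_unbalanced=False, seed0=2400)[0],
        seed=5,
    )
    from sstagg import check_balance

    truth = dict(check_balance(base).node_signs)
    # one flipped extra edge between two existing nodes creates inconsistency
    u, v = base.nodes[1], base.nodes[-1]
    extra = SignedEdge(u, v, -truth[u] * truth[v])
    g = SignedGraph(list(base.edges) + [extra], reference=base.reference, nodes=base.nodes)
    ew = exact_effective_weights(g)
    res = compare_to_reference_signs(ew, truth)
    assert res.mislabel_rate <= 0.25
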