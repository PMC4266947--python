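"""Exhaustive spanning-tree machinery: enumeration, counting, exact weights.

This is the oracle side of the package.  For graphs whose spanning trees can
be enumerated, the effective nodal weights

    S_{n->REF}(G) = (1/N(G)) * sum_t s_{n->REF}(t)

are computed exactly (rational arithmetic), the per-tree aggregates

    X(t) = sum_n s_{n->REF}(t) * X_n

are evaluated tree by tree, and the line index of balance z (minimum number
of edge deletions making the graph balanced) is found by brute force.  The
Monte-Carlo sampler is validated against these quantities on small graphs.

Every spanning tree is balanced by construction, so its path signs are
unambiguous even when the parent graph is not.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Mapping, Sequence

import sympy

from .errors import EnumerationCapError
from .graph import SignedGraph, check_balance, resolve_scores
from .weights import EffectiveWeights

#: Default ceiling on the number of trees the exact engine will enumerate.
DEFAULT_TREE_CAP = 10**6


@dataclass(frozen=True)
class SpanningTree:
    """A spanning tree of a parent signed graph, stored as edge indices.

    Storing indices (positions in ``parent.edges``) rather than edge values
    keeps parallel edges distinct: two value-identical parallel edges give
    two different spanning trees.
    """

    parent: SignedGraph
    edge_indices: tuple[int, ...]

    @property
    def edges(self):
        return tuple(self.parent.edges[k] for k in self.edge_indices)

    def validate(self) -> None:
        """Check the spanning-tree invariants: size, spanning, acyclic."""
        g = self.parent
        if len(self.edge_indices) != g.n_nodes - 1:
            raise ValueError(
                f"tree has {len(self.edge_indices)} edges, expected {g.n_nodes - 1}"
            )
        if len(set(self.edge_indices)) != len(self.edge_indices):
            raise ValueError("repeated edge index in spanning tree")
        parent_uf = list(range(g.n_nodes))

        def find(i: int) -> int:
            while parent_uf[i] != i:
                parent_uf[i] = parent_uf[parent_uf[i]]
                i = parent_uf[i]
            return i

        for k in self.edge_indices:
            e = g.edges[k]
            a, b = find(g.node_index(e.source)), find(g.node_index(e.target))
            if a == b:
                raise ValueError(f"edge {e} closes a cycle in the claimed tree")
            parent_uf[a] = b
        # n-1 acyclic edges on n nodes necessarily span


def tree_signs(tree: SpanningTree) -> dict[str, int]:
    """Path sign of every node relative to REF along the unique tree path.

    The result is the sign vector s_{n->REF}(t) in {-1,+1}; it satisfies
    s_u * s_v = sigma for every tree edge (u, v, sigma).
    """
    g = tree.parent
    adj: dict[int, list[tuple[int, int]]] = {i: [] for i in range(g.n_nodes)}
    for k in tree.edge_indices:
        e = g.edges[k]
        u, v = g.node_index(e.source), g.node_index(e.target)
        adj[u].append((v, e.sign))
        adj[v].append((u, e.sign))
    signs = [0] * g.n_nodes
    ref = g.node_index(g.reference)
    signs[ref] = 1
    stack = [ref]
    while stack:
        u = stack.pop()
        for v, sigma in adj[u]:
            if signs[v] == 0:
                signs[v] = signs[u] * sigma
                stack.append(v)
    if any(s == 0 for s in signs):
        raise ValueError("edge set does not span the graph")
    return {g.nodes[i]: signs[i] for i in range(g.n_nodes)}


def tree_score(tree: SpanningTree, scores: Mapping[str, float], impute_zero: bool = False) -> float:
    """Aggregate nodal scores over one spanning tree: X(t) = sum_n s_{n->REF}(t) X_n."""
    x = resolve_scores(tree.parent, scores, impute_zero)
    s = tree_signs(tree)
    return float(sum(s[n] * x[n] for n in tree.parent.nodes))


def count_spanning_trees(graph: SignedGraph) -> int:
    """Number of spanning trees N(G) by the matrix-tree theorem.

    The determinant of the reduced (multigraph) Laplacian is evaluated in
    exact integer arithmetic, so the count is correct for any size.
    """
    graph.require_connected("spanning-tree counting")
    n = graph.n_nodes
    if n == 1:
        return 1
    lap = [[0] * n for _ in range(n)]
    for e in graph.edges:
        u, v = graph.node_index(e.source), graph.node_index(e.target)
        lap[u][u] += 1
        lap[v][v] += 1
        lap[u][v] -= 1
        lap[v][u] -= 1
    reduced = sympy.Matrix([row[1:] for row in lap[1:]])
    return int(reduced.det())


def enumerate_spanning_trees(
    graph: SignedGraph, cap: int = DEFAULT_TREE_CAP
) -> Iterator[SpanningTree]:
    """Yield every spanning tree of the (multi)graph exactly once.

    Contraction–deletion recursion with deterministic edge ordering: the
    trees containing the first edge are the trees of the graph with that
    edge contracted, the rest are the trees of the graph with it deleted.
    Parallel edges yield distinct trees.  Refuses graphs whose matrix-tree
    count exceeds ``cap`` and points the caller to the sampler.
    """
    graph.require_connected("spanning-tree enumeration")
    n_trees = count_spanning_trees(graph)
    if n_trees > cap:
        raise EnumerationCapError(
            f"graph has {n_trees} spanning trees (> cap {cap}); "
            "use the Monte-Carlo sampler (estimate_effective_weights)"
        )

    n = graph.n_nodes
    edges = [
        (graph.node_index(e.source), graph.node_index(e.target), k)
        for k, e in enumerate(graph.edges)
    ]

    def connected(active_edges: list[tuple[int, int, int]], labels: list[int]) -> bool:
        comps = len(set(labels))
        if comps == 1:
            return True
        uf = {c: c for c in set(labels)}

        def find(i: int) -> int:
            while uf[i] != i:
                uf[i] = uf[uf[i]]
                i = uf[i]
            return i

        merged = 0
        for u, v, _ in active_edges:
            a, b = find(labels[u]), find(labels[v])
            if a != b:
                uf[a] = b
                merged += 1
                if merged == comps - 1:
                    return True
        return merged == comps - 1

    def recurse(
        active: list[tuple[int, int, int]], labels: list[int], chosen: list[int]
    ) -> Iterator[tuple[int, ...]]:
        if len(set(labels)) == 1:
            yield tuple(sorted(chosen))
            return
        # skip contracted self-loops deterministically
        i = 0
        while i < len(active) and labels[active[i][0]] == labels[active[i][1]]:
            i += 1
        if i == len(active):
            return  # disconnected remainder: no trees
        active = active[i:]
        u, v, k = active[0]
        # branch 1: trees containing edge k -> contract its endpoints
        lu, lv = labels[u], labels[v]
        contracted = [lv if l == lu else l for l in labels]
        yield from recurse(active[1:], contracted, chosen + [k])
        # branch 2: trees avoiding edge k -> delete it (if still connected)
        rest = active[1:]
        if connected(rest, labels):
            yield from recurse(rest, labels, chosen)

    seen_count = 0
    for idxs in recurse(edges, list(range(n)), []):
        seen_count += 1
        yield SpanningTree(parent=graph, edge_indices=idxs)
    assert seen_count == n_trees, "enumeration disagrees with matrix-tree count"


def exact_effective_weights(
    graph: SignedGraph, cap: int = DEFAULT_TREE_CAP
) -> EffectiveWeights:
    """Exact effective weights S_{n->REF}(G) by averaging signs over all trees.

    Internally rational: on a balanced graph the result is bit-exact +/-1 and
    equals the propagated nodal signs.
    """
    n_plus = {n: 0 for n in graph.nodes}
    n_minus = {n: 0 for n in graph.nodes}
    total = 0
    for tree in enumerate_spanning_trees(graph, cap=cap):
        total += 1
        for n, s in tree_signs(tree).items():
            if s > 0:
                n_plus[n] += 1
            else:
                n_minus[n] += 1
    exact_values = {
        n: Fraction(n_plus[n] - n_minus[n], total) for n in graph.nodes
    }
    ew = EffectiveWeights.from_sign_counts(
        n_plus, n_minus, exact=True, exact_values=exact_values
    )
    # float division of small ints is exact for +/-1; make the general case
    # follow the rationals to full double precision
    ew.weights = {n: float(exact_values[n]) for n in graph.nodes}
    return ew


def line_index_of_balance(
    graph: SignedGraph, cap: int = 2 * 10**6
) -> tuple[int, tuple[int, ...]]:
    """Minimum number z of edge deletions that balance the graph, by brute force.

    Returns ``(z, edge_indices)`` where the indices witness one minimal
    deletion set.  Deletions may disconnect the graph, so balance is checked
    component-wise (no cycle with negative sign product in any component).
    This is a test oracle: the subset search is exponential and refuses
    instances where the number of candidate subsets exceeds ``cap``.
    """
    graph.require_connected("line index of balance")
    if check_balance(graph).balanced:
        return 0, ()

    m = graph.n_edges
    examined = 0
    for z in range(1, m + 1):
        for subset in itertools.combinations(range(m), z):
            examined += 1
            if examined > cap:
                raise EnumerationCapError(
                    f"line-index search exceeded {cap} deletion subsets; "
                    "graph too large for the brute-force oracle"
                )
            if _balanced_after_deletion(graph, set(subset)):
                return z, subset
    raise AssertionError("unreachable: deleting all edges always balances")


def _balanced_after_deletion(graph: SignedGraph, removed: set[int]) -> bool:
    """Component-wise balance check of the graph minus the removed edges."""
    n = graph.n_nodes
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for k, e in enumerate(graph.edges):
        if k in removed:
            continue
        u, v = graph.node_index(e.source), graph.node_index(e.target)
        adj[u].append((v, e.sign))
        adj[v].append((u, e.sign))
    sign = [0] * n
    for start in range(n):
        if sign[start] != 0:
            continue
        sign[start] = 1
        stack = [start]
        while stack:
            u = stack.pop()
            for v, sigma in adj[u]:
                if sign[v] == 0:
                    sign[v] = sign[u] * sigma
                    stack.append(v)
                elif sign[v] != sign[u] * sigma:
                    return False
    return True
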