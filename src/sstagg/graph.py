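"""Signed-graph data model, balance (causal-consistency) analysis and balanced aggregation.

A causal network model is represented as a signed multigraph: nodes are
biological entities, edges carry a sign (+1 "A -> B": an increase in A causes
an increase in B; -1 "A -| B": an increase in A causes a decrease in B) and
optionally a semantic edge class used to weight random-walk traversal.  One
node is designated the *reference* node; it fixes the absolute sign convention
of the network.

Edge direction is stored for provenance but is ignored by balance analysis,
path signs and walker traversal: the sign of a node relative to the reference
is the product of edge signs along a non-oriented path.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import (
    DisconnectedGraphError,
    MissingScoreError,
    UnbalancedGraphError,
)

#: Relative traversal probabilities for the semantic edge classes of
#: BEL-encoded causal network models.  Intramolecular edges (a molecule and
#: its activity) are the most likely to be retained in a sampled tree;
#: expression edges (leading to changes in RNA abundance) the least, because
#: they act on longer timescales and often close feedback loops.
DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "intramolecular": 1.0,
    "direct": 1.0 / 2.0,
    "indirect": 1.0 / 3.0,
    "expression": 1.0 / 4.0,
    "default": 1.0,
}

EDGE_CLASSES = frozenset(DEFAULT_CLASS_WEIGHTS)


@dataclass(frozen=True)
class SignedEdge:
    """A signed, optionally class-annotated edge of a causal network model.

    Parallel edges between the same node pair are legitimate (a model may
    assert several relations between two entities, including contradictory
    ones); within a :class:`SignedGraph` each edge is identified by its
    position in the edge list, so value-identical parallel edges remain
    distinct tree members and traversal choices.
    """

    source: str
    target: str
    sign: int
    edge_class: str = "default"

    def __post_init__(self) -> None:
        if self.sign not in (-1, 1):
            raise ValueError(f"edge sign must be -1 or +1, got {self.sign!r}")
        if self.edge_class not in EDGE_CLASSES:
            raise ValueError(
                f"unknown edge class {self.edge_class!r}; expected one of {sorted(EDGE_CLASSES)}"
            )

    @property
    def traversal_weight(self) -> float:
        """Relative traversal probability derived from the edge class."""
        return DEFAULT_CLASS_WEIGHTS[self.edge_class]

    def endpoints(self) -> tuple[str, str]:
        return (self.source, self.target)

    def other(self, node: str) -> str:
        return self.target if node == self.source else self.source

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        arrow = "->" if self.sign > 0 else "-|"
        return f"{self.source} {arrow} {self.target}"


class SignedGraph:
    """A connected-checkable signed multigraph with a designated reference node.

    Parameters
    ----------
    edges:
        Iterable of :class:`SignedEdge`.  Self-loops are dropped with a
        warning: they can never belong to a spanning tree, and a negative
        self-loop would make every graph trivially unbalanced.
    reference:
        The reference node REF fixing the absolute sign convention.
    nodes:
        Optional explicit node set; inferred from edge endpoints otherwise.
        Needed for isolated nodes (only legal in the single-node graph).
    """

    def __init__(
        self,
        edges: Iterable[SignedEdge],
        reference: str,
        nodes: Iterable[str] | None = None,
    ) -> None:
        kept: list[SignedEdge] = []
        n_loops = 0
        for e in edges:
            if e.source == e.target:
                n_loops += 1
                continue
            kept.append(e)
        if n_loops:
            warnings.warn(
                f"dropped {n_loops} self-loop(s): they cannot belong to any spanning tree",
                stacklevel=2,
            )
        self._edges: tuple[SignedEdge, ...] = tuple(kept)

        ordered: dict[str, None] = {}
        if nodes is not None:
            for n in nodes:
                ordered.setdefault(n, None)
        for e in self._edges:
            ordered.setdefault(e.source, None)
            ordered.setdefault(e.target, None)
        if reference not in ordered:
            raise ValueError(f"reference node {reference!r} is not a node of the graph")
        self._nodes: tuple[str, ...] = tuple(ordered)
        self.reference: str = reference

        self._index: dict[str, int] = {n: i for i, n in enumerate(self._nodes)}
        # incidence[i] = [(edge_idx, other_node_idx), ...], direction ignored
        inc: list[list[tuple[int, int]]] = [[] for _ in self._nodes]
        for k, e in enumerate(self._edges):
            u, v = self._index[e.source], self._index[e.target]
            inc[u].append((k, v))
            inc[v].append((k, u))
        self._incidence: tuple[tuple[tuple[int, int], ...], ...] = tuple(
            tuple(lst) for lst in inc
        )

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[SignedEdge, ...]:
        return self._edges

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def node_index(self, node: str) -> int:
        return self._index[node]

    def incident(self, node: str) -> tuple[tuple[int, int], ...]:
        """(edge index, neighbour node index) pairs incident to *node*."""
        return self._incidence[self._index[node]]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SignedGraph({self.n_nodes} nodes, {self.n_edges} edges, "
            f"ref={self.reference!r})"
        )

    # -- structure ---------------------------------------------------------
    def is_connected(self) -> bool:
        if self.n_nodes <= 1:
            return True
        seen = {0}
        stack = [0]
        while stack:
            u = stack.pop()
            for _, v in self._incidence[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        return len(seen) == self.n_nodes

    def require_connected(self, what: str = "this operation") -> None:
        if not self.is_connected():
            raise DisconnectedGraphError(
                f"{what} requires a connected graph; use reference_component() "
                "to extract the component containing the reference node"
            )

    def reference_component(self) -> "SignedGraph":
        """The connected component containing the reference node, as a new graph."""
        ref_i = self._index[self.reference]
        seen = {ref_i}
        stack = [ref_i]
        while stack:
            u = stack.pop()
            for _, v in self._incidence[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        keep_nodes = [n for n in self._nodes if self._index[n] in seen]
        keep_edges = [
            e for e in self._edges if self._index[e.source] in seen
        ]
        return SignedGraph(keep_edges, self.reference, nodes=keep_nodes)

    def to_networkx(self):
        """Export as a :class:`networkx.MultiDiGraph` (sign/class as edge data)."""
        import networkx as nx

        g = nx.MultiDiGraph(reference=self.reference)
        g.add_nodes_from(self._nodes)
        for k, e in enumerate(self._edges):
            g.add_edge(e.source, e.target, key=k, sign=e.sign, edge_class=e.edge_class)
        return g


@dataclass
class BalanceReport:
    """Outcome of the balance (causal-consistency) check.

    ``node_signs`` holds the unambiguous nodal signs s_{n->REF} and is only
    defined on balanced graphs; ``witness_cycle`` holds one cycle whose edge
    signs multiply to -1 and is only defined on unbalanced graphs.
    """

    balanced: bool
    node_signs: dict[str, int] = field(default_factory=dict)
    witness_cycle: tuple[SignedEdge, ...] = ()


def check_balance(graph: SignedGraph) -> BalanceReport:
    """Decide whether *graph* is balanced and derive nodal signs or a witness.

    Signs are propagated breadth-first from the reference node; the graph is
    balanced iff no edge contradicts the propagated signs (equivalently,
    every cycle has a positive edge-sign product).  For an unbalanced graph
    the returned witness cycle is formed by a contradicting edge together
    with the BFS-tree paths joining its endpoints.
    """
    graph.require_connected("balance analysis")
    ref_i = graph.node_index(graph.reference)
    n = graph.n_nodes
    sign = [0] * n
    parent_edge: list[int | None] = [None] * n
    parent: list[int | None] = [None] * n
    depth = [0] * n
    sign[ref_i] = 1
    queue = deque([ref_i])
    order = []
    while queue:
        u = queue.popleft()
        order.append(u)
        for k, v in graph.incident(graph.nodes[u]):
            if sign[v] == 0:
                sign[v] = sign[u] * graph.edges[k].sign
                parent_edge[v] = k
                parent[v] = u
                depth[v] = depth[u] + 1
                queue.append(v)

    for k, e in enumerate(graph.edges):
        u = graph.node_index(e.source)
        v = graph.node_index(e.target)
        if sign[u] * sign[v] != e.sign:
            cycle = _bfs_cycle(graph, parent, parent_edge, depth, u, v, k)
            return BalanceReport(balanced=False, witness_cycle=cycle)

    node_signs = {graph.nodes[i]: sign[i] for i in range(n)}
    return BalanceReport(balanced=True, node_signs=node_signs)


def _bfs_cycle(
    graph: SignedGraph,
    parent: list[int | None],
    parent_edge: list[int | None],
    depth: list[int],
    u: int,
    v: int,
    closing_edge: int,
) -> tuple[SignedEdge, ...]:
    """Cycle formed by the closing edge and the BFS-tree paths u..lca..v."""
    path_u: list[int] = []
    path_v: list[int] = []
    while depth[u] > depth[v]:
        path_u.append(parent_edge[u])  # type: ignore[arg-type]
        u = parent[u]  # type: ignore[assignment]
    while depth[v] > depth[u]:
        path_v.append(parent_edge[v])  # type: ignore[arg-type]
        v = parent[v]  # type: ignore[assignment]
    while u != v:
        path_u.append(parent_edge[u])  # type: ignore[arg-type]
        path_v.append(parent_edge[v])  # type: ignore[arg-type]
        u = parent[u]  # type: ignore[assignment]
        v = parent[v]  # type: ignore[assignment]
    idxs = path_u + path_v[::-1] + [closing_edge]
    return tuple(graph.edges[k] for k in idxs)


def resolve_scores(
    graph: SignedGraph,
    scores: Mapping[str, float],
    impute_zero: bool = False,
) -> dict[str, float]:
    """Validate a node->score mapping against the graph's node set.

    Missing nodes are a hard error unless ``impute_zero`` is set, in which
    case an absent score contributes nothing to aggregation.  Non-finite
    values are always rejected.
    """
    out: dict[str, float] = {}
    for n in graph.nodes:
        if n in scores:
            x = float(scores[n])
            if not math.isfinite(x):
                raise ValueError(f"score for node {n!r} is not finite: {x}")
            out[n] = x
        elif impute_zero:
            out[n] = 0.0
        else:
            raise MissingScoreError(
                f"node {n!r} has no score; pass impute_zero=True to treat it as 0"
            )
    return out


def aggregate_balanced(
    graph: SignedGraph,
    scores: Mapping[str, float],
    impute_zero: bool = False,
) -> float:
    """Aggregate nodal scores over a balanced graph: X_G = sum_n s_{n->REF} X_n.

    Raises :class:`UnbalancedGraphError` on causally inconsistent input,
    for which the spanning-tree sampler must be used instead.
    """
    report = check_balance(graph)
    if not report.balanced:
        raise UnbalancedGraphError(
            "graph is causally inconsistent (unbalanced); aggregate via "
            "spanning-tree effective weights (exact_effective_weights or "
            "estimate_effective_weights) instead"
        )
    x = resolve_scores(graph, scores, impute_zero)
    return float(sum(report.node_signs[n] * x[n] for n in graph.nodes))
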