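"""Synthetic test inputs: the IFFL motif, random signed graphs, random scores.

The incoherent feed-forward loop (IFFL) is the minimal causally inconsistent
motif: A activates both B and C while B inhibits C, so the two paths joining
A and C (and A and B) carry opposite signs.  Random graphs are built on a
uniform random spanning-tree backbone, which guarantees connectivity at any
density without rejection sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph import SignedEdge, SignedGraph, check_balance


def iffl() -> SignedGraph:
    """The incoherent feed-forward loop: A -> B, A -> C, B -| C, reference A."""
    return SignedGraph(
        [
            SignedEdge("A", "B", +1),
            SignedEdge("A", "C", +1),
            SignedEdge("B", "C", -1),
        ],
        reference="A",
    )


@dataclass
class GraphGenSpec:
    """Parameters of the random signed-graph generator.

    ``n_edges`` counts total edges (the first ``n_nodes - 1`` form the tree
    backbone).  ``p_negative`` is the i.i.d. probability of a -1 edge.
    ``class_mix`` assigns semantic edge classes by the given fractions; the
    default puts every edge in the 'default' class so traversal is uniform.
    ``force_unbalanced`` resamples edge signs (bounded retries) until the
    graph is causally inconsistent.
    """

    n_nodes: int
    n_edges: int
    p_negative: float = 0.2
    class_mix: dict[str, float] = field(default_factory=lambda: {"default": 1.0})
    force_unbalanced: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.n_edges < self.n_nodes - 1:
            raise ValueError("n_edges must be >= n_nodes - 1 for connectivity")
        if not 0.0 <= self.p_negative <= 1.0:
            raise ValueError("p_negative must be in [0, 1]")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix fractions must sum to 1")


def random_signed_graph(spec: GraphGenSpec) -> SignedGraph:
    """Generate a connected random signed graph per *spec* (deterministic in seed).

    A uniform random labeled tree forms the backbone; the remaining edges are
    drawn uniformly over non-self-loop node pairs (parallel edges permitted).
    Signs are i.i.d. -1 with probability ``p_negative``; edge classes follow
    ``class_mix``.  With ``force_unbalanced`` the sign assignment is redrawn
    until the graph is unbalanced, which is impossible for tree graphs
    (trees are always balanced) and fails fast in that case.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes
    names = [f"N{i}" for i in range(n)]

    if spec.force_unbalanced and spec.n_edges == n - 1:
        raise ValueError(
            "cannot force an unbalanced graph with n_edges == n_nodes - 1: "
            "tree graphs are always balanced"
        )

    pairs: list[tuple[int, int]] = []
    if n > 1:
        backbone = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
        pairs.extend(backbone.edges())
    for _ in range(spec.n_edges - len(pairs)):
        u = int(rng.integers(n))
        v = int(rng.integers(n - 1))
        if v >= u:
            v += 1
        pairs.append((u, v))

    classes = list(spec.class_mix)
    probs = np.array([spec.class_mix[c] for c in classes])
    edge_classes = [classes[i] for i in rng.choice(len(classes), size=len(pairs), p=probs)]

    max_retries = 1000
    for attempt in range(max_retries + 1):
        signs = np.where(rng.random(len(pairs)) < spec.p_negative, -1, 1)
        edges = [
            SignedEdge(names[u], names[v], int(s), c)
            for (u, v), s, c in zip(pairs, signs, edge_classes)
        ]
        graph = SignedGraph(edges, reference=names[0], nodes=names)
        if not spec.force_unbalanced or not check_balance(graph).balanced:
            return graph
    raise RuntimeError(
        f"could not draw an unbalanced sign assignment in {max_retries} tries; "
        "increase p_negative or add cycle edges"
    )


def random_scores(
    nodes,
    distribution: str = "unit",
    seed: int = 0,
    mu: float = 0.0,
    sigma: float = 1.0,
) -> dict[str, float]:
    """Random nodal scores: 'unit' (all X_n = 1, the typical differential-
    expression placeholder) or 'gaussian' with mean ``mu`` and sd ``sigma``.
    Deterministic for a fixed seed."""
    nodes = list(nodes)
    if not nodes:
        raise ValueError("node set must be non-empty")
    if distribution == "unit":
        return {n: 1.0 for n in nodes}
    if distribution == "gaussian":
        rng = np.random.default_rng(seed)
        return {n: float(x) for n, x in zip(nodes, rng.normal(mu, sigma, len(nodes)))}
    raise ValueError(f"unknown distribution {distribution!r}")
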