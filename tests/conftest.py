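"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's own enumeration and
propagation code paths: spanning trees are found by exhaustive search over
edge subsets with a union-find acyclicity check, and path signs by explicit
path following, so the package can be validated against them.
"""

import itertools

import pytest

from sstagg import GraphGenSpec, SignedEdge, SignedGraph, iffl, random_signed_graph


@pytest.fixture
def iffl_graph() -> SignedGraph:
    return iffl()


@pytest.fixture
def chain_graph() -> SignedGraph:
    """Balanced chain A -> B -| C, reference A; signs (+1, +1, -1)."""
    return SignedGraph(
        [SignedEdge("A", "B", +1), SignedEdge("B", "C", -1)], reference="A"
    )


@pytest.fixture
def single_node_graph() -> SignedGraph:
    return SignedGraph([], reference="X", nodes=["X"])


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_force_tree_indices(graph: SignedGraph) -> list[tuple[int, ...]]:
    """All spanning trees as sorted edge-index tuples, by subset search."""
    n = graph.n_nodes
    m = graph.n_edges
    if n == 1:
        return [()]
    out = []
    for subset in itertools.combinations(range(m), n - 1):
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        acyclic = True
        for k in subset:
            e = graph.edges[k]
            a = find(graph.node_index(e.source))
            b = find(graph.node_index(e.target))
            if a == b:
                acyclic = False
                break
            parent[a] = b
        if acyclic:
            out.append(tuple(subset))
    return out


def brute_force_path_signs(graph: SignedGraph, tree_idxs: tuple[int, ...]) -> dict[str, int]:
    """Sign of each node along its unique tree path to REF, by path walking."""
    adj: dict[str, list[tuple[str, int]]] = {n: [] for n in graph.nodes}
    for k in tree_idxs:
        e = graph.edges[k]
        adj[e.source].append((e.target, e.sign))
        adj[e.target].append((e.source, e.sign))

    def path_sign(node: str) -> int:
        # depth-first path search from node to the reference
        stack = [(node, 1, {node})]
        while stack:
            cur, sgn, seen = stack.pop()
            if cur == graph.reference:
                return sgn
            for nxt, sigma in adj[cur]:
                if nxt not in seen:
                    stack.append((nxt, sgn * sigma, seen | {nxt}))
        raise AssertionError(f"no tree path from {node} to reference")

    return {n: path_sign(n) for n in graph.nodes}


def make_balanced(graph: SignedGraph, seed: int = 0) -> SignedGraph:
    """Rebuild a graph with edge signs consistent with random nodal signs.

    Drawing s_n in {-1,+1} per node and setting every edge sign to
    s_u * s_v yields a balanced graph by construction (every cycle's sign
    product telescopes to +1) while keeping negative edges present.
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    s = {n: int(x) for n, x in zip(graph.nodes, rng.choice([-1, 1], graph.n_nodes))}
    s[graph.reference] = 1
    edges = [
        SignedEdge(e.source, e.target, s[e.source] * s[e.target], e.edge_class)
        for e in graph.edges
    ]
    return SignedGraph(edges, reference=graph.reference, nodes=graph.nodes)


def small_random_graphs(count: int, *, max_nodes: int = 8, force_unbalanced: bool,
                        seed0: int = 100) -> list[SignedGraph]:
    """Deterministic battery of small random connected signed graphs."""
    graphs = []
    s = seed0
    while len(graphs) < count:
        rng_n = 3 + (s * 7919) % (max_nodes - 2)  # 3..max_nodes
        extra = 1 + (s * 104729) % 4
        spec = GraphGenSpec(
            n_nodes=rng_n,
            n_edges=rng_n - 1 + extra,
            p_negative=0.4,
            force_unbalanced=force_unbalanced,
            seed=s,
        )
        try:
            graphs.append(random_signed_graph(spec))
        except ValueError:
            pass
        s += 1
    return graphs
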