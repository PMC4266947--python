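"""Monte-Carlo estimation of effective nodal weights by sampling spanning trees.

Signed random walkers implement Aldous' first-entrance construction of a
uniform random spanning tree, extended with a sign state:

1. each walker starts at the reference node REF with sign +1 (REF is marked
   visited with sign +1);
2. from the current node the walker picks an incident edge with probability
   proportional to its traversal weight, ignoring edge direction and sign;
3. traversing a negative edge flips the walker's sign, a positive edge
   preserves it;
4. on first entrance to a node the walker marks it visited, records its
   current sign there, and adds the traversed edge to the tree;
5. on re-entering a visited node the walker adopts that node's stored sign
   (and continues walking from it);
6. the walk stops once every node has been visited.

The first-entrance edges form a spanning tree — uniformly distributed over
all spanning trees when the traversal weights are equal — and the recorded
node signs equal the tree's path signs relative to REF.  Averaging the
recorded sign of node n over many walkers estimates S_{n->REF}(G):

    S_{n->REF}(G) ~ (N_+(n) - N_-(n)) / (N_+(n) + N_-(n))

Each walker runs on its own counter-derived random stream, so results are
reproducible for a fixed seed and unchanged when the number of trees grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import CoverTimeError
from .exact import SpanningTree, tree_signs
from .graph import DEFAULT_CLASS_WEIGHTS, SignedGraph
from .weights import EffectiveWeights

__all__ = [
    "WalkConfig",
    "SampledTreeRecord",
    "run_signed_walker",
    "estimate_effective_weights",
    "convergence_check",
]


@dataclass
class WalkConfig:
    """Sampling configuration.

    ``n_trees`` is the number of independent walkers (= sampled spanning
    trees); 1000 by default, which for typical causal network models brings
    the weights within ~0.01 (median) of a 20x larger sample — see
    :func:`convergence_check`.  ``edge_class_weights`` maps the semantic edge
    classes of BEL-encoded models to relative traversal probabilities; the
    default profile is {intramolecular: 1, direct: 1/2, indirect: 1/3,
    expression: 1/4, default: 1}, so class-free graphs are sampled uniformly.
    ``max_steps_per_walk`` bounds the walk length; exceeding it raises
    :class:`CoverTimeError` (never a silent truncation) and defaults to
    ``500 * n_nodes * n_edges``, a generous multiple of the expected cover
    time.
    """

    n_trees: int = 1000
    seed: int = 0
    edge_class_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    max_steps_per_walk: int | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        for cls, w in self.edge_class_weights.items():
            if w <= 0:
                raise ValueError(f"traversal weight for class {cls!r} must be > 0")

    def step_budget(self, graph: SignedGraph) -> int:
        if self.max_steps_per_walk is not None:
            return self.max_steps_per_walk
        return 500 * max(1, graph.n_nodes) * max(1, graph.n_edges)


@dataclass
class SampledTreeRecord:
    """One walker's outcome: the reconstructed tree, its sign vector, steps taken."""

    tree: SpanningTree
    sign_vector: dict[str, int]
    walker_steps: int


# ---------------------------------------------------------------------------
# compiled walker kernel
# ---------------------------------------------------------------------------

_KERNEL = None


def _kernel():
    """Lazily compile the inner walker loop (one compilation per process)."""
    global _KERNEL
    if _KERNEL is not None:
        return _KERNEL
    from numba import njit

    @njit(cache=False)
    def walk(indptr, nbr, esign, eidx, cumw, ref, max_steps, sign_out, tree_out, rng):
        n = sign_out.shape[0]
        for i in range(n):
            sign_out[i] = 0
        sign_out[ref] = 1
        visited = 1
        cur = ref
        steps = 0
        while visited < n:
            steps += 1
            if steps > max_steps:
                return -1
            lo = indptr[cur]
            hi = indptr[cur + 1]
            r = rng.random() * cumw[hi - 1]
            k = lo + np.searchsorted(cumw[lo:hi], r, side="right")
            if k >= hi:
                k = hi - 1
            nxt = nbr[k]
            s = sign_out[cur] * esign[k]
            if sign_out[nxt] == 0:
                sign_out[nxt] = s
                tree_out[visited - 1] = eidx[k]
                visited += 1
            cur = nxt
        return steps

    _KERNEL = walk
    return _KERNEL


class _CompiledGraph:
    """CSR half-edge arrays of a graph under a given traversal-weight profile."""

    def __init__(self, graph: SignedGraph, class_weights: Mapping[str, float]):
        n = graph.n_nodes
        counts = [len(graph.incident(node)) for node in graph.nodes]
        total = sum(counts)
        self.indptr = np.zeros(n + 1, dtype=np.int64)
        self.indptr[1:] = np.cumsum(counts)
        self.nbr = np.empty(total, dtype=np.int64)
        self.esign = np.empty(total, dtype=np.int8)
        self.eidx = np.empty(total, dtype=np.int64)
        self.cumw = np.empty(total, dtype=np.float64)
        pos = 0
        for i, node in enumerate(graph.nodes):
            acc = 0.0
            for k, v in graph.incident(node):
                e = graph.edges[k]
                acc += class_weights.get(e.edge_class, DEFAULT_CLASS_WEIGHTS[e.edge_class])
                self.nbr[pos] = v
                self.esign[pos] = e.sign
                self.eidx[pos] = k
                self.cumw[pos] = acc
                pos += 1
        self.ref = graph.node_index(graph.reference)
        self.n_nodes = n


def _walker_rng(seed: int, walker: int) -> np.random.Generator:
    """Counter-based per-walker stream: Philox keyed by (seed, walker index)."""
    return np.random.Generator(np.random.Philox(key=(int(seed) << 40) + walker))


def run_signed_walker(
    graph: SignedGraph,
    cfg: WalkConfig | None = None,
    rng: np.random.Generator | None = None,
) -> SampledTreeRecord:
    """Run one signed walker and reconstruct its first-entrance spanning tree.

    Pure-Python reference implementation of the walk rules; draws random
    numbers in exactly the same pattern as the compiled kernel, so a walker
    given the same stream produces the same tree either way.
    """
    cfg = cfg or WalkConfig()
    rng = rng if rng is not None else _walker_rng(cfg.seed, 0)
    graph.require_connected("spanning-tree sampling")

    max_steps = cfg.step_budget(graph)
    cw = cfg.edge_class_weights
    ref = graph.reference
    sign: dict[str, int] = {ref: 1}
    tree_edges: list[int] = []
    cur = ref
    steps = 0
    n = graph.n_nodes
    while len(sign) < n:
        steps += 1
        if steps > max_steps:
            raise CoverTimeError(
                f"walker exceeded {max_steps} steps before covering the graph; "
                "check connectivity or traversal-weight pathologies"
            )
        incident = graph.incident(cur)
        weights = np.cumsum(
            [
                cw.get(
                    graph.edges[k].edge_class,
                    DEFAULT_CLASS_WEIGHTS[graph.edges[k].edge_class],
                )
                for k, _ in incident
            ]
        )
        r = rng.random() * weights[-1]
        choice = min(int(np.searchsorted(weights, r, side="right")), len(incident) - 1)
        k, v_idx = incident[choice]
        nxt = graph.nodes[v_idx]
        s = sign[cur] * graph.edges[k].sign
        if nxt not in sign:
            sign[nxt] = s
            tree_edges.append(k)
        cur = nxt

    tree = SpanningTree(parent=graph, edge_indices=tuple(sorted(tree_edges)))
    return SampledTreeRecord(tree=tree, sign_vector=dict(sign), walker_steps=steps)


def estimate_effective_weights(
    graph: SignedGraph,
    cfg: WalkConfig | None = None,
    return_records: bool = False,
) -> EffectiveWeights | tuple[EffectiveWeights, list[SampledTreeRecord]]:
    """Estimate S_{n->REF}(G) from ``cfg.n_trees`` independent signed walkers.

    Deterministic for a fixed seed.  Binomial standard errors
    ``sqrt((1 - S_n^2)/n_trees)`` are attached per node.  With
    ``return_records=True`` the reconstructed trees are returned as well
    (slower: uses the reference Python walker on identical random streams,
    so the weights are bit-identical to the fast path).
    """
    cfg = cfg or WalkConfig()
    graph.require_connected("spanning-tree sampling")

    if return_records:
        records = [
            run_signed_walker(graph, cfg, _walker_rng(cfg.seed, w))
            for w in range(cfg.n_trees)
        ]
        n_plus = {n: 0 for n in graph.nodes}
        n_minus = {n: 0 for n in graph.nodes}
        for rec in records:
            for n, s in rec.sign_vector.items():
                if s > 0:
                    n_plus[n] += 1
                else:
                    n_minus[n] += 1
        return EffectiveWeights.from_sign_counts(n_plus, n_minus), records

    walk = _kernel()
    cg = _CompiledGraph(graph, cfg.edge_class_weights)
    max_steps = cfg.step_budget(graph)
    sign_buf = np.zeros(cg.n_nodes, dtype=np.int8)
    tree_buf = np.zeros(max(1, cg.n_nodes - 1), dtype=np.int64)
    plus = np.zeros(cg.n_nodes, dtype=np.int64)
    for w in range(cfg.n_trees):
        steps = walk(
            cg.indptr, cg.nbr, cg.esign, cg.eidx, cg.cumw,
            cg.ref, max_steps, sign_buf, tree_buf, _walker_rng(cfg.seed, w),
        )
        if steps < 0:
            raise CoverTimeError(
                f"walker {w} exceeded {max_steps} steps before covering the graph; "
                "check connectivity or traversal-weight pathologies"
            )
        plus += sign_buf > 0
    n_plus = {n: int(plus[i]) for i, n in enumerate(graph.nodes)}
    n_minus = {n: cfg.n_trees - int(plus[i]) for i, n in enumerate(graph.nodes)}
    return EffectiveWeights.from_sign_counts(n_plus, n_minus)


def convergence_check(
    graph: SignedGraph,
    n_small: int = 1000,
    n_large: int = 20000,
    seed: int = 0,
    cfg: WalkConfig | None = None,
) -> tuple[float, float]:
    """Compare weight estimates at two sampling depths.

    Runs the sampler independently with ``n_small`` and ``n_large`` trees on
    distinct seeded substreams and returns ``(median, max)`` over nodes of
    ``|S_small - S_large|``.  A median below 0.01 (max below 0.05) indicates
    that the smaller sample is already adequate.
    """
    base = cfg or WalkConfig()
    sub = np.random.SeedSequence(seed).generate_state(2) & 0x7FFFFFFF
    small_cfg = WalkConfig(
        n_trees=n_small,
        seed=int(sub[0]),
        edge_class_weights=dict(base.edge_class_weights),
        max_steps_per_walk=base.max_steps_per_walk,
    )
    large_cfg = WalkConfig(
        n_trees=n_large,
        seed=int(sub[1]),
        edge_class_weights=dict(base.edge_class_weights),
        max_steps_per_walk=base.max_steps_per_walk,
    )
    s_small = estimate_effective_weights(graph, small_cfg)
    s_large = estimate_effective_weights(graph, large_cfg)
    diffs = np.array(
        [abs(s_small[n] - s_large[n]) for n in graph.nodes], dtype=float
    )
    return float(np.median(diffs)), float(np.max(diffs))
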