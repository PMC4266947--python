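# Methods

## Model

A causal network model is a connected signed multigraph G = (Nodes, Edges)
with a reference node REF. Each edge carries a sign σ ∈ {−1, +1}
(activation / inhibition) and optionally a semantic class. Edge direction
is stored but deliberately ignored by all sign computations: the sign of a
node n relative to REF is the product of edge signs along a *non-oriented*
path, and balance (causal consistency) is the property that this product is
path-independent — equivalently, that every cycle has positive sign
product, or that deleting z = 0 edges (the line index of balance) suffices
to remove all negative cycles.

On a balanced graph the aggregation of nodal scores X_n is the signed sum
X_G = Σ_n s_{n→REF}(G)·X_n. On an unbalanced graph s does not exist, but
every spanning tree t is balanced, so its path signs s_{n→REF}(t) are
unambiguous. The package defines

- effective weights S_{n→REF}(G) = ⟨s_{n→REF}(t)⟩_t over all (or sampled)
  spanning trees, a value in [−1, +1] whose magnitude measures how
  unambiguous the node's relation to REF is;
- the aggregate X_G = Σ_n S_n·X_n, equal to the mean of the per-tree
  aggregates X(t) = Σ_n s_{n→REF}(t)·X_n;
- the most representative spanning tree t\* = argmin_t |X(t) − X_G|, and
  G\* = t\* plus every non-tree edge whose endpoint signs under t\* are
  consistent with its edge sign. G\* is therefore the maximal balanced
  subgraph of G containing t\*; this is our concrete reading of "the
  subgraph corresponding to t\*", chosen because it keeps G\* balanced by
  construction while retaining as much of G as possible. Ties in the
  argmin are broken by input order, for reproducibility.

## Exact engine

Spanning trees are enumerated by contraction–deletion with a fixed edge
order (trees containing the first edge = trees of G with it contracted;
trees avoiding it = trees of G with it deleted, pruned by a connectivity
check). The recursion is multigraph-aware: parallel edges — which occur in
curated models as contradictory assertions between the same pair of
entities — are distinct tree members and are identified positionally.
N(G) is computed beforehand with the matrix-tree theorem (determinant of
the reduced integer Laplacian, exact arithmetic via sympy); enumeration
refuses graphs with more than `cap` trees (default 10⁶) and defers to the
sampler. Effective weights from enumeration are accumulated as exact
rationals, so the balanced-graph limit returns bit-exact ±1. The
line-index-of-balance routine is a brute-force subset search intended as a
test oracle only; balance after deletions is checked component-wise since a
deletion may disconnect the graph.

## Sampler

Walkers implement the first-entrance (Aldous) construction of a uniform
random spanning tree, extended with a sign state:

1. start at REF with sign +1, REF marked visited with +1;
2. choose an incident edge with probability proportional to its traversal
   weight, ignoring direction and sign;
3. a negative edge flips the walker's sign, a positive edge preserves it;
4. on first entrance, record the walker's sign at the node and keep the
   traversed edge — these edges form the sampled tree;
5. on re-entering a visited node the walker adopts that node's stored sign
   and continues from it (this is the only reading of the re-entry rule
   under which the recorded signs equal the tree's path signs, which we
   assert per walker in the tests);
6. stop when all nodes are visited.

With equal weights the first-entrance tree is exactly uniform over all
spanning trees (verified by chi-square against enumeration). Class weights
(intramolecular 1, direct 1/2, indirect 1/3, expression 1/4; plain edges 1)
are applied as a per-step local normalization over the current node's
incident edges; the induced tree distribution is the first-entrance
distribution of this weighted walk — a mild, full-support deformation of
the uniform one, which is the intended semantics rather than a Gibbs
measure over trees.

Estimation runs `n_trees` independent walkers (default 1000) and sets
S_n = (N₊(n) − N₋(n))/n_trees with the binomial standard error
√((1 − S_n²)/n_trees). Each walker uses its own counter-derived Philox
stream keyed by (seed, walker index), so results are reproducible and
walkers stay uncorrelated when n_trees changes; growing the sample extends
it rather than reshuffling it. The inner loop is JIT-compiled (numba); a
pure-Python walker that draws from identical streams is used when
reconstructed trees are requested, and the two paths are asserted
bit-identical in the tests. A walker exceeding `max_steps_per_walk`
(default 500·|V|·|E|, a generous multiple of the worst-case cover time
O(|V|·|E|)) raises a hard error — no silent truncation and no automatic
retry, because a blown step budget signals near-disconnection or a
traversal-weight pathology that resampling would mask.

`convergence_check` runs the estimator at two depths (default 1,000 vs
20,000 trees) on distinct substreams and reports the median and maximum
over nodes of |ΔS_n|; median < 0.01 and max < 0.05 are the adequacy
thresholds used for curated network models. No automatic stopping rule is
layered on top: the two-depth comparison itself is exposed, and the CLI
`--check-convergence` flag warns when the median criterion fails.

## Evaluation

`compare_to_reference_signs` scores effective weights against the nodal
signs of a manually pruned, causally consistent version of the same
network. The mislabeling rate is the zero-threshold sign disagreement; an
exactly zero weight counts as mislabeled because it carries no direction.
The ROC takes reference sign +1 as the positive class and S as the score
(sklearn's threshold sweep; validated in tests against a brute-force
sweep); AUROC is the trapezoidal integral, reported as undefined (None)
when only one class is present rather than coerced to 0 or 1. The rate is
pooled per node; per-network averaging, when several networks are
compared, is left to the caller.

## Synthetic data

`iffl()` returns the printed 3-node incoherent feed-forward loop.
`random_signed_graph` builds a connected graph from a uniform random
labeled-tree backbone (guaranteed connectivity at any density, no rejection
loop) plus uniformly drawn extra edges, with i.i.d. signs (default 20%
negative, a moderate inhibition fraction typical of signaling-network edge
lists), classes by a caller-given mix (default all plain, so core results
are independent of the BEL weighting), and optional resampling of signs
until the graph is unbalanced. Scores are unit (the differential-expression
placeholder) or Gaussian.

What these fixtures do not emulate: real curated models are modular and
tree-like with causal inconsistencies confined to a few peripheral feedback
loops (pruning a handful of edges restores consistency), whereas an
i.i.d.-sign random graph at 20% negative edges is frustrated globally —
nearly every node's sign is ambiguous (|S| < 0.5 for ~97% of nodes at the
144-node/241-edge scale we use). Two consequences. First, convergence at a
fixed tree count is intrinsically harder on these fixtures: a node with
S ≈ 0 has sampling noise SE ≈ 0.032 at 1,000 trees, so the median
two-depth difference sits near 0.02–0.03 and cannot reach the 0.01 median
(0.05 max) adequacy thresholds that localized real networks meet — those
thresholds are a property of the network's frustration structure, not of
the estimator, whose accuracy is instead validated directly against the
enumeration oracle (weights within 3 SE) and by the uniformity test.
Second, passing tests on these fixtures demonstrate correctness of the
machinery, not that any particular real network is well converged at 1,000
trees; for real use, run the two-depth check on the network at hand.

## Numerical and degenerate-input choices

Exact weights are rationals internally and exported as doubles. The
single-node graph has one (empty) spanning tree, S_REF = +1, and aggregate
X_REF. Self-loops are dropped at construction with a warning (they cannot
enter a tree; a negative one would make every graph unbalanced).
Disconnected input is a hard error everywhere — balance and tree sampling
are ill-posed across components — with `reference_component()` /
`--component-of-ref` as the explicit opt-in to proceed on REF's component.
Missing nodal scores raise; `impute_zero` treats an unmeasured node as
contributing nothing and must be requested explicitly. Node identifiers
are opaque case-sensitive strings.

## Limitations

- The brute-force line index is exponential and capped; no MAX-CUT-style
  solver is provided (or needed — it is a test oracle).
- Weighted sampling has no closed-form tree measure; results with BEL
  class weights are defined by the walk itself, as described above.
- Wilson's loop-erased sampler would mix faster on some graphs but is not
  implemented; the first-entrance walk is the algorithm this package is
  built around, and its cover time is adequate at the network scales
  targeted here.
- AUROC/mislabeling against real pruned curated networks requires those
  models' edge lists, which are not bundled; the evaluation machinery is
  exercised on synthetic ground truth instead.
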