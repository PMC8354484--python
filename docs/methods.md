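# Methods

## Model class and assumptions

The package analyzes switching (Glass-type) models of gene regulation. A
network is a signed digraph on nodes `0..N-1`; node 0 receives the external
signal, the last of the first three nodes (node 2 by default) is the
read-out. Each node's level decays linearly (rate `γ_n > 0`) and is
produced at a rate that depends only on which of its inputs exceed their
thresholds. The interaction algebra is fixed: activating inputs contribute
additively (`ℓ_{n,m}` below threshold, `ℓ_{n,m}+δ_{n,m}` above), and each
repressing input multiplies the summed activator term by its own two-level
factor (high factor when the repressor is low). A node with no in-edges
produces at a constant basal rate `β_n`. All parameters are strictly
positive; regions of parameter space are open, so every inequality in the
machinery is strict and witnessed with a margin.

Three-node networks are first-class: there are `3^9 = 19,683` of them, of
which `21·3^5 = 5,103` are *trivial* (no path from the input or from node 1
to the output; closed form `|a20·a21|+|a20·a01|+|a21·a10| = 0`). The
screening set drops trivial networks and keeps a single nine-edge network
(the all-activator one), giving 14,069 networks by direct arithmetic.

## Factor-graph enumeration

A node's region is encoded as a *threshold order* (permutation of its
out-edge targets by increasing `γθ`) plus a *binarization chain*
`B_1 ⊇ ... ⊇ B_E` of input-state sets (states whose production value
exceeds the i-th threshold). Candidates are generated combinatorially —
each `B_i` must be an up-set of the polarity-adjusted order on the input
hypercube — and then checked for realizability:

- **pure-sum logic** (all activators, or a basal node): the inequality
  system is linear in `(ℓ, δ, γθ)`; feasibility and a witness come from a
  single HiGHS linear program that maximizes the minimum slack. This is
  exact (up to the margin ε).
- **pure-product logic** (all repressors): linear after a log transform;
  same LP treatment.
- **mixed sum×product logic**: slack maximization by SLSQP from 20 seeded
  random starts in log space; any reported optimum is re-verified against
  the exact inequalities before acceptance. A candidate on which no start
  converges is counted as *undecided* and excluded (the count is carried on
  the factor graph; it has been zero on every shape exercised here).

For a node with three summed inputs and three out-thresholds the 887
combinatorial candidates prune to 707 realizable regions per threshold
order — so the full factor graph of the input node of the six-edge
all-activator design has 707 vertices in its scoring class, and exhaustive
sampling (the partition-oracle test) confirms the enumeration both covers
and is covered by random positive parameter draws.

Essentiality is per the standard reading: every out-threshold is crossed by
some pair of states, and every in-edge separates at least one pair of
states differing only in that input. Adjacency joins regions whose
inequality systems differ in exactly one comparison (one state moved across
one threshold, or an adjacent transposition of two thresholds with
identical binarizations). The *signal order* orients each class by
inclusion of the binarization chains; its unique minimum (all sets empty;
production below every threshold) plays the role of zero input and its
unique maximum of saturating input. The published sample parameter point
for the six-edge design classifies into the minimal input region crossed
with essential read-out regions, confirming the orientation.

## Combinatorial dynamics

Phase space is decomposed by the threshold hyperplanes; wall labels follow
the sign of `-γ_n θ + Λ_n` evaluated on each side, constant per region.
Cells whose walls all repel are attracting equilibrium cells (`FP`);
because an outgoing STG edge exists exactly when some wall absorbs, FP
cells are sinks and hence always minimal in the Morse graph (the
condensation of the STG restricted to recurrent components). Boundary
faces at 0 and ∞ are treated as repelling — positivity and decay dominate —
so boundary cells can be attractors. Two extensions: a node with no
out-edges receives a placeholder threshold used only to build the complex
(it appears in the region inequalities as `t[T][n]`), and a self-repressing
node has its self-threshold doubled into a thin slab; the two copies carry
opposite labels derived from the classical rule on their outer sides, and
labels of slab-flanking walls on other axes follow from the classical rule
evaluated with the cross-node bits (which are well defined inside the
slab). Collapsing the doubled coordinate (`k-* → k-1`, `k+* → k`) maps the
refined complex cell-by-cell onto the unrefined one and keeps FP labels on
the true threshold count.

## Scoring

Paths live in one threshold-order class of the input node's factor graph
(the identity class — targets by index — by default; other classes are
mirror images under threshold relabeling), are strictly monotone in the
signal order, and need at least three vertices. *Partial* paths have free
endpoints; *full* paths run minimum to maximum. Scores are exact: path
counts and hysteretic-path counts are dynamic programs over the class DAG
(the hysteretic partial count uses a two-state suffix DP: current vertex ×
whether a bistable vertex has occurred in the interior), so denominators of
order 10^11 are handled without enumeration. The per-vertex flags come from
one Morse-graph computation per (input-region, parameter-vertex) pair.

The hysteresis predicate requires, by default, *monostable endpoints*:
ascending = start has only output-low attractors, end only output-high,
and some strictly interior vertex has both. The existence-only variant
(start merely *has* a low attractor, end a high one) is available as
`strict_ends=False`, but it provably misclassifies: any path inside a
bistable stretch (e.g. created by a self-activating input node) satisfies
the existence form in *both* directions at once, which would let
all-activator designs score nonzero *descending* hysteresis — contradicting
the activator/repressor asymmetry that the monostable-endpoint form
reproduces (descending score exactly 0 for the all-activator fixtures,
ascending full-path score 100% for the six-edge design, and the
three-cycle's 100/20/0.2-fragile signature under both forms).

One number is deliberately reported as a bound, not a reproduction: the
product-of-factor-size maxima over 8- and 9-edge topologies. The honest
combinatorial bound (nested-chain counts × orders, cubed) and the exact
realizable counts bracket the historically printed maxima, which correspond
to a per-class count (756 for the 3-in/3-out shape) that matches neither
the raw chain count (887) nor exact joint realizability (707) and appears
to stem from precomputed region tables that include jointly unrealizable
chains; the acceptance test records the discrepancy rather than emulating
it.

## Parameter sampling

`ParameterGraph.sample_parameters` fixes `γ_n = 1` (any region witness can
be rescaled to this slice) and draws, per node, from the region polytope in
`(ℓ, δ, θ)` (or log space for product logic) intersected with an O(1) box
(upper edge 6.0, log-lower edge 0.02): a max-slack interior point followed
by seeded hit-and-run, every output re-certified against the exact
inequalities. The guarantee is membership with margin, not uniformity — the
regions are unbounded open cones and no canonical distribution exists, so
Monte-Carlo Hill frequencies are meaningful as orderings and trends, not as
third-digit percentages. Mixed-logic nodes fall back to a witness-anchored
rejection walk (cap 10^4 rejections). The box scale matters scientifically:
thresholds of order one keep the signal range `s ∈ [0, 4]` commensurate
with the switching thresholds, which is the regime the reference
computations used (their printed sample point has thresholds 0.7–3.4).

## Hill validation

Hill systems share one exponent `n` across edges; the right-hand side and
analytic Jacobian follow the same sum-then-multiply algebra with
`H± = ℓ + δ·(x or θ)^n/(θ^n + x^n)`, computed overflow-safely so exponents
of several hundred are usable. Equilibria: damped Newton (tolerance 1e-10,
100 iterations). Continuation: pseudo-arclength predictor–corrector with
SVD tangents, initial step 0.01, adaptive within [1e-5, 0.1], corrector
tolerance 1e-10, curve budget 10^5 steps; folds are flagged by determinant
sign changes and refined by bisection to |Δs| < 1e-8, with the output value
"just before/after" read from the accepted points flanking the fold. The
per-point hysteresis test follows the sampled-point procedure: ten random
guesses in the sub-threshold box (output above-threshold box for descending
mode), Newton at `s = 0`, acceptance only for equilibria in the stated
output band, continuation to `s = 4`, and a hysteretic verdict only for
complete curves with an even fold count of at least two and the correct
output step across every fold (zero folds is even but monotone, hence the
explicit lower bound). Incomplete curves are never hysteretic.

## Problem sizes used by the test-suite

The suite and acceptance script run on one CPU in a few minutes total:
enumeration checks over all 19,683 networks; the partition oracle at 10^4
draws per node shape; Morse soundness on all 27 regions of the three-cycle
and 10^3 sampled regions each for the five- and six-edge designs; the
stiff-limit agreement on 51 sampled essential-region points at `n = 100`
(attractor counts from multi-start Newton seeded at cell centers, matched
against Morse minimal-FP counts, ≥ 90% agreement required); and the
steepness trend at 200 Monte-Carlo samples per exponent (30 vs 4). These
sizes are the package's chosen desk-scale study conditions; the full
14,069-network ranking is exposed as a resumable batch (`switchgrade
screen --enumerate-3node --skip/--limit`) rather than a test.

## What the synthetic fixtures do and do not show

The fixtures are the exact worked topologies of the screening study, so
passing tests shows the engine reproduces the reference combinatorics and
the qualitative ODE agreement on those designs. They do not exercise real
expression data, extrinsic noise, unequal Hill exponents per edge, or
networks beyond four in/out edges per node (the enumerator refuses those);
Morse nodes other than FPs are detected but not classified (a cyclic
attractor appears as a non-FP recurrent component). The descending-mode
machinery mirrors ascending and is exercised only as the asymmetry check
on all-activator fixtures.

## Known limitations

- Mixed-logic realizability is decided numerically; "undecided" candidates
  are excluded with a count rather than resolved by exact algebraic
  decomposition.
- Hysteresis scores aggregate over one threshold-order class of the input
  node; cross-class aggregation (classes are γ-incomparable, so no
  monotone path crosses classes) is not implemented.
- The sampling distribution over unbounded regions is a documented
  package choice; quantities derived from it are trend-level.
- The essential read-out set for multi-threshold output nodes follows this
  package's essentiality definition; historical region tables used a
  convention that could not be reconstructed, so partial-path percentages
  agree with the reference values only to a few points (full-path scores
  agree exactly).
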