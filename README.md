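# switchgrade

Combinatorial screening of small gene regulatory networks for robust
bistable-switch (hysteresis) behavior, with Hill-ODE continuation
validation.

## Who this is for

Synthetic biologists and modellers who want to rank candidate circuit
topologies — small signed digraphs of activating (→) and repressing (⊣)
interactions — by how robustly they can act as a hysteretic switch: off at
low input, on at high input, bistable in between, *before* committing to a
specific ODE parameterization. The combinatorial engine covers the whole
parameter space of a design in seconds; the Hill-model validator then
checks the prediction at biologically plausible nonlinearity steepness.

## The model

Each node `n` carries a level `x_n` that decays at rate `γ_n` and is
produced at a piecewise-constant rate determined by which inputs sit above
their thresholds. An edge `m → n` contributes a low rate `ℓ_{n,m}` when
`x_m < θ_{n,m}` and a high rate `ℓ_{n,m} + δ_{n,m}` above it; activating
contributions are summed and each repressing input multiplies the sum by
its own two-level factor. For one node, the finitely many ways its
production values can interleave with its scaled out-thresholds `γ_n θ`
define the **factor graph** `PG(n)`: one vertex per realizable open
parameter region (a threshold order plus a nested chain of "above"
sets), edges between regions sharing a codimension-one boundary.
Realizability is decided exactly by linear feasibility for pure-sum and
pure-product input logic and by seeded slack maximization for mixed logic.
The **parameter graph** `PG = ∏_n PG(n)` then indexes every qualitatively
distinct dynamics of the network.

At each parameter-graph vertex, phase space is cut by the threshold
hyperplanes into boxes; each shared wall is crossed in the direction of the
flow sign `-γ_n θ + Λ_n(x)`, giving a **state transition graph** whose
condensation is an acyclic **Morse graph**. Minimal Morse nodes labelled
`FP(α_0, α_1, α_2)` are the attractors (`α_k` = number of thresholds below
the stable level of `x_k`). Nodes without out-edges get a placeholder
threshold, and self-repressing nodes get a doubled self-threshold so that
walls attracting from both sides become thin cells of their own.

A rising input to node 0 is a monotone path through `PG(0)`. A path
**exhibits ascending hysteresis** when its start is monostable with the
output low (`FP(·,·,0)` only), its end monostable with the output high,
and some strictly intermediate vertex holds both attractors at once. The
**hysteresis score** of a network is the percentage of (path,
parameter-vertex) pairs with this property over the essential vertices of
`PG(1) × PG(2)`; the **perturbed score** enlarges that set to its closed
one-edge neighborhood; their ratio is the **robustness score** (≤ 0.5 =
fragile). Descending hysteresis is the mirror. The Hill validator replaces
the step rates by Hill functions `ℓ + δ·x^n/(θ^n + x^n)`, samples certified
parameter points from a chosen region, and traces equilibrium curves in
the input signal by pseudo-arclength continuation, declaring a point
hysteretic when a curve completes with an even number (≥ 2) of folds that
step the output in the expected direction.

## Worked example

The activating three-cycle `0 → 1 → 2 → 0` is the smallest perfect — but
fragile — switch. With the network file

```
x0 : (x2)
x1 : (x0)
x2 : (x1)
```

```
$ switchgrade score net1.txt --parameter-set perturbed
{
  "denominator": 5,
  "mode": "ascending",
  "n_parameter_vertices": 5,
  "n_paths": 1,
  "network": "x0 : (x2)\nx1 : (x0)\nx2 : (x1)",
  "numerator": 1,
  "parameter_set": "perturbed",
  "path_kind": "partial",
  "score": 20.0
}
```

Each node has one in- and one out-edge, so each factor graph is a
three-vertex path (production below, straddling, or above the scaled
threshold) and the parameter graph has 27 vertices. `PG(1) × PG(2)` has a
single essential vertex, and the unique monotone path in `PG(0)` sweeps
monostable-low `FP(0,0,0)` → bistable → monostable-high `FP(1,1,1)`:
hysteresis score 100 %. But of the 5 vertices within one edge of the
essential pair only the essential one still switches — the perturbed score
above is 1/5 = 20 %, robustness 0.2, and the design is classified fragile:
remove any edge and the switch is gone.

The same pipeline in Python:

```python
from switchgrade import make_fixture, hysteresis_score
net = make_fixture("network12").network      # six-edge all-activator design
rep = hysteresis_score(net, "ascending", "full", "essential")
print(rep.score)                              # 100.0
```

which counts 292,217,420,280 (path, vertex) pairs by dynamic programming
over the 707-region factor graph of node 0 — every full signal sweep of
this design switches, at every essential parameter vertex. A batch ranking
over many networks is `switchgrade screen --enumerate-3node --out rank.csv`
(the full 14,069-network screen is cluster-scale; use `--skip/--limit` for
resumable slices), and

```
$ switchgrade hill-validate net12.txt --hill-n 30 --samples 12 --seed 5 --out hill.csv
hill_n,parameter_set,frequency,n_samples,failures
30.0,essential,100.0,12,0
```

validates the prediction on Hill ODEs at steepness 30.

## Layout

- `switchgrade.networks` — network dialect, enumeration, trivial filter
- `switchgrade.factor` — per-node region enumeration (factor graphs)
- `switchgrade.pgraph` — product graph, essential sets, regions, sampling
- `switchgrade.dynamics` — cubical complex, wall labels, STG, Morse graph
- `switchgrade.scoring` — monotone paths, hysteresis/robustness scores
- `switchgrade.hill` — Hill systems, continuation, Monte-Carlo validation
- `switchgrade.fixtures` / `switchgrade.cli` — reference networks, CLI

See `docs/methods.md` for modelling assumptions, numerical choices and
known limitations.
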