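# Methods

## Model

`csrpath` couples two model classes over one condition set. The canonical
layer is a Boolean hypergraph: a reaction has activator and
inhibitor-reactant sets and one product; it fires in condition `k` iff it
is present (`y_i = 1`), every activator is active, every
inhibitor-reactant is inactive, and no applied drug silences it. A species
is the OR of its producing reactions; stimuli are clamped to the
condition's settings. States are the **least fixed point** from the
all-off state, computed by synchronous sweeps — this makes simulation a
function of (presence, condition), matches the unstimulated-equals-off
baseline of CSR data, and rules out self-sustaining loops.

The non-canonical layer attaches weighted edges from measured signals to
response species. Weights come from a no-intercept least-squares fit of
the response matrix on the signal matrix: a coefficient is interpreted as
the stoichiometric yield of its edge, and an intercept would have no edge
interpretation (basal response is absorbed by normalisation instead). With
fewer conditions than signals, or an exactly collinear design, plain least
squares is refused (naming the dependent columns) unless a small ridge
penalty is passed. Pruning retains a fixed fraction (default 60 %) of the
largest-|w| coefficients **globally over the whole matrix**, with
deterministic (response, signal) lexicographic tie-breaking.

A measured response `j` with candidate incoming weights `w` has yield
bounds `B_min = Σ min(w, 0)`, `B_max = Σ max(w, 0)` (empty sums 0), taken
over the *candidate* edge set so that the scale is fixed regardless of
which edges survive pruning. Its prediction is
`s = (Σ w_i z_i − B_min)/(B_max − B_min)`, which lies in [0, 1] for every
activation pattern; degenerate bounds (`B_max = B_min`, only possible with
all-zero weights) drop that response from the objective with a warning.

## ILP formulation

Variables: binary `y_i` per reaction/edge, `z_i^k` per reaction/edge ×
condition, `x_j^k` per non-stimulus non-response species × condition, and
continuous deviations `e_j^k ∈ [0, 1]` per measured response entry. The
firing rule is linearised as `z ≤ y`, `z ≤ x_a`, `z ≤ 1 − x_q`,
`z ≥ y + Σx_a − Σx_q − |inputs| + const`, and the OR rule as `x ≥ z_i`,
`x ≤ Σ z_i`; stimulus states are substituted as constants. On acyclic
networks the feasible (x, z) for a fixed y is unique and equals forward
simulation — the package asserts this equivalence on every solve by
recomputing the objective from the returned presence vector via
simulation (tolerance 1e-6).

Objective: `α_sig` times the L1 signal mismatch (each binary-state term
`|x − m|` encoded exactly by the affine form `m + (1 − 2m)x`), plus
`α_res Σ e` with `e ≥ s − m`, `e ≥ m − s`, plus `β Σ y_i` over canonical
reactions *and* non-canonical edges (both are prunable and both count
toward map size; "size" counts edges, not species). Defaults
`α_sig = α_res = 1`, `β = 1/20`: the size reward for deleting a chain of
up to 20 reactions (20β = 1) can never outweigh one unit of mismatch, so
essential chains survive. Unmeasured species contribute no mismatch term;
a measured response with no candidate edges contributes its measured value
as a constant (its prediction is identically 0).

Cycles: the canonical sub-network is expected to be feed-forward.
Validation enumerates directed cycles as warnings; ILP compilation refuses
cyclic networks unless `allow_cycles=True`, in which case a grounded
justification encoding (per-condition justifier variables `u ≤ z`,
`x ≤ Σu`, plus continuous rank variables that must strictly increase
along justifying reactions) restricts feasible states to the least fixed
point. Inhibitory arcs lying on a cycle are refused outright — a least
fixed point is not well defined under cyclic negation, and forward
simulation likewise raises if synchronous sweeps fail to converge within
2·|species| iterations.

Inhibitor semantics (default `block-activity`): an applied drug masks the
*output activity* of its target species — the target contributes 0
wherever it is consumed (as activator, as inhibitor-reactant, as a
non-canonical edge source) while its own state may still be 1. This
matches kinase inhibitors, which block catalytic activity rather than the
target's phosphorylation (the target is still measured phosphorylated
while its substrates go silent). The alternative `clamp-node` mode forces
the target's state to 0. Two drugs may map to the same target species.

## Solver and solution pool

The backend is HiGHS via `scipy.optimize.milp` (`mip_rel_gap = 0`,
default integrality/feasibility tolerances 1e-6/1e-7), which certifies
global optimality. The near-optimal pool is harvested iteratively: solve,
record, exclude the found presence vector with a no-good cut
(`Σ_{y*=0} y + Σ_{y*=1} (1−y) ≥ 1`), repeat while the objective stays
within tolerance (default 10 %) of the optimum and the pool is below its
cap (default 100). Cuts touch only `y`, so "distinct" means distinct
topology, not distinct state assignment. When fewer near-optimal
topologies exist than the cap, the pool is provably complete. For a zero
optimum, where relative tolerance is undefined, the cutoff is one
map-size unit (`optimum + β`). Discovery order may vary between solver
versions; edge frequencies (share of pool solutions containing each edge)
are order-invariant and are what downstream code should consume.

Fit error is the mean absolute deviation between simulated and measured
values over **all** measured signal and response entries jointly, × 100.
Signals and responses are averaged in one pool rather than separately;
with equal mismatch weights the two conventions rank topologies
identically, and joint averaging keeps the statistic a single number.

## Normalisation

Raw fluorescence is mapped to [0, 1] per readout by a noise-gated,
basal-relative Hill filter: changes within the assay noise floor (default
166 fluorescence units, the spread of repeated unstimulated controls) map
to 0; otherwise the relative change `c = max(0, raw − basal −
noise_floor)/basal` is passed through `H(c) = c^n/(K^n + c^n)` (defaults
`n = 2`, `K = 1`, i.e. half-effect at a 100 % increase over basal);
values at or above the declared assay saturation map to 1. Decreases
below basal map to 0 by default — the Boolean model has no below-basal
state — with a two-sided option that scores |change|. All four parameters
are configurable; the filter is invariant to rescaling raw units when the
unit-bearing parameters are rescaled identically. A zero basal falls back
to absolute change.

## Synthetic data

The generator emulates the targeted study design: by default 7 stimuli +
5 inhibitors in a single-stimulus × single-inhibitor factorial (48
conditions), 16 measured signals, 22 responses, 113 canonical reactions,
352 candidate non-canonical edges. Species are laid out in a fixed
topological order (stimuli → intermediates → signals) and every reaction
points forward in it, so generated maps are acyclic by construction; each
non-stimulus species first gets one backbone producer so the map is
reachable, then extra reactions (occasionally AND-gates or
inhibitor-gated) are added. Non-canonical weights are uniform on
[−1, −0.1] ∪ [0.1, 1] — bounded away from 0 so every true edge is in
principle detectable. Measurements are the simulated states/scaled
responses of the *true* sub-network plus additive Gaussian noise (default
sd 0.05 on the [0, 1] scale), clipped to [0, 1].

A candidate network may include **decoy reactions** with ground-truth
presence 0: datasets are simulated without them, so decoys are exactly
the edges the data argues against — this is what makes edge-recovery
benchmarks meaningful. Recovery is scored against an operational
classification by forced solves: an edge is *identifiable* when pinning
it out pushes the optimum above the pool cutoff (every pooled solution
must then contain it) and *contradicted* when pinning it in does.

The harness also mirrors the two sensitivity protocols: substituting a
fraction of reactions with random forward-pointing ones (acyclicity
preserved; substitutes avoid duplicating kept reactions) and removing a
fraction of treatments at random, refitting, and evaluating the fit error
on the full design. Benchmark sizes used in the test suite (30-reaction /
8-signal / 8-response maps, 48 conditions, 10 seeds) keep the full pool
harvest to a few seconds per seed.

What the generator does **not** emulate: correlated (plate/batch) noise,
missing-value patterns, saturated or sub-basal raw dynamics beyond the
clipping, unmodelled crosstalk, or the curated structure of a real
literature map. Passing recovery benchmarks therefore demonstrates the
correctness and calibration of the inference machinery, not performance
on real phosphoproteomic data.

## Known limitations

* Boolean states cannot express graded signal activation; a response
  driven by a sub-threshold signal change can be missed (normalisation
  thresholds matter).
* MLR weights are fitted once against measured signals and are not
  re-estimated inside the ILP; strongly collinear signals spread weight
  arbitrarily (ridge mitigates, no sign guarantees).
* The pool cap (100) is a sample when the near-optimal set is larger;
  frequencies are then estimates relative to the enumeration order's
  coverage rather than the full set.
* Cyclic maps are supported only without inhibition on cycles.
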