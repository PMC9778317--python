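# Methods

This note documents the model, the numerical choices, the synthetic
environments, and the open design decisions made in building `ehc-compose`.
It states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Model

### Generators and propagators

State spaces are finite graphs. A generator `O` is an `n×n` rate matrix
(non-negative off-diagonals, zero-sum rows) driving the master equation
`τρ̇ = ρO` for the state-probability row vector `ρ`. The one-step
propagator is `P = exp((dt/τ) O)`, computed spectrally as
`G · diag(s(λ)) · W` from the eigendecomposition `O = GΛW`, `W = G⁻¹`.
In the circuit reading, `G` and `W` are the two synaptic weight matrices of
a linear feedback network (place layer → grid layer → place layer), each
column of `G` is one grid cell's firing map, and the power spectrum `s` is
a per-component gain — so tempo and stability changes are gain changes, not
weight changes.

The random-walk convention is `O = T − I` with `T` the degree-normalised
adjacency: every state has unit exit rate. This puts the spectrum of every
explore-type generator in `[−2, 0]` regardless of graph size, so one
power-spectrum parametrisation behaves uniformly across environments
without per-graph rescaling. The alternative graph-Laplacian convention
(`A − D`) would make exit rates degree-dependent and the spectrum
size-dependent.

### Power spectrum, tempo, stability

* `α = 1` (diffusive): `s(λ) = exp((dt/τ)λ)`; decay comes from
  `Re λ ≤ 0`, and `s(0) = 1` preserves stationary mass.
* `α < 1` (superdiffusive): `s(λ) = exp(−(dt/τ)(−λ)^α)` with the principal
  branch. On the real non-positive axis this is `exp(−(dt/τ)|λ|^α)`; the
  principal branch is the unique continuous extension needed for the
  complex conjugate eigenvalue pairs of directed (non-symmetric)
  generators. This is the subordinated (fractional) semigroup
  `exp(−t(−O)^α)`, which is again a stochastic matrix; its one-step rows
  have heavier jump tails ("occasional jumps" — verified on a 40-state ring
  in the test suite).

Defaults are `τ = 1` and `α = 1`, with `α = 0.5` as the superdiffusive
setting. Eigenvalues are sorted by descending real part (ties by ascending
imaginary part) so `G`, `W`, and exported component maps are reproducible
bit-for-bit.

### Sanitisation and numerical tolerances

Raw spectral products are real up to round-off for real generators because
complex eigenpairs conjugate-cancel; an imaginary residual above `1e-6`
raises (it means a broken basis, not round-off). Entries in `[−1e-6, 0)`
are clipped to zero and rows renormalised to sum exactly 1; the clipped
magnitude is recorded on the propagator (`clip_magnitude`). Anything below
`−1e-6` raises rather than being silently repaired. The one exception is
the truncated Zassenhaus product, whose entries may legitimately go
negative by up to its truncation error (`M = exact + E`, `exact ≥ 0`):
there the clip threshold is `max(1e-6, 2·residual)` with the residual
measured against the exact conjunctive propagator, and a residual larger
than 10× an order-implied norm bound still raises (that guard caught
nothing in practice but exists to expose sign/order convention bugs
loudly).

Eigendecomposition is rejected when the eigenvector matrix condition
exceeds `1e12` (defective generators — the absorbing lap chain is the
canonical case), and the caller falls back to a truncated power-series
exponential. The public `series_propagator` is the literal truncated sum
`Σ_{k≤n} (tO)^k/k!` (it doubles as the package's internal oracle and obeys
examples like `n_terms=1 → I + tO`); internal exponentials of composition
factors use the same series with scaling-and-squaring for norms above 1.

### Composition

* **Stacking**: ordered matrix product, row-vector convention (first
  propagator acts first). Order matters exactly when the factors do not
  commute.
* **Conjunctive**: exponentiate `Σ w_i O_i` (non-negative combinations of
  generators are generators). Built spectrally, series fallback when
  defective.
* **Interface (Zassenhaus)**: `exp(t(A+B)) ≈ e^{tA} e^{tB} e^{t²C₂}
  e^{t³C₃} e^{t⁴C₄}` with

      C₂ = −[A,B]/2
      C₃ = [B,[A,B]]/3 + [A,[A,B]]/6
      C₄ = −[A,[A,[A,B]]]/24 − [B,[A,[A,B]]]/8 − [B,[B,[A,B]]]/8

  The sign/order convention was pinned numerically before being frozen:
  the residual against the direct exponential scales as `t^(order+1)`
  (halving `t` divides the order-m residual by `2^(m+1)`) and decreases
  strictly from order 1 to 4 on random noncommuting rate-matrix pairs at
  `t = 0.5`. The expansion is asymptotic in `t`; convergence checks are
  run at `t ≤ 0.5` while experiment defaults use `dt = 1` only for
  commuting or nearly-commuting components. Correction matrices have
  zero-sum rows but can carry negative off-diagonals — they are algebraic
  devices, not Markov operators, and only the final product is required to
  be stochastic. More than two components fold left-to-right as pairwise
  interfaces (the accumulated product stands in for the exponential of the
  accumulated sum).
* **Sequencing**: temporal composition. Each stage is a propagator plus a
  hand-off condition — a region (leave when the sampled state enters it), a
  step budget, or both (whichever fires first). A region hand-off that
  never fires returns a truncation-flagged sequence rather than raising;
  the experiment layer counts flags and errors only above 20%.

Kronecker lifting embeds an outer generator `A` and inner generator `B`
into their product space as `A⊗I` and `I⊗B` (lap-major ordering). Because
the lifts act on disjoint index factors, and floating-point multiplication
is commutative entrywise, their commutator is *exactly* zero — the
acceptance script reports this max-absolute entry as its first quantity.

## Synthetic environments

All data are generated by the package; there are no external inputs.

* **Four-room grid world**: `(2r+1)×(2r+1)` grid, wall lines along the
  central row/column, four single-cell doorways near wall midpoints.
  Default `r = 5` (11×11, 104 states). Doorway cells are their own states
  and belong to *no* room region, so room-targeted row scaling leaves
  transit past the room untouched. Default avoidance scale `c = 10`
  (`c = 1` disables avoidance exactly).
* **T-maze**: corridor of `central_len` states (base → junction) plus two
  arms of `arm_len` states; defaults 8 and 6, giving a 20-state maze and a
  14-state base-to-arm-end geodesic. State order is corridor-then-arms;
  geodesics use breadth-first search with lowest-index-predecessor
  tie-breaking so the coverage statistic is deterministic.
* **Track × laps**: square perimeter loop (10×10 grid perimeter, 36
  states) crossed with a 4-state lap chain, lap-major indexing, no
  cross-lap adjacency (lap transitions belong to the lap generator).
  The track generator prefers the counterclockwise successor with drift
  0.8; the lap chain is absorbing at lap 4 (one trial ends after the last
  lap) with advance rate 1/60 — roughly one lap advance per track circuit,
  since the drifted walk moves ≈ 0.6 positions per unit time around the
  36-state loop.

Environment sizes are package choices at desk scale; they are not data
constraints. What the generator suite emulates is transition *structure*
(rooms, arms, laps, loops); what it does not emulate is measurement noise,
cell sampling variability, finite trial counts, or behavioural variability
of real recordings — so passing tests validate the mechanism, not its fit
to any particular dataset.

## Experiments

### Explore + avoid

Both conditions run the same two-layer stacked network so that depth
(integrated time per pass) is matched: the avoidance condition stacks the
exploration propagator with the avoid-room propagator; the control stacks
it with the degenerate `c = 1` avoid layer, which *is* the exploration
propagator. The difference of the two 20-step propagation densities then
isolates the avoidance content — it is exactly zero at `c = 1`, and at
`c = 10` the avoided room loses mass from the experiment's top-left-room
start. (A one-layer control would confound avoidance with propagation
speed: a two-layer stack advances two time units per pass.)

### Extended replay

The central generator drifts toward the junction within the corridor; the
lateral generator drifts toward the left arm end within the left arm *and
at the junction* — the turn belongs to the lateral behavioural component,
so a sequence handed off at the junction flows into the arm instead of
dithering on an undirected junction row. Segmented condition: independent
20-state events, half initialised at the corridor base (central
propagator), half at the junction (lateral propagator). Composed
condition: per-burst trajectories concatenating two events (central until
junction entry or budget exhaustion, then lateral), up to 40 states total —
the concatenation is the phenomenon, so the composed trajectory is longer
than any single event by construction. Every sequence is scored as the
percentage of the base-to-arm-end geodesic it visits, the goal arm chosen
per sequence by maximal geodesic overlap (ties to the left arm). The
comparison is a one-sided Mann-Whitney U test (composed greater): exact
null distribution for tie-free groups below n = 8, otherwise mid-rank
normal approximation with tie correction — coverage is discrete, so ties
are the norm at small n. A null configuration (both groups composed, from
disjoint stream indices) keeps the test honest; its p-values are uniform
across seeds (Kolmogorov–Smirnov check in the acceptance battery).

Randomness: one counter-based Philox stream per sequence keyed by
`(seed, sequence_index)`, so batches are bit-reproducible and independent
of execution order, and sampling uses inverse-CDF draws for cross-platform
stability.

### Event-specific rate remapping

The lifted track and lap generators compose conjunctively with weights
`(τ_box, τ_lap) = (1, 1)` (the lap chain's slowness is in its rate, not its
weight). The composed sum is defective (absorbing lap), so the propagator
comes from the series fallback. Each of the 144 lap-by-track units `u` gets
a firing map over initialisation states: the `k`-step propagated density of
a delta at each state, evaluated at `u`, reshaped to (lap, position).
Default horizon `k = 3` keeps maps place-field-like while mixing laps; it
is a config knob, and the firing-rate model (delta initialisation, k-step
horizon) is an interpretation — the underlying experiment's rate model is
under-specified. The preferred lap is the argmax over laps of the unit's
peak rate (ties to the lowest lap). A unit *shows lap preference* (rate
remapping) only if it is active on at least two laps with a strict peak
maximum: remapping means firing on several laps at different rates, so a
unit confined to a single lap has nothing to remap across. With the lap
weight at zero the composed propagator is block-diagonal in laps, every
unit is active on exactly one lap, and no unit shows lap preference; at
default weights every unit attains its maximum on its own lap coordinate.

## Problem sizes

Default experiment sizes — 104-state four-room map, 20-state T-maze with
50 sequences per condition, 144-state lap-by-track space — and the test
battery sizes (20 random graphs up to 30 states for oracle equivalence,
10 random 6-state pairs for Zassenhaus convergence, 200 seeds for rank-test
calibration and tempo monotonicity) were chosen to keep every quantity
statistically unambiguous at desk scale.

## Known limitations

* Continuous state spaces, hexagonal lattices, and continuous attractor
  dynamics are out of scope; spectral components are plain eigenvectors
  (no non-negativity constraint), so they are not directly comparable to
  rectified firing rates.
* The Zassenhaus interface is truncated (order ≤ 4) and asymptotic in `t`;
  it is not a substitute for the exact conjunctive propagator when
  components are strongly noncommuting at large `t`.
* The replay and ESR simulations reproduce mechanisms and qualitative
  signatures; no fitting to electrophysiology or calcium data is
  performed or supported.
* `alpha < 1` requires a diagonalisable generator (the series fallback
  only computes the `α = 1` exponential).
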