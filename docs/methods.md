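# Methods

## Model class and state basis

`autolump` operates on linear, time-invariant compartmental systems
`dy/dt = K y`. States are **concentrations**; a bolus dose of mass `D` into
state `i` sets `y0[i] = D / V[i]`. When per-state volumes are available, the
amount-basis matrix `diag(V) K diag(V)⁻¹` must have every column sum ≤ 0
(no mass created), strictly negative exactly where elimination occurs — this
is validated at construction. Nonlinear kinetics, time-varying parameters
and infusion inputs are out of scope; dosing is bolus-only.

For perfusion-limited PBPK construction (`build_rate_matrix`), tissue `i`
receives arterial blood at rate `Qᵢ/Vᵢ` and returns drug at its emergent
concentration `Cᵢ/Kpᵢ`; the lung carries the whole cardiac output in series
between the venous and arterial pools; portal tissues hand their venous
outflow to the liver, whose own outflow then carries the total (hepatic
artery + portal) flow; intrinsic clearance adds `CL/(V·Kp)` to the clearing
tissue's diagonal; deep sub-compartments exchange first-order with their
parent on the amount basis. Total tissue flow must equal cardiac output to a
relative tolerance of 10⁻⁶. Units in the bundled models are minutes, litres
and micrograms, but the core is unit-agnostic.

## Simulation and exposure

Trajectories use the closed form `y(t) = expm(K t) y0` (scipy's matrix
exponential; a single per-step propagator on uniform grids). The exposure
metric is the output-state AUC to infinity: for stable nonsingular `K` the
linear solve `(−K⁻¹ y0)[output]`; if `K` is singular, a quadrature fallback
integrates the matrix-exponential solution over doubling horizons until the
projected tail is below 10⁻⁹ relative, and raises an infinite-AUC error if
the observed state does not decay (e.g. closed systems). These tolerances,
like the 10⁻⁸/10⁻⁶ oracle agreements asserted in the tests, are
implementation choices.

## Lumping algebra

Partitions are stored as canonical restricted growth strings (block labels in
order of first appearance), which removes block-label symmetry, makes equal
partitions compare equal, and makes the search space the set of set
partitions rather than labelled assignments. The naive labelled count
(e.g. 16¹⁶ ≈ 1.8×10¹⁹ for 16 free states) is still exposed for reporting via
`labeled_assignment_count`. `M` is materialised from the partition on
demand; `M⁺ = Mᵀ diag(1/|block|)`, so `M M⁺ = I` holds exactly in exact
arithmetic (the test verifies this with rational arithmetic; the floating
product is within a couple of ulps). The lumped initial condition is
`ŷ(0) = M y(0)` — the standard proper-lumping choice, exact at t = 0.
Lumped block volume is the member sum; lumped flow is the member flow sum;
the lumped partition coefficient uses a **volume-weighted mean**, flagged as
`kp_rule = "volume_weighted_fallback"` in the returned records — it is exact
when members share a Kp and is the package's chosen convention for mixed
blocks of tissues; blocks containing blood, lung or sub-compartment states
report undefined (None) physiological parameters rather than erroring.

## Acceptance criterion

`ARD% = |AUC_lumped − AUC_ref| / AUC_ref × 100` with the **original** model's
AUC as the fixed reference denominator (at the default 0.002 % tolerance the
choice of denominator is numerically immaterial, but a fixed reference keeps
the criterion a true function of the partition). The reference AUC is
computed once per evaluator and cached. A lumped matrix `K̂ = M K M⁺` of a
stable system can itself be unstable or singular; such partitions have no
finite AUC and are scored `inf` — never acceptable — with a diagnostic
message, rather than returning a silent number. A trajectory sum-of-squares
criterion on a fixed time grid is provided as an alternative discrepancy
measure; it is not used for acceptance decisions.

## Search

All methods share one incremental outer loop: start fully lumped
(`m = 1 + number of constrained states`), ask the inner algorithm for an
acceptable partition at the current `m`, increment `m` on failure, stop at
the first acceptable `m`; reaching `m = n` returns the identity model, which
is exact. Constrained states (by default the output state in the CLI) remain
singleton blocks throughout.

* **Enumeration** iterates restricted growth strings in lexicographic order
  with exactly `k` free blocks; the count equals the Stirling number
  S(free, k), which the tests check against a brute-force oracle. Within the
  incremental loop the scan short-circuits at the first acceptable partition
  (order-dependent, so never used as a numeric target); `full_enumeration_at_m`
  also returns the order-independent global minimum.
* **NARS** draws uniform random legal partitions: uniform labels with
  rejection of assignments that leave a block empty, then canonicalisation.
  Each set partition corresponds to exactly k! surviving labelled
  assignments, so the draw is uniform over set partitions (verified by a
  frequency test over S(4,2) = 7 partitions).
* **Scree + NARS**: the eigenvalues of `K` are ranked by log₁₀|λ|
  (base 10 is a convention; the default cutoff 0 means |λ| = 1 in the model's
  time units) and the count above the cutoff, floored at 2, seeds the
  starting `m`. A largest-consecutive-drop rule is available as an
  alternative. No eigenvalue↔compartment correspondence is assumed — the
  rank order alone is used.
* **Simulated annealing** at fixed `m` starts from a uniform random legal
  partition and proposes moving one free state (chosen among states whose
  block has ≥ 2 members) to a different block, so block counts are preserved
  and no block empties. Acceptance is the Metropolis rule on ΔARD%
  (`exp(−Δ/T)` uphill, always downhill); when both the current and proposed
  partitions are infeasible (infinite ARD%) the move is treated as
  indifferent and accepted, letting the chain random-walk out of unstable
  regions of partition space. One proposal per cooling cycle; the
  temperature is multiplied by the cooling factor each cycle (defaults
  `T₀ = 10⁴`, 0.999, 2×10⁴ iterations), giving the strictly geometric
  temperature trace recorded alongside current/best ARD%. Ties in ARD% keep
  the first partition encountered.

Stochastic methods consume a single `numpy` Generator seeded from the run
seed, making NARS and SA bit-reproducible.

## Synthetic generators: what they do and don't emulate

`exactly_lumpable_system(block_sizes, seed)` builds blood + lung + tissue
groups in which every tissue in a group shares one random (Q, V, Kp) draw
(the first group also shares a clearance, so the system eliminates). Merging
exactly the copies leaves the output trajectory unchanged, giving a known
ground-truth minimal lumping — the recovery tests exploit this. Real tissues
are never exactly identical, so these fixtures establish correctness of the
algebra and searchers, not how aggressively real PBPK systems can be lumped.

`random_compartmental_system(n, seed)` draws a strongly connected random
topology (a random cycle plus ~n extra edges) with log-uniform rates on the
amount basis, one eliminating state, and column sums fixed at zero elsewhere;
Gershgorin's theorem then guarantees stability, and elimination makes the
AUC finite. These systems are deliberately *harder* to lump than real PBPK
models (no parallel structure), which is why coarse lumps of them are often
unstable — useful for exercising the infeasible-partition handling.

The bundled 17-state model reproduces the fentanyl PBPK **topology**
(arterial, venous, lung, seven perfused tissues, liver + 1 deep compartment,
spleen + 1, gut + 2, portal drainage, hepatic elimination, 750 µg arterial
bolus, arterial output). Its numeric Q/V/Kp/clearance/exchange values are
synthetic placeholders — plausible adult-human physiology with
lipophilic-opioid partitioning — because the published per-tissue table was
not available for transcription; the model and its JSON asset are flagged
`synthetic_placeholder`, and tests asserting the published fentanyl numbers
skip on that flag. Structural facts (17 states, liver-only elimination,
dose, topology) are asserted regardless.

## Problem sizes and numerical choices

The test suite and acceptance script run enumeration up to S(16,2) = 32 767
partitions (m = 3 on the 17-state model), NARS up to 10⁵ samples per
increment and SA at its default 2×10⁴-iteration budget — sizes chosen so the
whole pipeline completes in minutes on one CPU while still covering every
code path at full fidelity; exhaustive enumeration at m ≥ 4 (millions of
partitions) is supported by the same code but not exercised by default.
Oracle comparisons use scipy's DOP853 adaptive Runge–Kutta at rtol 10⁻¹¹ for
trajectories (agreement demanded at 10⁻⁸ relative) and composite trapezoid
quadrature on fast/geometric grids for the AUC (10⁻⁶ relative): a single
uniform grid cannot resolve both the fast transient and the slow tail of a
stiff system.

## Known limitations

* Proper (0/1) lumping only — no weighted/improper lumping, balanced
  truncation or observer-based reduction.
* Single output state, single bolus input; multi-output criteria are out of
  scope.
* The AUC criterion integrates over the whole profile, so two different
  profiles with equal AUC are indistinguishable to it; the trajectory
  sum-of-squares criterion is provided for that case.
* The scree heuristic is a starting-point suggestion only; on systems whose
  eigenvalues cluster near the cutoff it can suggest a start far from the
  final `m`.
* Lumped systems are not guaranteed stable; unstable lumps are rejected by
  the criterion rather than repaired.
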