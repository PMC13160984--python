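# Methods

## Model summary and assumptions

The package simulates a one-dimensional slice through a cortical bone wall.
Three coupled layers are modelled, all deterministic:

1. **Signal propagation.**  Osteocytes at lattice sites `x_i = i·Δx` hold
   continuous molecule occupancies `N_i` (expected counts of an underlying
   random walk; they are never rounded to integers).  Per time step a
   fraction `q⁻¹` of a site's molecules moves left, `q¹` right, `q⁰` stays,
   and production `R·Δt` is added after redistribution.  Jumps beyond the
   extreme osteocytes are absorbed: the effective absorbing "ghost" sites
   sit at `(i₋−1)Δx` and `(i₊+1)Δx`, one spacing beyond the extreme cells,
   and absorbed molecules accumulate in per-surface counters whose per-step
   increments define the outgoing fluxes `J±`.
2. **Mechanotransduction.**  Production is proportional to the normalised
   stimulus minus first-order degradation, with the stimulus either the
   stress `σ = F/(LW)` or the strain energy density `Ψ = σ²/(2E)`.  `L(t) =
   b₊ − b₋` uses the continuous boundary positions; under a force gradient
   each osteocyte evaluates `F(x_i, t)` at its own position while the
   denominator `L·W` is global.  The model is compression-only; negative
   forces are rejected rather than extrapolated.
3. **Cell response and boundary motion.**  The default *differential* cell
   model integrates osteoblast/osteoclast populations (explicit Euler at
   the global `Δt`) from the relative flux excess/deficit with first-order
   elimination; populations are continuous non-negative reals representing
   averages over a surface patch, and both types may coexist transiently.
   The *instantaneous* model (speed directly proportional to the flux
   imbalance) is retained for phase-portrait analysis only: with moving
   boundaries it is prone to growing oscillations, which is why the
   differential model is the default.  Boundaries move with speed
   `k_f·Ob − k_r·Oc` (outward positive); advancing a full spacing beyond
   the extreme osteocyte creates a new one with zero molecules, receding
   onto an osteocyte removes it and credits its molecules to the surface
   counter in the same step (producing the characteristic one-step flux
   spike).

Step ordering within one update: (1) occupancy update and flux accounting,
(2) cell populations from the fluxes, (3) boundary motion, (4) osteocyte
creation/removal, re-applied until no rule fires.  Creation uses a strict
inequality (`b₊ > x_{i₊} + Δx`), removal a non-strict one (`b₊ ≤ x_{i₊}`),
so a boundary landing exactly on an osteocyte removes it.  Runs start from
the continuum steady state at the initial width and force (occupancies
`N_i = Δx·n̄(x_i)`, no cells, zero counters) and are first left to settle
under the reference force before any protocol change.

## Parameters

Internal units are µm / day / N / MPa throughout; all conversions live in
`osteonet.parameters`.

| parameter | default | units | role |
|---|---|---|---|
| Δx | 10 | µm | osteocyte spacing; density ρ = 1/Δx is tied to it exactly |
| Δt | 1e-5 | day | explicit step; requires λ₂Δt < 1 and A·Δt < 1 |
| q⁻¹, q⁰, q¹ | 0.32, 0.36, 0.32 | — | jump fractions; sum to 1, unbiased |
| λ₁ | 11 059 200 | /day | production scale (128/s); sets occupancy magnitude |
| λ₂ | 320 | /day | degradation; with D gives Λ_D = √(D/λ₂) = 100 µm |
| W | 20 | µm | lateral spacing; only sets the force scale |
| L̄, F̄, σ̄, Ψ̄ | 200 µm, 0.04 N, 10 MPa, 5e-3 MPa | | reference state, σ̄ = F̄/(L̄W), Ψ̄ = σ̄²/2E |
| E | 1e4 | MPa | Young's modulus (10 GPa, mouse cortical bone) |
| J₀ | derived | /day | reference flux ρλ₁Λ_D·tanh(L̄/2Λ_D) ≈ 8.42262e7 |
| k_f, k_r | 20, 100 | µm/day·cell | bone formed/resorbed per cell |
| α_Ob, α_Oc | 0.04, 0.2 | /day | cell generation strengths |
| A_Ob, A_Oc | 0.2, 1 | /day | cell elimination rates |
| v_f, v_r | 10, 10 | µm/day | instantaneous-model speeds (phase portraits) |

Derived quantities (D, Λ_D, J₀) are always computed from the primitives —
a configured `J₀` deviating from the calibration constraint by more than
0.01% is rejected — so displayed and effective values cannot drift apart.
The calibration chain pins `D = 3.2 mm²/day` (rms displacement ≈ 9 µm/s,
comparable to calcium-wave speeds), `Λ_D = 100 µm` (large enough for
diffusion-dominated transport at the 200 µm reference width, small enough
that the force–length law is not degenerate), and `J₀/λ₁ = 10·tanh(1)`.

## Scenario conditions (the study protocols)

The built-in scenarios fix the loading schedules: overload–unload (F̄ to
40 d, 1.2·F̄ to 200 d, F̄ to 400 d), unload–reload (same times with 0.8·F̄),
disuse under either stimulus (F̄ to 20 d, then 0.02 N), and the gradient
run (F̄ + 5e-5 N/µm·x).  End times not fixed by the protocols are package
choices: 150 d for stress-disuse, 80 d for strain-energy disuse (steady by
~50 d), 100 d for the gradient run.  Sampling stores a record every 0.01
day plus one at every topology event; the raw 1e-5-day steps are not
storable.  These schedules *are* the synthetic data of the package — there
is no measured input anywhere — so passing tests demonstrate internal
consistency of the model and its continuum analysis, not agreement with
any experimental bone data.

## Numerical choices

* **Inner loop.**  A numba-compiled kernel advances occupancies, cells,
  boundaries and topology (≈1e7 steps/s single-threaded), with
  pure-NumPy single-step functions kept as the reference implementation;
  a test drives both through identical histories (including topology
  events at exaggerated cell kinetics) and requires agreement.
* **Stability guards.**  The explicit update requires `λ₂Δt < 1` and
  `A·Δt < 1` (validated); occupancies are clamped at zero with a warning
  if an update would undershoot (it does not at default parameters).
* **Hyperbolics.**  All cosh/sinh ratios are evaluated in overflow-safe
  form, and the gradient boundary fluxes use a cancellation-free
  regrouping (`tanh(z/2)` and `1 − z·csch z` factors) exact for widths
  both much smaller and much larger than Λ_D; the small-z branch switches
  to a series below z = 1e-3.
* **Root finding.**  The Wolff-law inversion brackets on (0, 10·L̄] and
  uses Brent's method at 1e-9 relative tolerance; forces below the
  stress-mode threshold report "no solution" rather than an error.
* **Fixed-boundary steady state.**  The discrete/continuum flux comparison
  iterates the lattice update until the per-step relative flux change is
  below 1e-10; a direct linear solve of the fixed point is used as an
  independent oracle in the tests.
* **Phase-portrait sign convention.**  The boundary-evolution law makes
  formation extend the wall outward on both sides, so the left-boundary
  velocity is `db₋/dt = −v(J₋−J₀)/J₀` (and `db₊/dt = +v(J₊−J₀)/J₀`); the
  consistency of this sign with the instantaneous cell model is asserted
  in the tests (an underloaded left surface recedes inward).

## Behaviours worth knowing about

* **Discrete steady widths are short.**  At the reference spacing the
  lattice surface flux is ≈6.5% below the continuum closed form (a
  first-order one-sided-difference effect of the ghost-site registration;
  it halves with each spacing refinement), so the moving-boundary model
  equilibrates at L ≈ 187 µm rather than 200 µm under the reference force.
* **History dependence.**  A 20% unload/reload cycle removes four
  osteocytes per surface but regenerates only three, leaving the wall
  permanently shorter — discreteness makes the adapted state depend on
  loading history, which no continuum Wolff law can produce.
* **Topology chatter at thresholds.**  A boundary sitting exactly at a
  creation threshold while overloaded (e.g. a run started at a lattice
  multiple and immediately overloaded) generates rapid creation/removal
  pairs until the boundary moves decisively.  The standard scenarios never
  do this (they settle under-loaded first), but custom protocols can.
* **The single-osteocyte endgame.**  Under stress-mode disuse the model
  resorbs almost the entire wall, but the last osteocyte is a discrete
  "whole" producer while the stress diverges as 1/L, so the outgoing flux
  recrosses J₀ at a sub-spacing width (≈6.5 µm at 0.02 N) and a sliver can
  stabilise.  Whether the final osteocyte is removed before this rescue is
  decided by tens of nanometres of boundary travel at the default disuse
  force — the outcome at 0.02 N is knife-edge — whereas deeper disuse
  (≤0.015 N) robustly resorbs everything.  The continuum analysis, which
  scales producer number with L, predicts full resorption for any force
  below F(0).

## Limitations

One-dimensional geometry; regular osteocyte spacing; no osteocyte
apoptosis independent of resorption; no desensitisation or accommodation
(hence unbounded growth under a sustained gradient); stress and
strain-energy stimuli only (no fluid-shear or strain-rate
mechanosensation); quasi-steady continuum analysis only (no time-dependent
PDE on the moving domain).  Cell populations are mean-field; no lineage or
biochemical (RANKL/OPG-type) detail.
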