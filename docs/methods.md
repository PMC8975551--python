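# Methods

This document describes the mathematical model implemented by `bicoidms2`,
the numerical choices made, and the provenance of the built-in synthetic
fixtures.

## 1. Promoter model

### State space

A reporter promoter is modelled as a continuous-time Markov chain over
states `(i, a)`, where `i ∈ {0, …, N}` is the number of occupied activator
(Bicoid) binding sites and `a ∈ {OFF, ON}` is the promoter activity state —
`2N + 2` states in total (`promoter_model.enumerate_states`).

Transitions:

- **Binding** `(i, a) → (i+1, a)` at rate `(N − i) · kb · c`, where `c` is
  the local activator concentration and `kb` the per-site association rate
  constant.
- **Unbinding** `(i, a) → (i−1, a)` at the aggregate rate `k₋ᵢ`, supplied as
  a per-occupancy table (`KineticRates.k_off_site`). Cooperativity is
  expressed by making `k₋ᵢ` grow slower than linearly in `i` (e.g. the
  `hbP2-like` fixture multiplies the per-site unbinding by `0.6^max(0, i−3)`).
- **Promoter activation** `(i, OFF) → (i, ON)` at rate
  `k_on_base · S(i)`, where the activation weight `S(i)` is zero below the
  occupancy threshold `K` and grows with `i` above it. Two scalings are
  provided: `"binomial"` (`S(i) = C(i, K)`, the number of ways to choose the
  `K` contacting sites; the default) and `"linear"` (`S(i) = i / K`).
  Arbitrary weight tables are also accepted.
- **Promoter deactivation** `(i, ON) → (i, OFF)` at the constant rate
  `k_off_promoter`.
- **RNAP firing**: while the promoter is ON, polymerases initiate as a
  Poisson process of rate `rnap_rate`. Firing does not change the promoter
  state, so it is not part of the generator; it is layered on top
  (simulation) or handled by the Feynman–Kac operator (analytics, §3).

### Activator gradient

The activator concentration is a static exponential,
`c(x) = c0 · d · e^(−x/λ)`, with `x` the anterior–posterior position in
percent embryo length (%EL), `λ` the decay length, and `d` a dosage factor
(`d = 1` for the wild-type two-copy "2X" dosage, `d = 0.5` for "1X").
Halving the dosage is mathematically identical to translating every
concentration-determined profile anterior by `λ·ln 2`
(`BcdGradient.halving_distance`); this exact identity is used as a
validation invariant throughout the test-suite.

## 2. Numerics

### Master equation

`build_generator` assembles the `(2N+2) × (2N+2)` rate matrix `Q` (row →
column convention, rows summing to zero). Time marching uses stepwise
`scipy.linalg.expm`: the interval between requested output times is split
into uniform sub-steps and the per-step matrix `expm(Qᵀ·dt)` is computed
once per distinct `dt` and reused. For chains this small the matrix
exponential is exact to machine precision and unconditionally stable, so no
stiff ODE integrator is needed. Probabilities are clipped to `[0, 1]` and
renormalised after each step to absorb rounding.

Stationary distributions come from the null space of `Qᵀ`
(`scipy.linalg.null_space`); if the chain is numerically reducible a warning
is raised and a long-time propagation fallback is used.

### Stochastic simulation

`gillespie_simulate` is a standard direct-method SSA over the `(i, a)`
chain. RNAP initiations are added by thinning: for each ON dwell of length
`τ`, a Poisson(`rnap_rate·τ`) number of initiation times is drawn uniformly
inside the dwell. The SSA and the master equation are cross-validated in the
test-suite (time-dependent `p_ON` within 3 binomial standard errors over 500
replicates).

### MS2 signal kernel

Each initiation event contributes a trapezoidal fluorescence pulse
(`SignalKernel`): linear rise over the stem-loop transcription time
(`loop_ramp_time`, default 60 s), plateau until the polymerase completes the
gene (`elongation_time`, default 180 s), then instantaneous release. The
spot-detection threshold is 0.5 intensity units (one polymerase = 1 unit at
plateau) by default.

### Exact spot/expression probabilities (Feynman–Kac)

The probability that *no* initiation occurs in a window of length `t` is

```
P_surv(t) = 1ᵀ · expm((Qᵀ − ρ·D)·t) · p0
```

where `D` is the diagonal indicator of ON states and `ρ` the initiation
rate (`initiation_survival`). This is exact for the full bursty chain.
The mean-field alternative `1 − exp(−ρ ∫ p_ON dt)` ignores burst clumping
and, by Jensen's inequality, systematically *over*-estimates the expression
probability. Both are exposed (`method="exact"` / `"poisson"` on
`steady_state_spot_probability` and `expressing_probability_profile`);
`"exact"` is the default because it matches simulation (validated against
500 SSA replicates; the Poisson form was biased high by ≈ 0.07 for the
`B6-like` fixture at its boundary).

For the steady-state *spot detection* probability, detecting a spot at time
`t` with a zero threshold is equivalent to at least one initiation in the
preceding elongation window, so `P_spot = 1 − P_surv(τ_elong)` started from
the stationary distribution. With the default 0.5-polymerase threshold this
is a slight over-count (a single initiation within 60 s of the observation
has not yet reached threshold); the discrepancy is small and is quantified
in the test-suite rather than corrected analytically.

## 3. Pattern analysis

- **Sigmoid fits** (`pattern_fit`): `f(x) = fmax / (1 + e^((x − x0)·η))`,
  weighted least squares with binomial-motivated weights and multi-start
  initialisation. Boundary width is defined by the 5%→95% crossing,
  `w = 2·ln 19 / η`. The equivalent Hill coefficient for an exponential
  input gradient is `H = λ·η` exactly (no numerical differentiation
  needed); `numeric_hill_from_model` cross-checks this from model profiles.
- **Shift maps** (`shift_analysis`): for each position `x` and candidate
  shift `Δ`, the 2X counts at `x` are compared with linearly interpolated 1X
  counts at `x − Δ` under a Beta(1,1)-marginalised binomial likelihood of a
  shared success probability; rows are normalised into per-position
  posteriors over `Δ`. `best_constant_shift` sums the posterior rows over a
  boundary window (default 30–60 %EL), refines the argmax quadratically,
  and bootstraps over rows for a 95% CI. An `objective="log"` variant sums
  log-rows (joint posterior) instead; the choice is logged. The effective
  decay length is `λ_eff = |Δ̃| / ln 2`.
- **Berg–Purcell ratio**: for concentration sensing at a boundary `x_b`, the
  averaging time scales inversely with concentration, so the relative
  sensing time between two decay lengths is `exp(x_b·(1/λ₁ − 1/λ₂))`.

## 4. Fitting

`model_fitting` evaluates a binomial log-likelihood of an observed
fraction-active kymograph against `predicted_kymograph` surfaces and
optimises free parameters (log₁₀-space) with `scipy.optimize.
differential_evolution` (seeded Sobol initialisation, local polish).
Defaults (popsize 12, maxiter 40, tol 0.005) are smaller than a
brute-force budget because the bounded ≤4-parameter problems converge well
before that; they are configurable on `FitSpec`. Identifiability is
reported via per-parameter likelihood profiles (width at `LL_max − 2`);
parameters whose profile is flat to the bounds are flagged
`non_identifiable`.

Two practical caveats discovered during development and reflected in the
defaults/tests:

- With steady-state data only, `(k_on_base, k_off_promoter)` lie on a pure
  scale ridge — the stationary `p_ON` depends only on their ratio. Early
  time points (30–200 s) break the degeneracy; synthetic fitting data
  should include them.
- `predicted_kymograph`'s internal time step (`internal_dt`) introduces a
  small discretisation bias; when comparing likelihoods across models
  (e.g. `lambda_scan`) the fit's `internal_dt` should match the resolution
  at which the data were generated.

`lambda_scan` fits each decay length on a fixed grid and flags values whose
LL falls below the 5th percentile of a parametric bootstrap (B = 200
binomial redraws from the best-fitting surface, LL re-evaluated without
refitting).

## 5. Synthetic fixtures

No experimental data ships with the package. `synthetic_data` provides a
generator for realistic single-nucleus trace tables (mitotic-wave birth
times, per-nucleus SSA, kernel convolution, Gaussian measurement noise) and
six frozen fixture parameter sets (`B6-like`, `B9-like`, `B12-like`,
`H6B6-like`, `Z2B6-like`, `hbP2-like`). The kinetic constants are invented:
they were calibrated once, against qualitative anchors only (anterior spot
probability bands, ordering of boundary positions, near-saturation of the
strong-promoter variant), using the analytic steady-state spot probability —
not against any test outcome. All fixtures share the base constants
`kb·c0 = 0.07 s⁻¹`, per-site unbinding `0.005 s⁻¹` (aggregate `i·k_u`),
`k_on_base = 0.0021 s⁻¹`, `k_off_promoter = 0.05 s⁻¹`,
`rnap_rate = 0.018 s⁻¹`, gradient `λ = 15 %EL`; variants modify site count,
promoter kinetics, binding strength, or unbinding cooperativity.

`boundary_centered_model(λ, x_center)` builds a nine-site cooperative model
whose expression boundary sits exactly at `x_center`: `kb` is solved
numerically (Brent's method on `log kb`) so that the exact survival profile
crosses 0.5 there.

## 6. Limitations

- The gradient is static; nuclear import dynamics and gradient formation
  are outside scope.
- The trace generator uses a single common measurement-noise scale and
  ignores spot-tracking dropouts.
- The fixture constants are plausible but invented; quantitative agreement
  with any particular experimental dataset is not claimed.
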