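# Methods

## The model

The package describes the spatially averaged ("bulk") velocity of an
epithelial monolayer responding to a uniaxial DC electric field through an
excitation–adaptation cascade coupled to linear friction:

    dv/dt     = −γ v + α [s_eff]⁺          (velocity, μm/h)
    ds_eff/dt = (s − s_eff − I) / τe       (effective signal, unitless)
    dI/dt     = (s − I) / τa               (inhibitor, unitless)

with zero initial conditions.  `s(t)` is the applied field in units of the
reference strength (3 V/cm ≡ s = 1); `[x]⁺ = max(x, 0)` encodes that a
negative transduced signal produces no reverse force (monolayers do not
migrate backwards when the field switches off).  Because τe ≪ τa the
response to a constant field is transient: `s_eff` peaks at
τmax = ln(τa/τe)/(τe⁻¹ − τa⁻¹) and adapts away, and the only steady state is
full adaptation, `(v, s_eff, I) = (0, 0, s)`, with eigenvalues
(−γ, −τe⁻¹, −τa⁻¹), all strictly negative.

A sign note: a common rendering of the effective-signal equation reads
`(s − s_eff + I)/τe`, but only the `−I` grouping is solved by the standard
unit-step response

    s_eff(t) = τa/(τa−τe) · (e^{−t/τa} − e^{−t/τe}),   I(t) = 1 − e^{−t/τa},

and by the adjoint structure used throughout; the package implements the
`−I` form and a unit test pins the check.

Default parameters are posterior means calibrated to nine-replicate MDCK
pulse-stimulation data: γ = 1.765 h⁻¹, α = 149.92 μm/h², τe = 0.260 h,
τa = 2.038 h.  All internal computation is in hours, μm/h and normalised
field units; conversion by the reference field happens only at I/O.

Simulation integrates the linear system segment-by-segment across protocol
breakpoints (RK45, rtol 1e-8 / atol 1e-10, tighter than any downstream
tolerance since this layer serves as the oracle for the control solvers).
Single-pulse protocols additionally have an exact piecewise closed form —
including the post-pulse `s_eff` zero crossing at
t_c = t_end + ln(A/(−B))/(τe⁻¹ − τa⁻¹), beyond which the clamped velocity
decays exactly as `v(t_c)e^{−γ(t−t_c)}` — which is what makes the MCMC
likelihood cheap (≈0.2 ms for 9 × 33 observations).

Rate collisions (γ = τe⁻¹, γ = τa⁻¹) make the closed forms singular; they
raise a degenerate-parameters error rather than falling back to confluent
limits, which no calibrated parameter set approaches.

## Calibration

γ is identified first, from post-stimulation decay: with the field off and
`s_eff` clamped at zero, `v(t) = C·e^{−γ(t−t_end)}` with `C = v(t_end)`
pinned to the observed value, so the least-squares problem is univariate.
It is solved by bounded scalar minimisation polished with a root solve of
the SSR gradient, giving round-off-level recovery on noiseless
exponentials.  Note the small bias when the fit is anchored exactly at
field-off: `s_eff` needs ≈ 3τe·ε ≈ 0.08 h to cross zero after the pulse, so
anchoring one sample later removes the bias (the CLI test demonstrates
both).

With γ fixed, (α, τe, τa) and the noise scale σ are sampled jointly under
an iid Gaussian likelihood pooled across replicates.  Choices the
underlying analysis leaves open, fixed here as package defaults:

- **Priors**: independent uniforms α ∈ (0, 1000) μm/h², τe ∈ (0.01, 2) h,
  τa ∈ (0.1, 10) h, σ ∈ (0, 50) μm/h, with τe < τa enforced through the
  support.  Weakly informative; the calibrated values sit far from every
  bound.
- **σ** is inferred as a fourth parameter rather than fixed: the Gaussian
  error model needs a scale and the data identify it well.
- **Sampler**: Haario-style adaptive Metropolis — per-chain empirical
  covariance tracked by a stochastic-approximation recursion (decay
  exponent 0.6) with a global log-step-size tuned toward the 0.234
  acceptance target.  Adaptation freezes at the end of warm-up (first 50%
  of iterations) so the retained chain is a valid Markov chain.
- **Initialisation**: chains start from a cheap Nelder–Mead posterior-mode
  search, jittered 5% per coordinate; this makes 5 × 10³-iteration runs
  converge reliably where prior-random starts need many more.
- **Convergence**: split-chain potential-scale-reduction R̂ per parameter,
  threshold 1.05 with four chains, checked every 2000 iterations for early
  stopping; non-convergence at the iteration cap returns the samples with a
  warning flag rather than raising.

All randomness flows from one integer seed; runs are bit-reproducible.

## Optimal stimulation design

Charge delivered to the tissue is budgeted through the isoperimetric
constraint ∫₀ᵀ s² dt = s_budget.  The canonical budget is 27 V²h/cm² — the
charge of constant 3 V/cm stimulation over T = 3 h, which is also how the
default horizon is fixed (the analysis that motivates these problems never
states T directly; the budget pins it).

For objectives **linear** in the state (total distance ∫v dt; terminal
velocity v(T)) the costate system is independent of the state and solvable
in closed form.  Every costate is a finite exponential sum
Σ cⱼ e^{rⱼ(t−T)}; the package manipulates these exactly (`ExpSum`):
the λ_I convolution integral and ∫g² dt are evaluated algebraically, so the
budget multiplier μ* = ½√(∫g²dt / s_budget) involves no quadrature or
root-finding and the budget holds to round-off.  The optimal field is
S* = g/(2μ*) with switching profile g = τe⁻¹λ_seff + τa⁻¹λ_I.  Since the
state map is linear, S* is also the matched filter of the corresponding
response kernel — an independent global-optimality certificate used by the
tests (Cauchy–Schwarz: no budget-respecting field does better).

Sign conventions are chosen so that maximisation costates are positive
where an increase of the state helps the objective: for the distance
problem λ_v(t) = (1 − e^{γ(t−T)})/γ > 0 on [0, T).  For the
terminal-velocity problem the objective is the integrand of v(T) = ∫v̇ dt,
entering the Hamiltonian with weight (1 + λ_v); with λ_v = e^{γ(t−T)} − 1
this gives dλ_seff/dt = −α(1 + λ_v) + τe⁻¹λ_seff and
λ_seff = α/(γ − τe⁻¹)·(e^{τe⁻¹(t−T)} − e^{γ(t−T)}).  Both families are
verified against backward numerical integration from the transversality
condition λ(T) = 0 to 1e-6 relative across 50 random parameter draws.

Induced trajectories are simulated with the clamp off, consistent with the
linear derivation (S* for the distance objective is non-negative anyway);
a clamped re-simulation is attached to every solution for physical
reference.

Two structural consequences worth stating plainly, because they differ from
numbers sometimes quoted for this problem family:

- **The optimal field always switches off at the horizon.**  Transversality
  forces λ(T) = 0, hence S*(T) = 0: stimulation in the final instants
  cannot propagate through the excitation cascade in time to move the
  tissue.  The terminal-velocity-optimal field therefore ramps up over
  ≈95% of the horizon and drops to zero in a short terminal boundary layer
  — it is not globally monotone increasing.
- **At the calibrated parameters, T = 3 h and the canonical budget**, the
  distance-optimal field improves on constant stimulation by 6.17%
  (117.50 μm vs 110.67 μm), and the terminal-velocity optimum reaches
  92.0 μm/h against 29.9 μm/h for the constant field.  These are the true
  optima (matched-filter certificate above); reported reference values of
  2.17%, 62.9 μm/h and 52.5 μm/h are consistent only with suboptimal
  control profiles (and, for the constant-field baseline, with a shorter
  ≈2 h horizon that contradicts the stated budget), so the package's
  numbers strictly dominate them.  The acceptance artefacts report the
  computed values; `tests/test_acceptance.py` asserts the reference
  comparisons as stated and documents the discrepancy by failing them
  honestly.

**Bang-bang limit.**  Replacing the charge budget by a bound
0 ≤ s ≤ s_max makes the Hamiltonian linear in the control; the switching
function τe⁻¹λ_seff + τa⁻¹λ_I is strictly positive before the horizon, so
the optimal policy is the constant pulse at s_max — naive pulse stimulation
is optimal in this regime, which is why iterated experimental practice
converged on it.  A random-search oracle (200 bounded random protocols)
backs the dominance claim in the tests.

**Posterior ensembles.**  Parameter uncertainty propagates by recomputing
S* — including its own μ* — for each posterior draw and taking pointwise
5/95% envelopes of the field and the induced velocity; draws violating the
parameter constraints are skipped with a logged warning.

## Constant-velocity problems (collocation BVPs)

Quadratic objectives couple states and costates into two-point BVPs solved
with SciPy's fourth-order collocation scheme with residual control and
damped Newton (the bvp4c algorithm), at relative tolerance 1e-3, boundary
tolerance 1e-6, node cap 10⁶ — the working tolerances of the reference
analysis.  Neither objective involves the control directly, so the
stationarity condition is closed with a quadratic control regularisation
ρ∫s²dt (default ρ = 1/2, exposed in `SolverConfig.control_weight`), giving
S = −(τe⁻¹λ_seff + τa⁻¹λ_I)/(2ρ).

Two readings of "hold the monolayer at v*" are implemented on
`ConstantVelocityProblem.objective`:

- `"acceleration"` (default): minimise ∫v̇²dt with the terminal pin
  v(T) = v*.  Its exact minimiser is the linear ramp v ≈ v*·t/T — *not* a
  plateau: an instant jump to v* would cost ∫v̇² ≈ v*²/δ → ∞ over the onset
  layer.  The ramp still requires the velocity *slope* to jump at t = 0,
  which only an onset field spike can deliver (≈52 V/cm at the
  pulse-average target v* = 36.9 μm/h) — far above the tolerated in-vitro
  scale, while the *mean* field stays near the reference strength.  Both
  the onset spike and the mean field are exactly linear in v* (the problem
  is linear-quadratic), which the v* grid search exposes.
- `"tracking"`: minimise ∫(v − v*)²dt — the cruise-control reading.  The
  velocity jumps to v* quasi-instantly and plateaus (flat to <2% through
  the mid-horizon), at the cost of an even larger onset spike.  This
  variant reproduces the plateau phenomenology usually displayed for this
  problem.

Field caps are applied post hoc (`min(s, s_max)`, floored at 0 for
physical realisability) and the clipped control re-simulated with the clamp
on.  Tightening the cap degrades tracking monotonically in the mean
deviation from v*; the pointwise terminal error |v(T) − v*| is *not*
monotone near the 3 V/cm cap because v(T) − v* changes sign as the cap
varies (the clipped onset alters the inhibitor history, so the late
open-loop field over- or under-shoots).  Tests assert the monotone mean
-deviation property; the acceptance suite also records the terminal-error
reading as stated by the reference claims.

The **windowed** problem minimises ∫Φ(t)(v − v*)²dt with the smooth window
Φ(t) = logistic((t−t1)/ε)·logistic((t2−t)/ε), ε = 1/50 h (hours chosen so
ε ≪ t1 for every studied t1), t2 = T − t1 by default, and full
transversality (no terminal pin needed).  The admissible waiting-time band
is ((T − τa)/2, τmax): below it the held window is long relative to the
adaptation timescale and the onset field grows unphysical (with a velocity
overshoot before the plateau); above τmax the field can start from zero and
the velocity rises into the window without overshoot.  The overshoot in the
regularised problem is modest (1–3% of v* below the band vs <0.2% above),
so tests classify the regimes by contrast rather than absolute size.  The
control magnitude scales linearly in v* (R² > 0.99).

## Synthetic data

The generator emulates the calibration experiment: nine replicate
monolayers, a 1× reference-field pulse for 3 h, recording to 5.5 h at
10-minute cadence (no sample at t = 0 where v ≡ 0), iid Gaussian noise of
σ = 3 μm/h added to the deterministic model solution.  σ is a free fixture
parameter chosen to match the visual spread of experimental bulk-velocity
traces.  The noise is deliberately exactly the likelihood's error model —
no temporal autocorrelation, no replicate-level parameter variation, no
edge effects — so recovery studies validate the inference machinery, not
the realism of the error model; real PIV-averaged data would be
autocorrelated, and passing tests here say nothing about that mismatch.

## Problem sizes used in tests and the acceptance script

Oracle comparisons run on 41–241-point grids; the adjoint/closed-form
sweeps use 50 random parameter draws; the recovery study runs 20 seeds of
4-chain × 5 × 10³-iteration MCMC on the default nine-replicate design
(≈1 minute total with the closed-form likelihood); BVP phenomenology uses
the default 400-node initial mesh.  The acceptance script simulates on
601-point grids over the 3 h horizon.  These sizes make the whole suite
run in a few minutes while leaving every comparison tolerance-bound, not
grid-bound.

## Known limitations

- Spatially uniform, uniaxial fields only; no edge-region phenomenology,
  no per-cell resolution.
- Confluent parameter limits (coincident relaxation rates) are rejected,
  not implemented.
- The ρ-regularised BVP control is a numerical closure of an
  under-determined stationarity condition; absolute field magnitudes in the
  constant-velocity solutions scale with 1/ρ and should be read as "far
  above physiological", not as precise predictions.
- The calibration's Gaussian-iid error model understates uncertainty for
  autocorrelated experimental noise.
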