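# Methods

## Scope and structure

The package implements an inverse-design workflow for the blades of a
miniature axial blood pump as six cooperating modules: `geometry` (designs,
circular-arc camber lines, factorial enumeration, constraint boxes),
`virtual_pump` (the analytic performance model), `curves` (quartic fitting,
similitude scaling, interpolation, curve metrics), `surrogates` (MLR, GPR,
BRANN), `ga` (the constrained genetic algorithm) and `pipeline`
(orchestration, verification, retargeting, reporting), plus a thin CLI.

## Geometry

Blade angles are measured from the tangential direction and stored in
degrees; chords in mm. A camber line is the unique circular arc with the
prescribed endpoint tangents and chord, R = C/(2 sin(θ/2)); arcs are built
in the unwrapped blade-to-blade plane at the mid-span radius
r_m = (r_hub + r_shroud)/2 = 2.425 mm, with the inlet endpoint at the
origin and the chord along the stagger direction (the bisector of the two
tangent angles). Sweeping the section from hub to shroud, edge solids and
tip-gap geometry are out of scope; the tip gap, blade thickness and blade
counts are carried as constants only.

The factorial generator enumerates the 2⁵ combinations of per-parameter
(low, high) levels in lexicographic order over
(β₁, β₂, α₂, C_L,imp, C_L,diff) with low before high, so design IDs are
stable across runs. Combinations violating β₂ > β₁ are collected and
reported rather than silently dropped (the default levels produce none).
Constraint iteration k widens the iteration-0 box (the factorial extremes)
by 5° per side for angles and 1 mm per side for chords, with β₂ capped at
90°; indices 0–4 are supported.

## The analytic pump model

The workflow's simulation stage is an Euler-equation mean-line model with
algebraic losses. It is not a calibrated replica of any particular pump; it
is a stand-in truth designed around three requirements: exact affinity
consistency, smooth dependence on all five blade parameters, and
qualitatively realistic curve shapes and magnitudes for a pump of this
size and duty.

With blade speed U = ω r_m, axial velocity c_x = Q/A over the annulus
A = π(r_shroud² − r_hub²), and slip-corrected outlet swirl
c_θ = σ_s (U − c_x cot β₂):

    ΔP = ρ U c_θ                                  (Euler head)
       − k_inc · ½ρ (U − c_x cot β₁)²             (impeller incidence)
       − k_dif · ½ρ (c_θ − c_x cot α₂)²           (diffuser incidence)
       − k_fric · (C_imp + C_diff)/c_ref · ½ρ c_x²   (passage drag)
    P  = ρ Q U c_θ + k_par ρ ω³ r_m⁵              (shaft power)
    η  = Q ΔP / P

Every ΔP term is homogeneous of degree 2 in (ω, Q) and the power of degree
3, so ψ and η are functions of φ alone and similitude scaling round-trips
are exact to machine precision — which turns the scaling machinery's
correctness into a testable identity rather than an approximation. Head
and efficiency may go negative beyond runout and are reported raw;
downstream interpolation tolerates this.

Defaults: σ_s = 0.85, k_inc = k_dif = 0.02, k_fric = 10.0 (per unit total
chord, referenced to c_ref = 23 mm), k_par = 2.0. These were calibrated
once, analytically, against the shape requirements: with blade angles in
the factorial ranges the zero-incidence flows sit far above the operating
region (≈ 5–8 L/min), so both incidence losses *decrease* with flow across
the whole grid; large incidence coefficients would therefore produce a
rising HQ curve. Keeping them small and letting a drag loss quadratic in
the through-flow dynamic head dominate gives a head that falls
monotonically with flow (≈ 167 → 144 mmHg over 0.5–2 L/min at 20,000 rpm
for the mid-box design), an efficiency curve peaking inside the sampled
range (η ≈ 0.28 near 2.5 L/min), design-point efficiencies of 0.26–0.31
across the 32 base designs, and scaled speeds near 15,000 rpm — all in the
physiologically and mechanically plausible range for this class of device.
The parasitic power term (disc friction and windage on ρω³r_m⁵) is what
drives efficiency to zero at shut-off and fixes the location of the
best-efficiency point.

What the model does not emulate: turbulence and transition, tip-leakage
flow, surface roughness, unsteady rotor–stator interaction, or solver
noise (Gaussian pressure noise can be enabled explicitly, seeded, for
robustness studies). Consequently, passing tests demonstrate the
correctness and behaviour of the *workflow* — scaling, surrogate
protocols, constrained optimisation, verification — not the hydrodynamic
optimality of any real blade shape.

## Curves and scaling

The HQ curve is fitted with an ordinary least-squares quartic in Q
(minimum five distinct samples). Efficiency is never polynomial-fitted:
design-point efficiency is always piecewise-linear interpolation in Q, and
interpolation refuses to extrapolate outside the sampled flow range.

The operating-point match solves the quartic-minus-parabola equation by
companion-matrix roots (numpy) followed by Newton polishing. Root policy:
real roots with |imag| < 1e-9·max(1, |real|), restricted to Q > 0; roots
inside the fitted range are preferred and the one nearest the target flow
is chosen (several in-range roots warn; the model family used here yields
monotone-decreasing heads, for which the intersection with the rising
affinity parabola is unique). If only out-of-range positive roots exist
the nearest to the range is taken and flagged as extrapolated; an empty
positive root set raises with the full root set attached. Clinical units
(L/min, mmHg, rpm) at every interface; SI internally; 1 mmHg = 133.322 Pa.

The specific speed N_s = ω√Q/(gH)^(3/4) is computed with gH = ΔP/ρ (gravity
cancels). At 15,000 rpm, 2 L/min, 70 mmHg, ρ = 1050 kg/m³ it evaluates to
1.762 — the mixed-flow regime, though packaging constrains the machine to
axial form. The rotational Reynolds number ωD²ρ/μ reaches ≈ 37,000 at
20,000 rpm. A pipe-flow Reynolds estimate is deliberately not exposed as a
headline quantity: its velocity scale is convention-dependent.

## Surrogates

Features and targets are min-max normalised to [−1, 1] on the training
data (zero-span columns map to 0); holdout or query rows use the training
map and may fall outside [−1, 1], in which case predictions carry an
"extrapolating" flag. All reported RMSEs are on the natural efficiency
scale.

* **MLR** — least squares with intercept; trained and scored on all data
  (no holdout), as befits the benchmark.
* **GPR** — scikit-learn `GaussianProcessRegressor`, constant (trained)
  mean via target normalisation, anisotropic Matérn 5/2 by default
  (squared-exponential, exponential and rational-quadratic kernels
  available for comparison, with a ranking helper). Noise-free kernel with
  jitter 1e-10, escalated ×10 to at most 1e-6 on Cholesky failure.
  Validation protocol: 5-fold cross-validation (shuffled, seeded), fold
  hyperparameters refitted by marginal-likelihood maximisation, mean
  held-out RMSE reported; the returned model is refitted on all data. The
  CV estimate is reporting, not model selection — matching the protocol of
  proprietary tools' internals exactly is not attempted.
* **BRANN** — 5 → n_hidden (default 5, tanh) → 1 network trained by
  Levenberg–Marquardt on F = βE_D + αE_W with α, β re-estimated each
  accepted step by the Gauss–Newton evidence approximation
  (γ = N_w − α tr(H⁻¹), α = γ/2E_W, β = (N − γ)/2E_D). Because F ≡ N/2
  identically after each evidence update, stopping tracks the data misfit:
  the run ends on trust-region exhaustion (μ > 1e10), a scaled-space
  training RMSE below 1e-8, or the iteration cap (300), and is flagged
  unconverged only if the misfit was still falling materially at the cap.
  β is clipped to [1e-6, 1e10]; on noise-free data it grows to the cap and
  γ saturates at its evidence-framework bound min(N, N_w). Holdout: a
  seeded random draw of round(0.15·n) designs (5 of 32) never seen in
  training. Initial weights uniform (−0.5, 0.5) under the seed; training
  is bit-reproducible. A fixed-regularisation mode (α, β frozen) exists
  for studying weight decay in isolation.

## Genetic algorithm

Real-coded, minimising over the five parameters. Selection is
stochastic-universal sampling on 1/√rank scaling; `elite_count` = 3 of a
population of 50 survive unchanged; a 0.8 fraction of the remaining
offspring come from intermediate crossover (child = p₁ + u·(p₂ − p₁),
u ~ U(0,1) per coordinate) and the rest from Gaussian mutation whose
per-coordinate standard deviation starts at the box width and shrinks
linearly over the generation budget. Every candidate is repaired before
evaluation — clipped into the box, then β₂ lifted to min(90, β₁ + 10⁻³°)
when the ordering fails — so the objective's domain stays clean and no
infeasible design is ever evaluated. Convergence: relative change of the
generation-best objective over a 50-generation window ≤ 10⁻⁶ (window and
tolerance configurable), or 500 generations. Elitism makes the best-so-far
history non-increasing; a fixed seed makes runs identical. The
repeatability study reruns the GA under distinct seeds and reports the
per-parameter relative spread 100·(max − min)/max, flagging the
combination of large spread with indistinguishable objective values as
non-identifiability rather than optimiser failure.

Where the surrogate's optimum sits at a box corner (common at iteration 0,
whose box corners are training designs), the repair projection lets
repeats land on the corner exactly, so spreads are typically ≪ 1%.

## Pipeline

The survey fixes 20,000 rpm for all dataset generation; each design's
scaled speed is recorded but not re-simulated in the main path (scaling
validity is a test, not a pipeline stage — on this model the re-simulation
check is exact). The baseline is the design with the highest interpolated
efficiency at the target after scaling. Each (surrogate × iteration) row
trains the surrogate, runs the seeded repeatability study, takes the best
of the repeats, verifies it with a fresh simulation scaled to the target,
and records the relative prediction error with the *simulated* value as
denominator (the more conservative reference). The reported winner is the
widest constraint iteration of the GPR-guided runs whose prediction error
stays below 15%; efficiency gains are computed from verified values only.
Retargeting to the alternate operating points (1 L/min / 60 mmHg,
0.5 L/min / 50 mmHg) rescales the existing survey-speed curve — no new
simulation — and the same mechanism builds retargeted surrogate datasets
at zero additional simulation cost.

Per-stage seeds derive from the master seed by mixing it with a CRC-32 of
a stage tag through `numpy.random.SeedSequence`, so any stage is
independently reproducible. Reports carry the software version, a SHA-256
configuration hash and all seeds; reruns with the same configuration are
byte-identical.

## Problem sizes

The shipped defaults are the study's own conditions: 32 designs × 8 flow
rates, one survey speed, surrogates on 32 points, GA with population 50
for at most 500 generations, five repeats per optimisation row. A full
`run_all` with three surrogates and five constraint iterations completes
in a few seconds; the test suite, including the end-to-end acceptance
properties, runs in well under a minute.

## Known limitations

* The analytic pump is smooth and noise-free, so surrogate validation
  errors are orders of magnitude smaller than they would be against a
  turbulent flow solver, and the GPR interpolates its training set almost
  exactly. The *protocols* (CV, holdout, verification, error-vs-iteration
  trends) are faithfully exercised; the error magnitudes are not
  transferable.
* The two chord lengths enter the loss model only through their sum, so
  their individual effects on the objective are identical; optima push
  both to a bound, which keeps them identifiable.
* Efficiency is hydraulic (QΔP over shaft power) and treated as exactly
  invariant under affinity scaling; no Reynolds correction is applied.
* Single-objective only; haemolysis, thrombosis and HQ-gradient
  considerations are out of scope.
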