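# Methods

## Model

Cupula deflection δ (μm, the vertical displacement of the cupula
cross-section, not an angular deflection) responds to head angular velocity
ω (°/s) as an overdamped second-order bandpass system,

    H(s) = δ/ω = K s / ((τ_L s + 1)(τ_S s + 1)),

the torsion-pendulum picture: endolymph inertia, viscous duct drag, and
elastic cupula restoring force. τ_S (rapid cupular adaptation) is fixed at
0.01 s throughout — the package targets everyday rotation frequencies, not
high-frequency adaptation. K carries units μm per (°/s); note that the
amplitude gain actually measured at an operating frequency f inside the
passband is |H(j2πf)| ≈ K/τ_L, not K itself (at 10 Hz with τ_L ≈ 1 s,
|H| ≈ 0.82 K).

Off-center rotation at offset distance d (cm between rotation axis and canal
center, ≥ 3 cm because the canal sits 3 cm from the body center) modifies the
two leading parameters:

    H_d(s) = (1 + β₁ d + β₂ d²) K₀ s / (((1 − α d) τ_L0 s + 1)(τ_S s + 1)).

Both modifier polynomials are anchored at d = 0 (they equal 1 there), so K₀
and τ_L0 are the d = 0 intercepts of the fitted offset laws. This anchoring
is what makes α = −slope/intercept of the linear τ_L fit reproducible from
the observation tables.

All time-domain responses are exact inverse Laplace transforms:

* step velocity ω₀·u(t): δ(t) = K ω₀ (e^(−t/τ_L) − e^(−t/τ_S)) / (τ_L − τ_S)
  — a spike on the τ_S scale decaying on the τ_L scale;
* step acceleration a·t: δ(t) = K a [1 − (τ_L e^(−t/τ_L) − τ_S e^(−t/τ_S)) /
  (τ_L − τ_S)] — monotone rise to the saturation value K·a (final-value
  theorem), linear in a;
* sinusoid ω_amp sin(2πft): steady state |H| ω_amp sin(2πft + φ) plus the
  two-exponential start-from-rest transient.

Confluent (τ_L = τ_S) branches use the repeated-pole forms. Each closed form
is tested against an independent state-space ODE integration to 1e-8
relative error.

## Stimulus catalog and forcing reduction

The 21 conditions cross three ground-parallel, clockwise motion types with
offsets 3–103 cm: step acceleration (10/20/30 °/s² at 3 cm), step velocity
(10/20/30 °/s at 3 cm; 10 °/s at 13–103 cm), and 10 Hz sinusoids
(peak-to-peak 1/2/3 °/s at 3 cm; 1 °/s at 13–103 cm). Step-velocity onset is
a true step (maximum torque at onset, no ramp); degrees at all I/O
boundaries, radians internally.

The rotational body force on the endolymph is offered in three conventions:
the component form ρα(y, x) as commonly printed, and the two tangential
Euler variants ρα(y, −x) (clockwise) and ρα(−y, x). The component form is
the default for fidelity to the source description, but it is the gradient
of ραxy — an exact 1-form whose closed-loop line integral vanishes at every
axis position, i.e. it exerts **no net forcing on a closed duct**. The
tangential variants integrate to ±2ραA (A the enclosed, shoelace area),
independent of axis offset. Two consequences are documented by the test
suite rather than resolved: the printed component form looks like a sign
typo of the clockwise Euler force, and even the corrected tangential forcing
is offset-invariant on a closed loop — the 1-D reduction cannot, by itself,
produce an offset effect. The mechanism by which offset alters gain and time
constant in the full 3-D two-way FSI solution is outside this package's
scope; the offset dependence used for synthetic studies comes from the
modified transfer function directly.

## Reduced-order duct surrogate

The 3-D problem is collapsed to one volumetric degree of freedom V (m³
displaced through the cupula): I V̈ + (B + C_V) V̇ + K_V V = G(t), with duct
inertance I, Poiseuille resistance B, Kelvin–Voigt cupular stiffness K_V and
damping C_V, and loop-integrated forcing G. The surrogate is *calibrated*,
not derived: given targets (τ_L, τ_S, operating gain), the characteristic
roots are matched exactly via I = K_V τ_L τ_S and B + C_V = K_V (τ_L + τ_S),
and the free scale K_V is fixed by the gain target through
K = 2ρA/(A_eff K_V). Defaults: C_V = 0.05 B (the viscoelastic law is named
in the source but its coefficient is not given; the dashpot is kept small
relative to duct drag); effective cupula area A_eff = 0.97×10⁻¹² m³ /
1.763 μm ≈ 5.50×10⁻⁷ m² from the published centered-rotation peak pair,
absorbing all clamped-plate profile factors. Integration uses LSODA with
rtol 1e-8 / atol 1e-24 (V is of order 1e-12 m³); a step-velocity onset is
realized exactly as initial momentum q(0⁺) = G_imp/I because a Dirac
forcing is not representable on a sample grid. With the published
calibration the simulated centered step-velocity peak volume comes out
≈1.1×10⁻¹² m³, near the published 0.97×10⁻¹².

## Summary statistics

* **Peak**: global maximum of |δ|, refined by a guarded three-point
  parabola so estimates are not grid-limited.
* **τ_L (37 % criterion)**: first time after the peak at which the trace
  falls to 0.37 × peak (the literal 0.37, not 1/e), linearly interpolated,
  measured from stimulus onset t = 0. With peaks arriving ≈ 0.05 s after
  onset this reference reproduces the magnitude of the published values; the
  source does not state the reference point. The statistic overestimates the
  pole: for τ_L = 1.025 s, τ_S = 0.01 s it returns ≈ 1.076 s (~5 % high).
  This bias propagates into α recovered from synthetic studies (≈ 4 % low,
  noise-free) and is the dominant recovery error.
* **Gain factor**: steady-state amplitude of the final full cycle
  ((max − min)/2, parabolic-refined; the source shows two-cycle records, so
  no FFT bin is used) divided by ω_amp. Records include ≥ 5 τ_L warm-up
  before the measured cycle. No phase is extracted.

## Fitting and model selection

τ_L(d) and gain(d) are each fit with OLS linear and quadratic polynomials
and a two-parameter exponential A e^(−kd) (nonlinear LS started from the
log-linear fit plus perturbed restarts; the exponential's functional form is
a package choice — the source names the family without specifying it, so its
MSE is indicative only). MSE uses divisor n (n = 7 for the canonical sets);
this convention reproduces the published linear-τ value 5.73×10⁻⁶ s²
exactly. Default selection takes linear for τ_L (all errors tiny; simplicity
preferred) and quadratic for gain; a min-MSE policy is available. The
canonical gain fit gives β₁ ≈ 0.01291 versus the published 0.01295 — the
source evidently fit unrounded simulation outputs, and the rounded table
values cannot reproduce the fifth digit; β₂ and α match to their printed
precision.

## Synthetic-data generator

`generate_study` emulates the simulation study's outputs: for each condition
it evaluates the closed-form response at the effective parameters
(1 − αd) τ_L0 and the quadratic gain, on a 1 kHz grid (well above the
100 Hz floor needed to resolve τ_S), 10 s step records and 7 s sinusoidal
records (≈ 5 τ_L warm-up plus two 10 Hz cycles), with optional i.i.d.
Gaussian noise scaled to the trace peak (default 0 — the FEM traces being
emulated are noise-free). Fixed seed and config give byte-identical traces.

One deliberate design choice: because |H| at the operating point scales as
K/τ_L, simulating sinusoids verbatim from the effective parameters would
make the measured gain grow as (1 + β₁d + β₂d²)/(1 − αd) — entangling the
two offset laws and breaking the defining property that the observable gain
is quadratic in d. The generator therefore anchors each condition's
operating-point amplitude gain to the quadratic law by rescaling K with
h(τ_L0)/h(τ_L(d)), where h is the per-unit-K gain magnitude at the operating
frequency (`anchor_operating_gain`, default on). What the synthetic study
emulates is the *statistical structure* of the reported observations — an
overdamped response family whose measured τ_L falls linearly and measured
gain rises quadratically with offset; it does not emulate 3-D flow fields,
canal-specific (horizontal/anterior/posterior) differences, or any physical
mechanism of the offset effect, so passing recovery tests validates the
extraction-and-fitting chain, not the biomechanics.

## Numerical choices and limitations

* Noise-free closed-loop recovery: β₁, β₂ to ~1e-6 relative; α to ≈ 4 %
  (the 37 % statistic's bias, documented above, not corrected — the package
  reproduces the estimator as specified rather than debiasing it).
* With 1 % trace noise, recovered constants scatter with per-replicate sd of
  roughly 3–6 %; means over many seeded replicates stay within a few
  percent. The first-passage threshold crossing under noise biases τ̂_L
  slightly early, roughly proportionally across offsets, so most of it
  cancels in α = −slope/intercept.
* Parabolic refinements are guarded (concavity check, half-sample clamp) and
  fall back to the raw sample under noise.
* Degenerate inputs raise: all-zero traces (no peak), non-decaying traces
  (unresolved τ), records shorter than warm-up + 2 cycles, τ_L ≤ τ_S,
  (1 − αd) ≤ 0, open centerlines where loop invariance is requested.
* The duct surrogate shares one scalar A_eff across conditions and cannot
  reproduce offset effects (see above); anterior/posterior canal responses
  are not modeled (the reported ordering HC > AC > PC is noted, not
  computed).
* No uncertainty quantification on α, β₁, β₂ (point estimates only), and no
  full-Bode gain fitting — the gain is defined at the 10 Hz operating point.
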