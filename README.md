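# sccdyn

Semicircular-canal (SCC) cupula dynamics under **off-center rotation**:
stimulus kinematics, the bandpass (torsion-pendulum) transfer function and its
offset-dependent modification, a reduced-order duct surrogate, trace-summary
statistics, and least-squares fitting of the offset laws.

## The problem

The three semicircular canals of the inner ear transduce head rotation: the
endolymph fluid lags the rotating membranous labyrinth, deflecting the
gelatinous cupula that spans each canal's ampulla. Classical models assume the
rotation axis passes through the canal center and describe the deflection
δ (μm) as a bandpass filter of head angular velocity ω (°/s):

    δ/ω = K s / ((τ_L s + 1)(τ_S s + 1))

with gain K, long time constant τ_L ≈ 1 s and short time constant
τ_S = 0.01 s. Real rotations — driving, flight, sports, VR motion platforms —
are almost never centered: the canal sits at an offset distance d (cm) from
the rotation axis (at least 3 cm, the canal-to-body-center distance). Across
simulated conditions spanning d = 3…103 cm, the long time constant falls
linearly and the operating-point gain grows quadratically with offset, which
the modified transfer function captures:

    δ/ω = (1 + β₁ d + β₂ d²) K s / (((1 − α d) τ_L s + 1)(τ_S s + 1))

with α = 0.002143 cm⁻¹, β₁ = 0.01295 cm⁻¹, β₂ = 0.000059 cm⁻². This package
implements the full analysis chain — the 21-condition stimulus catalog
(step-acceleration, step-velocity, sinusoidal at 10 Hz), closed-form and
reduced-order responses, the 37 %-of-peak τ_L estimator and the
δ_amp/ω_amp gain factor, and the linear/quadratic/exponential model fits
compared by mean squared error — plus a seeded synthetic-study pipeline that
regenerates traces from the model and closes the loop back to the constants.

## Worked example

Fit the offset laws to the seven published (d, τ_L) and (d, gain) observation
pairs and assemble the modified model:

```python
from sccdyn import assemble_modified_model, effective_params
from sccdyn.datasets import canonical_tau_observations, canonical_gain_observations
from sccdyn.fitting import fit_all_families

tau_fits = fit_all_families(canonical_tau_observations())
gain_fits = fit_all_families(canonical_gain_observations())
for f in tau_fits:
    print(f"tau_L  {f.family:<12} MSE = {f.mse:.3g} s^2")
model = assemble_modified_model(
    next(f for f in tau_fits if f.family == "linear"),
    next(f for f in gain_fits if f.family == "quadratic"),
)
print(f"alpha = {model.alpha:.6f} /cm, beta1 = {model.beta1:.5f} /cm, beta2 = {model.beta2:.6f} /cm^2")
p = effective_params(model, 103.0)
print(f"at d = 103 cm: tau_L = {p.tau_L:.3f} s, K = {p.K:.3f} um/(deg/s)")
```

prints

```
tau_L  linear       MSE = 5.73e-06 s^2
tau_L  quadratic    MSE = 2.35e-06 s^2
tau_L  exponential  MSE = 2.26e-05 s^2
alpha = 0.002143 /cm, beta1 = 0.01291 /cm, beta2 = 0.000059 /cm^2
at d = 103 cm: tau_L = 0.806 s, K = 0.499 um/(deg/s)
```

The linear τ_L fit already has a tiny error (5.73×10⁻⁶ s²), so the simpler
family is kept even though the quadratic is marginally better; the gain is
clearly quadratic. Normalizing the coefficients by their d = 0 intercepts
yields the model constants: at one meter of offset the long time constant has
shrunk by ~22 % and the gain nearly tripled — the same angular velocity is
felt differently away from the axis.

The same operations are available from a shell:

```sh
sccdyn simulate --condition V13·10 --out trace.csv
sccdyn extract trace.csv stimulus.json
sccdyn fit-offset-model observations.csv
sccdyn reproduce-tables
sccdyn synth-study --seed 1 --noise-sd 0.01 --out report.json
```

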