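"""Bandpass (torsion-pendulum) model of cupula deflection.

The classical second-order model relates cupula displacement ``delta``
(here the scalar vertical displacement of the cupula cross-section, in
μm) to head angular velocity ``omega`` (°/s) through

    delta / omega = K s / ((tau_L s + 1)(tau_S s + 1)),

with gain ``K`` (μm per °/s), long time constant ``tau_L`` (s, endolymph-
cupula relaxation) and short time constant ``tau_S`` (s, rapid cupular
adaptation, fixed at 0.01 s).  The offset-dependent modification makes
both leading parameters functions of the offset distance ``d`` (cm)
between rotation axis and canal center:

    delta / omega = (1 + beta1 d + beta2 d²) K s
                    / (((1 - alpha d) tau_L s + 1)(tau_S s + 1)),

i.e. the long time constant shrinks linearly and the gain grows
quadratically with offset.  Both factors are anchored at d = 0 (they
equal 1 there), so ``K0`` and ``tau_L0`` are the centered-rotation
intercepts recovered from fits.

All time-domain responses are exact inverse Laplace transforms of the
model under the respective stimulus and therefore agree with numerical
state-space integration to integration tolerance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

__all__ = [
    "BandpassParams",
    "OffsetModel",
    "effective_params",
    "frequency_response",
    "operating_gain",
    "normalized_gain_curve",
    "step_velocity_response",
    "step_accel_response",
    "sinusoid_response",
    "DEFAULT_TAU_S",
]

#: Short time constant, s — fixed; the study targets everyday rotations,
#: not high-frequency adaptation.
DEFAULT_TAU_S = 0.01

_CONFLUENT_RTOL = 1e-9


@dataclass(frozen=True)
class BandpassParams:
    """Parameters of the classical bandpass transfer function.

    K has units μm per (°/s); tau_L > tau_S > 0 (overdamped).
    """

    K: float
    tau_L: float
    tau_S: float = DEFAULT_TAU_S

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError("gain K must be positive")
        if not self.tau_L > self.tau_S > 0:
            raise ValueError("require tau_L > tau_S > 0")

    def to_dict(self) -> dict:
        return {
            "K_um_per_deg_s": self.K,
            "tau_L_s": self.tau_L,
            "tau_S_s": self.tau_S,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BandpassParams":
        return cls(K=d["K_um_per_deg_s"], tau_L=d["tau_L_s"], tau_S=d["tau_S_s"])


@dataclass(frozen=True)
class OffsetModel:
    """Offset-dependent bandpass model.

    ``K0`` and ``tau_L0`` are the centered-rotation gain and long time
    constant (anchored at ``d_ref`` = 0 cm); ``alpha`` (cm⁻¹) is the
    linear shrink rate of tau_L, ``beta1`` (cm⁻¹) and ``beta2`` (cm⁻²)
    the quadratic gain-growth coefficients.
    """

    K0: float
    tau_L0: float
    tau_S: float = DEFAULT_TAU_S
    alpha: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    d_ref: float = 0.0

    def tau_multiplier(self, d) -> np.ndarray | float:
        return 1.0 - self.alpha * (np.asarray(d, dtype=float) - self.d_ref)

    def gain_multiplier(self, d) -> np.ndarray | float:
        dd = np.asarray(d, dtype=float) - self.d_ref
        return 1.0 + self.beta1 * dd + self.beta2 * dd**2

    def to_dict(self) -> dict:
        return {
            "K0_um_per_deg_s": self.K0,
            "tau_L0_s": self.tau_L0,
            "tau_S_s": self.tau_S,
            "alpha_per_cm": self.alpha,
            "beta1_per_cm": self.beta1,
            "beta2_per_cm2": self.beta2,
            "d_ref_cm": self.d_ref,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OffsetModel":
        return cls(
            K0=d["K0_um_per_deg_s"],
            tau_L0=d["tau_L0_s"],
            tau_S=d["tau_S_s"],
            alpha=d["alpha_per_cm"],
            beta1=d["beta1_per_cm"],
            beta2=d["beta2_per_cm2"],
            d_ref=d.get("d_ref_cm", 0.0),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "OffsetModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def effective_params(m: OffsetModel, d: float) -> BandpassParams:
    """Bandpass parameters at offset distance ``d`` (cm).

    K_eff = (1 + beta1 d + beta2 d²) K0, tau_L_eff = (1 - alpha d) tau_L0,
    tau_S unchanged (d measured from the model's anchor ``d_ref``).
    """
    tm = float(m.tau_multiplier(d))
    if tm <= 0:
        raise ValueError(f"(1 - alpha d) = {tm:.4g} <= 0 at d = {d} cm")
    gm = float(m.gain_multiplier(d))
    if gm <= 0:
        raise ValueError(f"gain multiplier {gm:.4g} <= 0 at d = {d} cm")
    return BandpassParams(K=gm * m.K0, tau_L=tm * m.tau_L0, tau_S=m.tau_S)


def frequency_response(p: BandpassParams, f) -> np.ndarray | complex:
    """Complex transfer-function value ``H(j 2 pi f)``.

    Zero at DC, roll-off above 1/(2 pi tau_S): the canal behaves as a
    bandpass filter of angular velocity.
    """
    s = 2j * np.pi * np.asarray(f, dtype=float)
    H = p.K * s / ((p.tau_L * s + 1.0) * (p.tau_S * s + 1.0))
    return H if np.ndim(f) else complex(H)


def operating_gain(p: BandpassParams, f: float) -> float:
    """Amplitude gain |H| at the operating frequency, μm per (°/s)."""
    return abs(frequency_response(p, f))


def normalized_gain_curve(m: OffsetModel, d_list, f_grid, d_ref: float = 3.0) -> np.ndarray:
    """Gain magnitude ratios |H_d(f)| / |H_dref(f)| over offsets and
    frequencies, normalized to the centered-rotation offset (3 cm).

    Returns an array of shape ``(len(d_list), len(f_grid))``; the row at
    ``d = d_ref`` is identically 1.
    """
    d_list = np.asarray(d_list, dtype=float)
    f_grid = np.asarray(f_grid, dtype=float)
    if not np.any(np.isclose(d_list, d_ref)):
        raise ValueError(f"reference offset d = {d_ref} cm must be in d_list")
    ref = np.abs(frequency_response(effective_params(m, d_ref), f_grid))
    out = np.empty((d_list.size, f_grid.size))
    for i, d in enumerate(d_list):
        out[i] = np.abs(frequency_response(effective_params(m, d), f_grid)) / ref
    return out


def _is_confluent(p: BandpassParams) -> bool:
    return math.isclose(p.tau_L, p.tau_S, rel_tol=_CONFLUENT_RTOL)


def step_velocity_response(p: BandpassParams, omega0: float, t) -> np.ndarray:
    """Cupula displacement (μm) under a step of angular velocity.

    Inverse Laplace of ``H(s) omega0 / s``:

        delta(t) = K omega0 (exp(-t/tau_L) - exp(-t/tau_S)) / (tau_L - tau_S)

    (confluent ``tau_L = tau_S = tau``: ``K omega0 t exp(-t/tau)/tau²``).
    The response rises on the tau_S scale to a peak of roughly
    ``K omega0 / tau_L`` and decays back to zero on the tau_L scale.
    ``omega0`` in °/s.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if _is_confluent(p):
        tau = p.tau_L
        return p.K * omega0 * t * np.exp(-t / tau) / tau**2
    return (
        p.K
        * omega0
        * (np.exp(-t / p.tau_L) - np.exp(-t / p.tau_S))
        / (p.tau_L - p.tau_S)
    )


def step_accel_response(p: BandpassParams, a: float, t) -> np.ndarray:
    """Cupula displacement (μm) under constant angular acceleration from
    rest.

    Inverse Laplace of ``H(s) a / s²``:

        delta(t) = K a [1 - (tau_L exp(-t/tau_L) - tau_S exp(-t/tau_S))
                        / (tau_L - tau_S)],

    rising monotonically to the steady state ``K a`` (final-value
    theorem): under sustained acceleration the pressure across the cupula
    equilibrates and the deflection saturates.  ``a`` in °/s².
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be nonnegative")
    if _is_confluent(p):
        tau = p.tau_L
        return p.K * a * (1.0 - np.exp(-t / tau) * (1.0 + t / tau))
    return p.K * a * (
        1.0
        - (p.tau_L * np.exp(-t / p.tau_L) - p.tau_S * np.exp(-t / p.tau_S))
        / (p.tau_L - p.tau_S)
    )


def sinusoid_response(p: BandpassParams, omega_amp: float, f: float, t_grid) -> np.ndarray:
    """Zero-state response (μm) to ``omega(t) = omega_amp sin(2 pi f t)``.

    Steady-state amplitude is ``|H(f)| omega_amp``; the start-from-rest
    transient (two decaying exponentials) is included so the record can
    be treated like a measured trace.  ``omega_amp`` in °/s.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid must be nonnegative")
    if omega_amp == 0.0:
        return np.zeros_like(t)
    Om = 2.0 * math.pi * f
    H = complex(frequency_response(p, f))
    steady = omega_amp * abs(H) * np.sin(Om * t + np.angle(H))
    C = p.K / (p.tau_L * p.tau_S)  # H(s) = C s / ((s + a)(s + b))
    a = 1.0 / p.tau_L
    b = 1.0 / p.tau_S
    W = omega_amp * Om
    if _is_confluent(p):
        # double pole at -a: residue terms (N(-a) t + N'(-a)) e^{-a t}
        # with N(s) = C W s / (s² + Om²)
        n_a = C * W * (-a) / (a * a + Om * Om)
        np_a = C * W * (Om * Om - a * a) / (a * a + Om * Om) ** 2
        transient = (n_a * t + np_a) * np.exp(-a * t)
    else:
        c_a = C * (-a) * W / ((b - a) * (a * a + Om * Om))
        c_b = C * (-b) * W / ((a - b) * (b * b + Om * Om))
        transient = c_a * np.exp(-a * t) + c_b * np.exp(-b * t)
    return steady + transient
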