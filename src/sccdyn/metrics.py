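"""Parameter-extraction statistics for cupula response traces.

Two summary statistics identify the bandpass parameters from simulated
records:

* the **37 % criterion** for the long time constant: after a
  step-velocity stimulus the displacement spikes on the tau_S scale and
  then decays on the tau_L scale; tau_L is estimated as the time,
  measured from stimulus onset (t = 0), at which the trace first falls
  back to 37 % of its peak.  The literal factor 0.37 is used (not 1/e).
  Because the peak sits slightly after onset, the statistic mildly
  overestimates the pole time constant (about 5 % at tau_L ≈ 1 s,
  tau_S = 0.01 s).
* the **gain factor** at the operating point: the steady-state
  displacement amplitude of a sinusoidal record divided by the
  angular-velocity amplitude, ``gain = delta_amp / omega_amp``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .traces import Trace

__all__ = [
    "PeakEstimate",
    "ExtractionResult",
    "find_peak",
    "tau_from_step_trace",
    "extract_step",
    "sinusoid_amplitude",
    "gain_factor",
    "TAU_THRESHOLD_FRACTION",
]

#: Fraction of the peak at which the long time constant is read off.
TAU_THRESHOLD_FRACTION = 0.37


class PeakEstimate(NamedTuple):
    value: float
    time: float
    unsaturated: bool  # peak at the final sample (trace still rising)


@dataclass
class ExtractionResult:
    """Summary of one trace extraction (step or sinusoidal)."""

    condition_code: str | None = None
    peak_value: float | None = None
    peak_time: float | None = None
    threshold_value: float | None = None  # 0.37 * peak for step extractions
    tau_L: float | None = None
    amplitude: float | None = None
    gain: float | None = None
    d_off: float | None = None
    method: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "condition_code": self.condition_code,
            "peak_value": self.peak_value,
            "peak_time_s": self.peak_time,
            "threshold_value": self.threshold_value,
            "tau_L_s": self.tau_L,
            "amplitude": self.amplitude,
            "gain_um_per_deg_s": self.gain,
            "d_off_cm": self.d_off,
            "method": self.method,
        }


def _parabolic_peak(y: np.ndarray, i: int) -> float:
    """Three-point parabolic refinement of a sampled extremum (guarded:
    falls back to the sample value when the local curvature is not
    concave)."""
    if not 0 < i < y.size - 1:
        return float(y[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(y1)
    return float(y1 - 0.125 * (y0 - y2) ** 2 / denom)


def find_peak(trace: Trace, refine: bool = True) -> PeakEstimate:
    """Global extremum of |values|, sign preserved.

    With ``refine`` the peak value and time are interpolated with a
    parabola through the three samples around the maximum.  A trace that
    is still rising at its last sample is flagged ``unsaturated``.
    """
    y = trace.values
    if y.size == 0 or np.all(y == 0.0):
        raise ValueError("no peak: trace is empty or identically zero")
    mag = np.abs(y)
    i = int(np.argmax(mag))
    sign = 1.0 if y[i] >= 0 else -1.0
    unsaturated = i == y.size - 1
    peak_val = mag[i]
    peak_t = trace.times[i]
    if refine and 0 < i < y.size - 1:
        peak_val = _parabolic_peak(mag, i)
        y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
        denom = y0 - 2.0 * y1 + y2
        if denom < 0:
            frac = 0.5 * (y0 - y2) / denom
            # non-uniform grids: interpolate around sample i
            peak_t = trace.times[i] + frac * (
                trace.times[i + 1] - trace.times[i] if frac >= 0 else trace.times[i] - trace.times[i - 1]
            )
    return PeakEstimate(value=sign * peak_val, time=float(peak_t), unsaturated=unsaturated)


def tau_from_step_trace(trace: Trace, refine_peak: bool = True) -> float:
    """Long time constant (s) via the 37 %-of-peak criterion.

    The threshold is 0.37 x peak; the crossing is the first time after
    the peak at which the trace magnitude falls to or below it, linearly
    interpolated between samples and measured from stimulus onset t = 0.
    """
    return extract_step(trace, refine_peak=refine_peak).tau_L


def extract_step(trace: Trace, refine_peak: bool = True) -> ExtractionResult:
    """Full step-response extraction: peak, 37 % threshold and tau_L."""
    pk = find_peak(trace, refine=refine_peak)
    if pk.unsaturated:
        raise ValueError("unresolved tau: trace still rising at final sample")
    peak_mag = abs(pk.value)
    threshold = TAU_THRESHOLD_FRACTION * peak_mag
    mag = np.abs(trace.values)
    i_pk = int(np.argmax(mag))
    after = np.nonzero(mag[i_pk:] <= threshold)[0]
    if after.size == 0:
        raise ValueError("unresolved tau: trace never decays below 37% of peak")
    j = i_pk + int(after[0])
    if j == 0:
        tau = float(trace.times[0])
    else:
        t1, t2 = trace.times[j - 1], trace.times[j]
        v1, v2 = mag[j - 1], mag[j]
        tau = float(t2 if v1 == v2 else t1 + (threshold - v1) * (t2 - t1) / (v2 - v1))
    return ExtractionResult(
        condition_code=trace.condition_code,
        peak_value=float(pk.value),
        peak_time=pk.time,
        threshold_value=float(threshold),
        tau_L=tau,
        d_off=trace.meta.get("d_off_cm"),
        method={
            "threshold_fraction": TAU_THRESHOLD_FRACTION,
            "crossing": "linear interpolation",
            "peak_refinement": "parabolic" if refine_peak else "none",
            "reference": "stimulus onset (t = 0)",
        },
    )


def sinusoid_amplitude(
    trace: Trace, f: float, warmup: float | None = None, refine: bool = True
) -> float:
    """Steady-state amplitude from the final full cycle of a sinusoidal
    record, as half the peak-to-peak excursion.

    ``warmup`` (s) is the transient portion to discard; the record must
    contain at least two full cycles after it (default warmup: everything
    up to two cycles before the end).  Extremes are parabolically refined
    so the estimate is not limited by the sample grid.
    """
    if f <= 0:
        raise ValueError("frequency must be positive")
    t = trace.times
    if t.size == 0:
        raise ValueError("empty trace")
    period = 1.0 / f
    if warmup is None:
        warmup = t[-1] - 2.0 * period
    if t[-1] - warmup < 2.0 * period - 1e-12:
        raise ValueError("insufficient post-warmup data: need at least two full cycles")
    sel = t >= t[-1] - period
    seg = trace.values[sel]
    if seg.size < 4:
        raise ValueError("final cycle too sparsely sampled")
    if not np.any(seg != 0.0):
        return 0.0
    i_max = int(np.argmax(seg))
    i_min = int(np.argmin(seg))
    if refine:
        hi = _parabolic_peak(seg, i_max)
        lo = -_parabolic_peak(-seg, i_min)
    else:
        hi, lo = float(seg[i_max]), float(seg[i_min])
    return 0.5 * (hi - lo)


def gain_factor(delta_amp: float, omega_amp: float) -> float:
    """Operating-point gain: displacement amplitude (μm) over
    angular-velocity amplitude (°/s)."""
    if omega_amp <= 0:
        raise ValueError("omega_amp must be positive")
    return delta_amp / omega_amp
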