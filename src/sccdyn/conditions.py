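"""Rotational stimulus conditions and their kinematics.

The study design crosses three ground-parallel motion types with offset
distances from 3 cm (rotation axis through the body center, with the
horizontal canal assumed 3 cm from it) up to 103 cm:

* **SAM** -- step-acceleration motion, constant angular acceleration from
  rest: ``omega(t) = (domega/dt) * t``;
* **SVM** -- step-velocity motion, instantaneous onset of a constant
  angular velocity: ``omega(t) = omega0`` for ``t >= 0``;
* **SINUSOIDAL** -- ``omega(t) = (omega_pp / 2) * sin(2*pi*f*t)`` where
  ``omega_pp`` is the peak-to-peak angular velocity and ``f`` the
  operating frequency (10 Hz by default, inside the bandpass passband).

Conditions are coded ``[A|V|S]<d_off>·<magnitude>``, e.g. ``V13·10`` is a
step-velocity stimulus of 10 °/s with the rotation axis 13 cm from the
canal center.  Angles are degrees at every I/O boundary and radians in
:class:`MotionProfile` arrays.
"""

from __future__ import annotations

import enum
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MotionKind",
    "RotationCondition",
    "MotionProfile",
    "build_condition_catalog",
    "parse_condition_code",
    "evaluate_motion",
    "catalog_to_json",
    "catalog_from_json",
    "DEFAULT_OPERATING_FREQUENCY_HZ",
    "MIN_OFFSET_CM",
]

#: Operating frequency of the sinusoidal stimuli, Hz (within the passband).
DEFAULT_OPERATING_FREQUENCY_HZ = 10.0

#: Minimum offset distance, cm: the canal center sits 3 cm from the body
#: center, so the axis can never be closer than that.
MIN_OFFSET_CM = 3.0


class MotionKind(str, enum.Enum):
    SAM = "SAM"
    SVM = "SVM"
    SINUSOIDAL = "SINUSOIDAL"


_KIND_PREFIX = {MotionKind.SAM: "A", MotionKind.SVM: "V", MotionKind.SINUSOIDAL: "S"}
_PREFIX_KIND = {v: k for k, v in _KIND_PREFIX.items()}

# Accept the typographic middle dot used in the condition table as well as
# plain ASCII substitutes.
_CODE_RE = re.compile(r"^([AVS])(\d+(?:\.\d+)?)[·\.x](\d+(?:\.\d+)?)$")


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else f"{x:g}"


@dataclass(frozen=True)
class RotationCondition:
    """One coded rotational stimulus.

    Parameters
    ----------
    motion_kind : MotionKind
        SAM, SVM or SINUSOIDAL.
    d_off : float
        Offset distance between rotation axis and canal center, cm (>= 3).
    magnitude : float
        Angular acceleration in °/s² (SAM), angular velocity in °/s (SVM),
        or peak-to-peak angular velocity in °/s (SINUSOIDAL).
    frequency : float or None
        Stimulus frequency in Hz; required for SINUSOIDAL, absent otherwise.
    direction : str
        Rotation sense; the study uses clockwise ("cw") throughout.
    """

    motion_kind: MotionKind
    d_off: float
    magnitude: float
    frequency: float | None = None
    direction: str = "cw"

    def __post_init__(self) -> None:
        if self.d_off < MIN_OFFSET_CM:
            raise ValueError(
                f"d_off = {self.d_off} cm below the {MIN_OFFSET_CM} cm minimum"
            )
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")
        if self.motion_kind == MotionKind.SINUSOIDAL:
            if self.frequency is None or self.frequency <= 0:
                raise ValueError("sinusoidal conditions require frequency > 0")
        elif self.frequency is not None:
            raise ValueError(f"{self.motion_kind.value} conditions carry no frequency")

    @property
    def code(self) -> str:
        """Catalog code, e.g. ``V13·10``."""
        return (
            f"{_KIND_PREFIX[self.motion_kind]}"
            f"{_format_number(self.d_off)}·{_format_number(self.magnitude)}"
        )

    @property
    def omega_amplitude_deg_s(self) -> float:
        """Angular-velocity amplitude in °/s (half the peak-to-peak value
        for sinusoids, the step value for SVM)."""
        if self.motion_kind == MotionKind.SINUSOIDAL:
            return self.magnitude / 2.0
        return self.magnitude

    def to_dict(self) -> dict:
        return {
            "code": self.code,
            "motion_kind": self.motion_kind.value,
            "d_off_cm": self.d_off,
            "magnitude_deg": self.magnitude,
            "frequency_hz": self.frequency,
            "direction": self.direction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RotationCondition":
        cond = cls(
            motion_kind=MotionKind(d["motion_kind"]),
            d_off=float(d["d_off_cm"]),
            magnitude=float(d["magnitude_deg"]),
            frequency=None if d.get("frequency_hz") is None else float(d["frequency_hz"]),
            direction=d.get("direction", "cw"),
        )
        if "code" in d and d["code"] != cond.code:
            raise ValueError(f"code {d['code']!r} inconsistent with fields ({cond.code!r})")
        return cond


def parse_condition_code(
    code: str, frequency: float = DEFAULT_OPERATING_FREQUENCY_HZ
) -> RotationCondition:
    """Parse a catalog code such as ``A3·20`` or ``S103·1`` into a condition.

    Sinusoidal codes do not encode the frequency; ``frequency`` supplies it.
    """
    m = _CODE_RE.match(code.strip())
    if m is None:
        raise ValueError(f"unrecognized condition code {code!r}")
    kind = _PREFIX_KIND[m.group(1)]
    return RotationCondition(
        motion_kind=kind,
        d_off=float(m.group(2)),
        magnitude=float(m.group(3)),
        frequency=frequency if kind == MotionKind.SINUSOIDAL else None,
    )


def build_condition_catalog(
    frequency: float = DEFAULT_OPERATING_FREQUENCY_HZ,
) -> list[RotationCondition]:
    """The 21 stimulus conditions of the study design, in table order.

    Rows 1-3: SAM at d_off = 3 cm, 10/20/30 °/s²; rows 4-6: SVM at 3 cm,
    10/20/30 °/s; rows 7-12: SVM at 10 °/s, d_off = 13...103 cm; rows
    13-15: sinusoids at 3 cm, peak-to-peak 1/2/3 °/s; rows 16-21:
    sinusoids at peak-to-peak 1 °/s, d_off = 13...103 cm.
    """
    far_offsets = [13.0, 23.0, 33.0, 43.0, 53.0, 103.0]
    cat: list[RotationCondition] = []
    for a in (10.0, 20.0, 30.0):
        cat.append(RotationCondition(MotionKind.SAM, 3.0, a))
    for w in (10.0, 20.0, 30.0):
        cat.append(RotationCondition(MotionKind.SVM, 3.0, w))
    for d in far_offsets:
        cat.append(RotationCondition(MotionKind.SVM, d, 10.0))
    for wpp in (1.0, 2.0, 3.0):
        cat.append(RotationCondition(MotionKind.SINUSOIDAL, 3.0, wpp, frequency))
    for d in far_offsets:
        cat.append(RotationCondition(MotionKind.SINUSOIDAL, d, 1.0, frequency))
    return cat


def catalog_to_json(conditions: Iterable[RotationCondition], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([c.to_dict() for c in conditions], ensure_ascii=False, indent=2)
    )


def catalog_from_json(path: str | Path) -> list[RotationCondition]:
    return [RotationCondition.from_dict(d) for d in json.loads(Path(path).read_text())]


@dataclass
class MotionProfile:
    """Sampled stimulus kinematics on a time grid (radians internally).

    ``omega`` is the derivative of ``theta`` and ``alpha`` of ``omega`` on
    smooth segments; step-velocity onsets carry a velocity jump at t = 0
    whose Dirac acceleration is not representable on the grid (``alpha``
    is zero there and the jump is recorded in ``omega[0]``).
    """

    times: np.ndarray
    theta: np.ndarray
    omega: np.ndarray
    alpha: np.ndarray
    condition_code: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        n = self.times.size
        if not (self.theta.size == self.omega.size == self.alpha.size == n):
            raise ValueError("times/theta/omega/alpha must share one length")
        if n and (self.times[0] != 0.0 or np.any(np.diff(self.times) <= 0)):
            raise ValueError("times must start at 0 and be strictly increasing")

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "time_s": self.times,
                "theta_rad": self.theta,
                "omega_rad_s": self.omega,
                "alpha_rad_s2": self.alpha,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "MotionProfile":
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(),
            theta=df["theta_rad"].to_numpy(),
            omega=df["omega_rad_s"].to_numpy(),
            alpha=df["alpha_rad_s2"].to_numpy(),
        )


def evaluate_motion(cond: RotationCondition, times: Sequence[float]) -> MotionProfile:
    """Evaluate a condition's angle/velocity/acceleration over a time grid.

    Degree-valued condition magnitudes are converted to radians; the
    returned profile stores rad, rad/s, rad/s².
    """
    t = np.asarray(times, dtype=float)
    if t.size == 0 or t[0] != 0.0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must start at 0 and be strictly increasing")
    if cond.motion_kind == MotionKind.SAM:
        a = math.radians(cond.magnitude)
        theta, omega, alpha = 0.5 * a * t**2, a * t, np.full_like(t, a)
    elif cond.motion_kind == MotionKind.SVM:
        w0 = math.radians(cond.magnitude)
        # true step at t = 0: maximum torque at onset, no ramp
        theta, omega, alpha = w0 * t, np.full_like(t, w0), np.zeros_like(t)
    elif cond.motion_kind == MotionKind.SINUSOIDAL:
        w_amp = math.radians(cond.magnitude) / 2.0
        two_pi_f = 2.0 * math.pi * cond.frequency
        omega = w_amp * np.sin(two_pi_f * t)
        theta = w_amp * (1.0 - np.cos(two_pi_f * t)) / two_pi_f
        alpha = w_amp * two_pi_f * np.cos(two_pi_f * t)
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown motion kind {cond.motion_kind!r}")
    return MotionProfile(
        times=t,
        theta=theta,
        omega=omega,
        alpha=alpha,
        condition_code=cond.code,
        meta={"units_note": "external I/O in degrees, internal storage in radians"},
    )
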