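"""Canonical published observation tables.

These are the printed FEM study outputs for the horizontal canal: peak
volume deformation / displacement and 37 %-criterion time constants for
the step-velocity conditions, and angular-velocity / displacement
amplitudes with gain factors for the sinusoidal conditions, across
offset distances d_off = 3 ... 103 cm.  They serve as fitting inputs and
as reference values for regression tests; the same seven (d_off, tau_L)
and (d_off, gain) pairs ship as CSV fixtures under ``sccdyn/data`` in
the ``d_cm,value,kind`` layout read by the fit-offset-model CLI.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .fitting import ObservationSet

__all__ = [
    "svm_fixed_offset_table",
    "svm_varying_offset_table",
    "sinusoid_fixed_offset_table",
    "sinusoid_varying_offset_table",
    "additional_offset_table",
    "canonical_tau_observations",
    "canonical_gain_observations",
    "load_bundled_observations",
    "PUBLISHED_ALPHA",
    "PUBLISHED_BETA1",
    "PUBLISHED_BETA2",
    "CANONICAL_D_CM",
    "CANONICAL_TAU_L_S",
    "CANONICAL_GAIN",
]

# Published constants of the offset-dependent model.
PUBLISHED_ALPHA = 0.002143  # cm⁻¹
PUBLISHED_BETA1 = 0.01295  # cm⁻¹
PUBLISHED_BETA2 = 0.000059  # cm⁻²

# Step-velocity responses at fixed d_off = 3 cm, varying omega.
_SVM_FIXED = [
    # code, peak volume m³, peak displacement μm, 37% threshold μm, tau_L s
    ("V3·10", 0.97e-12, 1.763, 0.652, 1.025),
    ("V3·20", 1.95e-12, 3.541, 1.310, 1.028),
    ("V3·30", 2.95e-12, 5.350, 1.980, 1.030),
]

# Step-velocity responses at omega = 10 °/s, varying d_off.
_SVM_VARYING = [
    ("V3·10", 0.97e-12, 1.763, 0.652, 1.025),
    ("V13·10", 1.07e-12, 1.973, 0.730, 1.004),
    ("V23·10", 1.18e-12, 2.223, 0.823, 0.984),
    ("V33·10", 1.32e-12, 2.514, 0.930, 0.959),
]

# Sinusoidal responses at fixed d_off = 3 cm, varying peak-to-peak omega.
_SIN_FIXED = [
    # code, omega amplitude °/s, displacement amplitude μm, gain μm/(°/s)
    ("S3·1", 0.5, 0.0882, 0.1764),
    ("S3·2", 1.0, 0.1771, 0.1771),
    ("S3·3", 1.5, 0.2675, 0.1783),
]

# Sinusoidal responses at omega amplitude 0.5 °/s, varying d_off.
_SIN_VARYING = [
    ("S3·1", 0.5, 0.0882, 0.1764),
    ("S13·1", 0.5, 0.0987, 0.1974),
    ("S23·1", 0.5, 0.1112, 0.2224),
    ("S33·1", 0.5, 0.1256, 0.2512),
]

# Additional far offsets used to pin down the offset laws.
_ADDITIONAL = [
    # d_off cm, omega amplitude °/s, displacement amplitude μm, gain, tau_L s
    (43.0, 0.5, 0.1402, 0.2804, 0.940),
    (53.0, 0.5, 0.1565, 0.3130, 0.921),
    (103.0, 0.5, 0.2492, 0.4984, 0.803),
]

# Canonical seven-point observation sets assembled from the tables above.
CANONICAL_D_CM = np.array([3.0, 13.0, 23.0, 33.0, 43.0, 53.0, 103.0])
CANONICAL_TAU_L_S = np.array([1.025, 1.004, 0.984, 0.959, 0.940, 0.921, 0.803])
CANONICAL_GAIN = np.array([0.1764, 0.1974, 0.2224, 0.2512, 0.2804, 0.3130, 0.4984])


def svm_fixed_offset_table() -> pd.DataFrame:
    return pd.DataFrame(
        _SVM_FIXED,
        columns=["code", "peak_volume_m3", "peak_displacement_um", "threshold_37pct_um", "tau_L_s"],
    )


def svm_varying_offset_table() -> pd.DataFrame:
    return pd.DataFrame(
        _SVM_VARYING,
        columns=["code", "peak_volume_m3", "peak_displacement_um", "threshold_37pct_um", "tau_L_s"],
    )


def sinusoid_fixed_offset_table() -> pd.DataFrame:
    return pd.DataFrame(
        _SIN_FIXED, columns=["code", "omega_amp_deg_s", "delta_amp_um", "gain_um_per_deg_s"]
    )


def sinusoid_varying_offset_table() -> pd.DataFrame:
    return pd.DataFrame(
        _SIN_VARYING, columns=["code", "omega_amp_deg_s", "delta_amp_um", "gain_um_per_deg_s"]
    )


def additional_offset_table() -> pd.DataFrame:
    return pd.DataFrame(
        _ADDITIONAL,
        columns=["d_off_cm", "omega_amp_deg_s", "delta_amp_um", "gain_um_per_deg_s", "tau_L_s"],
    )


def canonical_tau_observations() -> ObservationSet:
    """The seven published (d_off, tau_L) pairs."""
    return ObservationSet(
        d_values=CANONICAL_D_CM.copy(),
        y_values=CANONICAL_TAU_L_S.copy(),
        kind="tau_L",
        source="published tables",
    )


def canonical_gain_observations() -> ObservationSet:
    """The seven published (d_off, gain-factor) pairs."""
    return ObservationSet(
        d_values=CANONICAL_D_CM.copy(),
        y_values=CANONICAL_GAIN.copy(),
        kind="gain",
        source="published tables",
    )


def load_bundled_observations(kind: str) -> ObservationSet:
    """Load a canonical observation set from the bundled CSV fixtures."""
    if kind not in ("tau_L", "gain"):
        raise ValueError("kind must be 'tau_L' or 'gain'")
    name = "canonical_tau.csv" if kind == "tau_L" else "canonical_gain.csv"
    with resources.files("sccdyn.data").joinpath(name).open("r") as fh:
        df = pd.read_csv(fh)
    return ObservationSet(
        d_values=df["d_cm"].to_numpy(float),
        y_values=df["value"].to_numpy(float),
        kind=str(df["kind"].iloc[0]),
        source=f"bundled fixture {name}",
    )
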