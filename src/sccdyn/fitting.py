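"""Least-squares fitting of parameter-versus-offset laws.

The long time constant tau_L(d) and operating-point gain(d) are each fit
with three candidate families over offset distance d (cm):

* linear       ``y = a + b d``            (ordinary least squares)
* quadratic    ``y = c0 + c1 d + c2 d²``  (ordinary least squares)
* exponential  ``y = A exp(-k d)``        (nonlinear LS, log-linear start)

Families are compared by mean squared error with divisor n (not n - p).
The default selection policy mirrors the study's choice: the linear
family for tau_L (all three errors are tiny; simplicity wins) and the
quadratic family for the gain (an order of magnitude better than the
alternatives).  Normalizing the selected coefficients by their d = 0
intercept yields the constants of the offset-dependent transfer
function:

    alpha = -b / a,   beta1 = c1 / c0,   beta2 = c2 / c0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .bandpass import DEFAULT_TAU_S, OffsetModel

__all__ = [
    "ObservationSet",
    "FitResult",
    "fit_family",
    "fit_all_families",
    "mse",
    "select_model",
    "assemble_modified_model",
    "FAMILIES",
]

FAMILIES = ("linear", "quadratic", "exponential")
_FAMILY_NPARAMS = {"linear": 2, "quadratic": 3, "exponential": 2}


@dataclass
class ObservationSet:
    """Paired (offset distance, parameter) observations.

    ``kind`` is "tau_L" (seconds) or "gain" (μm per °/s); ``source``
    records provenance (published tables vs a synthetic study).
    """

    d_values: np.ndarray
    y_values: np.ndarray
    kind: str
    source: str = "unspecified"

    def __post_init__(self) -> None:
        self.d_values = np.asarray(self.d_values, dtype=float)
        self.y_values = np.asarray(self.y_values, dtype=float)
        if self.d_values.shape != self.y_values.shape or self.d_values.ndim != 1:
            raise ValueError("d_values and y_values must be matching 1-D arrays")
        if self.d_values.size < 3:
            raise ValueError("need at least 3 observations")
        if np.any(np.diff(self.d_values) <= 0):
            raise ValueError("d_values must be strictly increasing")
        if self.kind not in ("tau_L", "gain"):
            raise ValueError("kind must be 'tau_L' or 'gain'")

    @property
    def n(self) -> int:
        return self.d_values.size

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"d_cm": self.d_values, "value": self.y_values, "kind": self.kind}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, kind: str | None = None) -> "ObservationSet":
        df = pd.read_csv(path)
        if kind is not None:
            df = df[df["kind"] == kind]
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"observation CSV holds kinds {list(kinds)}; pass kind=")
        df = df.sort_values("d_cm")
        return cls(
            d_values=df["d_cm"].to_numpy(float),
            y_values=df["value"].to_numpy(float),
            kind=str(kinds[0]),
            source=str(path),
        )


@dataclass
class FitResult:
    """One family's fit: raw coefficients, MSE, and intercept-normalized
    constants (alpha for linear tau fits; beta1/beta2 for quadratic gain
    fits)."""

    family: str
    kind: str
    coefficients: dict
    mse: float
    n: int
    intercept: float
    normalized: dict = field(default_factory=dict)
    source: str = "unspecified"

    def predict(self, d) -> np.ndarray:
        d = np.asarray(d, dtype=float)
        c = self.coefficients
        if self.family == "linear":
            return c["a"] + c["b"] * d
        if self.family == "quadratic":
            return c["c0"] + c["c1"] * d + c["c2"] * d**2
        return c["A"] * np.exp(-c["k"] * d)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "kind": self.kind,
            "coefficients": self.coefficients,
            "mse": self.mse,
            "n": self.n,
            "intercept": self.intercept,
            "normalized": self.normalized,
            "source": self.source,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def mse(residuals: Sequence[float]) -> float:
    """Mean squared error with divisor n."""
    r = np.asarray(residuals, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one residual")
    return float(np.mean(r**2))


def _fit_exponential(d: np.ndarray, y: np.ndarray) -> dict:
    if np.any(y <= 0):
        raise ValueError("exponential family requires positive observations")
    # log-linear start, plus mild perturbations as extra starts
    k0, logA0 = np.polyfit(d, np.log(y), 1)
    starts = [(np.exp(logA0), -k0)]
    starts += [(np.exp(logA0) * s, -k0 * s) for s in (0.5, 2.0)]
    best, best_sse = None, np.inf
    for A0, kk0 in starts:
        try:
            popt, _ = curve_fit(
                lambda x, A, k: A * np.exp(-k * x), d, y, p0=[A0, kk0], maxfev=20000
            )
        except RuntimeError:
            continue
        sse = float(np.sum((y - popt[0] * np.exp(-popt[1] * d)) ** 2))
        if sse < best_sse:
            best, best_sse = popt, sse
    if best is None:
        raise RuntimeError("exponential fit failed to converge from all starts")
    return {"A": float(best[0]), "k": float(best[1])}


def fit_family(obs: ObservationSet, family: str) -> FitResult:
    """Fit one family to an observation set.

    Raises ``ValueError`` for unknown families or when there are fewer
    than (number of family parameters + 1) points, and ``RuntimeError``
    for a non-convergent exponential fit.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")
    if obs.n < _FAMILY_NPARAMS[family] + 1:
        raise ValueError(f"{family} fit needs at least {_FAMILY_NPARAMS[family] + 1} points")
    d, y = obs.d_values, obs.y_values
    normalized: dict = {}
    if family == "linear":
        X = np.column_stack([np.ones_like(d), d])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        a, b = float(beta[0]), float(beta[1])
        coefficients = {"a": a, "b": b}
        intercept = a
        resid = y - X @ beta
        if obs.kind == "tau_L" and a != 0.0:
            normalized["alpha"] = -b / a
    elif family == "quadratic":
        X = np.column_stack([np.ones_like(d), d, d**2])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        c0, c1, c2 = (float(v) for v in beta)
        coefficients = {"c0": c0, "c1": c1, "c2": c2}
        intercept = c0
        resid = y - X @ beta
        if obs.kind == "gain" and c0 != 0.0:
            normalized["beta1"] = c1 / c0
            normalized["beta2"] = c2 / c0
    else:
        coefficients = _fit_exponential(d, y)
        intercept = coefficients["A"]  # value at d = 0
        resid = y - coefficients["A"] * np.exp(-coefficients["k"] * d)
    return FitResult(
        family=family,
        kind=obs.kind,
        coefficients=coefficients,
        mse=mse(resid),
        n=obs.n,
        intercept=intercept,
        normalized=normalized,
        source=obs.source,
    )


def fit_all_families(obs: ObservationSet) -> list[FitResult]:
    return [fit_family(obs, fam) for fam in FAMILIES]


def select_model(results: Iterable[FitResult], policy: str = "published-default") -> FitResult:
    """Choose among candidate fits of one observation set.

    ``published-default`` prefers the linear family for tau_L (all candidate
    errors are small, so simplicity wins) and the quadratic family for
    the gain; ``min-mse`` simply takes the smallest MSE.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least 2 candidate fits")
    kinds = {r.kind for r in results}
    if len(kinds) != 1:
        raise ValueError("candidates must come from one observation set")
    if policy == "min-mse":
        return min(results, key=lambda r: r.mse)
    if policy == "published-default":
        wanted = "linear" if kinds.pop() == "tau_L" else "quadratic"
        for r in results:
            if r.family == wanted:
                return r
        raise ValueError(f"default policy needs a {wanted} candidate")
    raise ValueError(f"unknown policy {policy!r}")


def assemble_modified_model(
    tau_fit: FitResult, gain_fit: FitResult, tau_S: float = DEFAULT_TAU_S
) -> OffsetModel:
    """Build the offset-dependent transfer-function model from the
    selected fits.

    Requires a linear tau_L fit and a quadratic gain fit; the d = 0
    intercepts anchor the centered-rotation parameters and normalize the
    slopes into alpha, beta1, beta2.
    """
    if tau_fit.kind != "tau_L" or tau_fit.family != "linear":
        raise ValueError("tau_fit must be a linear fit of tau_L observations")
    if gain_fit.kind != "gain" or gain_fit.family != "quadratic":
        raise ValueError("gain_fit must be a quadratic fit of gain observations")
    tau_L0 = tau_fit.intercept
    K0 = gain_fit.intercept
    if tau_L0 <= 0 or K0 <= 0:
        raise ValueError("non-positive intercepts cannot anchor the model")
    return OffsetModel(
        K0=K0,
        tau_L0=tau_L0,
        tau_S=tau_S,
        alpha=tau_fit.normalized["alpha"],
        beta1=gain_fit.normalized["beta1"],
        beta2=gain_fit.normalized["beta2"],
        d_ref=0.0,
    )
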