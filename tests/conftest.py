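import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sccdyn.bandpass import BandpassParams
from sccdyn.study import published_offset_model


@pytest.fixture(scope="session")
def published_model():
    return published_offset_model()


@pytest.fixture
def centered_params():
    """Centered-rotation bandpass parameters of the published study."""
    return BandpassParams(K=0.1684412446808511, tau_L=1.025, tau_S=0.01)


def ode_response(p: BandpassParams, omega_fn, t_grid, rtol=1e-11):
    """Independent state-space oracle for the bandpass transfer function.

    Integrates tau_L tau_S x'' + (tau_L + tau_S) x' + x = omega(t) with
    delta = K x' from rest, so the transfer function delta/omega matches
    K s / ((tau_L s + 1)(tau_S s + 1)) without using any closed form.
    """
    a2 = p.tau_L * p.tau_S
    a1 = p.tau_L + p.tau_S

    def rhs(t, y):
        return [y[1], (omega_fn(t) - a1 * y[1] - y[0]) / a2]

    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        [0.0, 0.0],
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=1e-14,
    )
    assert sol.success
    return p.K * sol.y[1]


def rel_max_err(actual, expected):
    """Max-norm relative error against the expected signal's amplitude."""
    expected = np.asarray(expected, dtype=float)
    scale = np.max(np.abs(expected))
    return float(np.max(np.abs(np.asarray(actual) - expected)) / scale)
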