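"""Rotational volume-force field and its line-integral reduction.

In a frame rotating with angular acceleration ``alpha_t`` about the z
axis, the endolymph experiences an Euler body force of magnitude
``rho * R * alpha_t`` at distance ``R`` from the axis.  The field is
offered in three conventions:

* ``as_printed`` -- the component form ``F = rho*alpha_t*(y, x)``, i.e.
  ``Fx = rho*R*alpha_t*sin(atan2(y, x))`` and
  ``Fy = rho*R*alpha_t*cos(atan2(y, x))``.  Note the x-component sign
  makes this field not purely tangential.
* ``tangential_cw`` -- the clockwise Euler force ``rho*alpha_t*(y, -x)``.
* ``tangential_ccw`` -- the counter-clockwise variant ``rho*alpha_t*(-y, x)``.

For a closed planar loop the line integral of a tangential variant is
``±2 * rho * alpha_t * A`` (A the enclosed area) and is invariant to
displacing the rotation axis; the ``as_printed`` field has no such
invariance.  No z-component is applied anywhere (rotations are
ground-parallel about z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FORCE_MODES", "Centerline", "volume_force", "loop_forcing", "circle_centerline"]

FORCE_MODES = ("as_printed", "tangential_cw", "tangential_ccw")


def volume_force(
    x, y, rho: float, alpha_t: float, mode: str = "as_printed"
) -> tuple[np.ndarray, np.ndarray]:
    """Rotational volume force (N/m³) at planar points about the origin.

    Parameters
    ----------
    x, y : array_like
        Coordinates in the rotation plane, m, measured from the rotation
        axis.  The origin itself (R = 0) yields zero force in every mode.
    rho : float
        Fluid density, kg/m³.
    alpha_t : float
        Angular acceleration of the stimulus, rad/s².
    mode : str
        One of ``as_printed``, ``tangential_cw``, ``tangential_ccw``.

    Returns
    -------
    (F_x, F_y) : ndarray pair
        Force density components; ``|F| = rho * R * |alpha_t|`` in every
        mode.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = rho * alpha_t
    if mode == "as_printed":
        return c * y, c * x
    if mode == "tangential_cw":
        return c * y, -c * x
    if mode == "tangential_ccw":
        return -c * y, c * x
    raise ValueError(f"unknown force mode {mode!r}; expected one of {FORCE_MODES}")


@dataclass
class Centerline:
    """Planar duct centerline: ordered vertices with cross-sectional areas.

    The polyline is the reduction surface onto which the 3-D force field
    is projected; ``areas`` feed the lumped inertance/resistance sums of
    the duct surrogate.
    """

    points: np.ndarray  # (n, 2), m
    areas: np.ndarray  # (n,), m²
    closed: bool = True

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if self.points.shape[0] < 3:
            raise ValueError("a centerline needs at least 3 vertices")
        if self.areas.shape != (self.points.shape[0],):
            raise ValueError("areas must have one entry per vertex")
        if np.any(self.areas <= 0):
            raise ValueError("all cross-sectional areas must be positive")

    def closed_points(self) -> np.ndarray:
        """Vertices with explicit closure (first vertex repeated at the end)."""
        p = self.points
        if np.allclose(p[0], p[-1]):
            return p
        return np.vstack([p, p[:1]])

    def enclosed_area(self) -> float:
        """Signed shoelace area of the closed loop, m² (positive if ccw)."""
        if not self.closed:
            raise ValueError("enclosed area requires a closed centerline")
        p = self.closed_points()
        x, y = p[:, 0], p[:, 1]
        return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))

    def segment_lengths(self) -> np.ndarray:
        p = self.closed_points() if self.closed else self.points
        return np.linalg.norm(np.diff(p, axis=0), axis=1)


def circle_centerline(
    radius: float = 1.6e-3,
    n: int = 256,
    duct_area: float = 7.1e-7,
    center: tuple[float, float] = (0.0, 0.0),
) -> Centerline:
    """Circular duct centerline (default: 1.6 mm torus radius, uniform area)."""
    phi = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack(
        [center[0] + radius * np.cos(phi), center[1] + radius * np.sin(phi)]
    )
    return Centerline(points=pts, areas=np.full(n, duct_area), closed=True)


def loop_forcing(
    cl: Centerline,
    rho: float,
    alpha_t: float,
    offset: tuple[float, float] = (0.0, 0.0),
    mode: str = "as_printed",
    require_closed: bool = True,
) -> float:
    """Line integral of the rotational force along the centerline, Pa.

    The force field is evaluated about a rotation axis displaced by
    ``offset`` (m) from the centerline's coordinate origin and its
    tangential component integrated with the trapezoidal rule:
    ``G = ∮ F · t̂ ds``.  For the tangential modes on a closed loop this
    equals ``±2 * rho * alpha_t * A`` independent of ``offset``.
    """
    if require_closed and not cl.closed:
        raise ValueError("offset-invariant loop forcing requires a closed centerline")
    p = cl.closed_points() if cl.closed else cl.points
    fx, fy = volume_force(p[:, 0] - offset[0], p[:, 1] - offset[1], rho, alpha_t, mode)
    dx = np.diff(p[:, 0])
    dy = np.diff(p[:, 1])
    # trapezoidal F·dl over each segment
    return float(np.sum(0.5 * (fx[:-1] + fx[1:]) * dx + 0.5 * (fy[:-1] + fy[1:]) * dy))
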