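"""Material constants for endolymph and cupula.

Defaults: endolymph density 1000 kg/m³ and viscosity 0.0085 Pa·s
(water-like, incompressible Newtonian); cupula density 1000 kg/m³,
Young's modulus 5.4 Pa, Poisson ratio 0.3 (soft, nearly incompressible
gel).  Lamé coefficients follow from E and nu:

    mu_L     = E / (2 (1 + nu))
    lambda_L = nu E / ((1 + nu)(1 - 2 nu))
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["lame_coefficients", "MaterialProperties"]


def lame_coefficients(E: float, nu: float) -> tuple[float, float]:
    """Lamé coefficients (mu_L, lambda_L) in Pa from Young's modulus and
    Poisson's ratio.

    Raises
    ------
    ValueError
        If E <= 0 or nu is outside [0, 0.5); nu = 0.5 is the
        incompressible limit where lambda_L diverges.
    """
    if E <= 0:
        raise ValueError("Young's modulus must be positive")
    if not 0.0 <= nu < 0.5:
        raise ValueError("Poisson's ratio must lie in [0, 0.5)")
    mu_L = E / (2.0 * (1.0 + nu))
    lambda_L = nu * E / ((1.0 + nu) * (1.0 - 2.0 * nu))
    return mu_L, lambda_L


@dataclass(frozen=True)
class MaterialProperties:
    rho_endolymph: float = 1000.0  # kg/m³
    mu_endolymph: float = 0.0085  # Pa·s
    rho_cupula: float = 1000.0  # kg/m³
    E: float = 5.4  # Pa
    nu: float = 0.3
    mu_L: float = field(init=False)
    lambda_L: float = field(init=False)

    def __post_init__(self) -> None:
        mu_L, lambda_L = lame_coefficients(self.E, self.nu)
        object.__setattr__(self, "mu_L", mu_L)
        object.__setattr__(self, "lambda_L", lambda_L)
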