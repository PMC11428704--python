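"""Blood material laws.

Carreau–Yasuda shear-thinning viscosity, the shear-rate magnitude of a
velocity-gradient tensor, and the algebraic closure quantities of the
k–ω SST turbulence model (blending function F2, eddy viscosity, turbulent
stress tensor).  The k and ω transport equations themselves are not solved
anywhere in this package; the closure formulas are exposed as pure
functions so they can be evaluated and tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from . import presets

__all__ = [
    "RheologyParams",
    "SSTClosureParams",
    "apparent_viscosity",
    "shear_rate_magnitude",
    "sst_blending_F2",
    "turbulent_viscosity",
    "turbulent_stress",
]


@dataclass(frozen=True)
class RheologyParams:
    """Blood density and Carreau–Yasuda constants.

    Parameters
    ----------
    density : float
        Mass density, kg/m^3.
    mu_inf : float
        Infinite-shear viscosity plateau, Pa·s.
    mu_zero : float
        Zero-shear viscosity plateau, Pa·s (``mu_zero >= mu_inf``).
    lambda_time : float
        Relaxation time constant lambda, s.
    power_n : float
        Power-law exponent n in (0, 1]; n = 1 or ``mu_zero == mu_inf``
        recovers a Newtonian fluid.
    """

    density: float = presets.BLOOD_DENSITY
    mu_inf: float = presets.MU_INF
    mu_zero: float = presets.MU_ZERO
    lambda_time: float = presets.LAMBDA_TIME
    power_n: float = presets.POWER_N

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if self.mu_inf <= 0:
            raise ValueError(f"mu_inf must be positive, got {self.mu_inf}")
        if self.mu_zero < self.mu_inf:
            raise ValueError(
                f"mu_zero ({self.mu_zero}) must be >= mu_inf ({self.mu_inf})"
            )
        if self.lambda_time < 0:
            raise ValueError("lambda_time must be >= 0")
        if not 0 < self.power_n <= 1:
            raise ValueError(f"power_n must be in (0, 1], got {self.power_n}")

    @property
    def is_newtonian(self) -> bool:
        return self.mu_zero == self.mu_inf

    @property
    def kinematic_viscosity_inf(self) -> float:
        """Infinite-shear kinematic viscosity, m^2/s."""
        return self.mu_inf / self.density

    @classmethod
    def newtonian(cls, viscosity: float = presets.MU_INF,
                  density: float = presets.BLOOD_DENSITY) -> "RheologyParams":
        """Newtonian fluid with the given constant viscosity."""
        return cls(density=density, mu_inf=viscosity, mu_zero=viscosity)

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RheologyParams":
        """Build from config keys density/mu_inf/mu_zero/lambda_time/power_n."""
        known = {"density", "mu_inf", "mu_zero", "lambda_time", "power_n"}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown rheology keys: {sorted(extra)}")
        return cls(**dict(d))


def apparent_viscosity(shear_rate, params: RheologyParams):
    """Carreau–Yasuda apparent viscosity, Pa·s.

    mu(g) = mu_inf + (mu_zero - mu_inf) * (1 + (lambda*g)^2)^((n-1)/2)

    Monotone non-increasing in the shear rate ``g`` and bounded between the
    two viscosity plateaus.  Accepts scalars or arrays.
    """
    g = np.asarray(shear_rate, dtype=float)
    if np.any(g < 0) or not np.all(np.isfinite(g)):
        raise ValueError("shear_rate must be finite and >= 0")
    mu = params.mu_inf + (params.mu_zero - params.mu_inf) * (
        1.0 + (params.lambda_time * g) ** 2
    ) ** ((params.power_n - 1.0) / 2.0)
    return mu if mu.ndim else float(mu)


def shear_rate_magnitude(velocity_gradient):
    """Shear-rate magnitude sqrt(2 D:D) of a velocity-gradient tensor, 1/s.

    ``D`` is the symmetric part of the gradient; a rigid-body rotation
    therefore yields zero.  Accepts a 2x2 or 3x3 tensor, or an array of
    them in the trailing two axes.
    """
    grad = np.asarray(velocity_gradient, dtype=float)
    if grad.ndim < 2 or grad.shape[-1] != grad.shape[-2] or grad.shape[-1] not in (2, 3):
        raise ValueError("velocity_gradient must be (...,2,2) or (...,3,3)")
    if not np.all(np.isfinite(grad)):
        raise ValueError("velocity_gradient must be finite")
    d = 0.5 * (grad + np.swapaxes(grad, -1, -2))
    mag = np.sqrt(2.0 * np.sum(d * d, axis=(-2, -1)))
    return mag if mag.ndim else float(mag)


@dataclass(frozen=True)
class SSTClosureParams:
    """Pointwise inputs of the SST algebraic closure.

    k and omega are the turbulent kinetic energy (m^2/s^2) and specific
    dissipation rate (1/s); ``wall_distance`` is the distance d to the
    closest wall (m); ``strain_rate`` is the strain-rate invariant S (1/s);
    ``kinematic_viscosity`` is nu (m^2/s).  a1 and beta_star default to the
    standard literature values 0.31 and 0.09.
    """

    turbulent_kinetic_energy: float
    specific_dissipation: float
    wall_distance: float
    strain_rate: float = 0.0
    kinematic_viscosity: float = presets.MU_INF / presets.BLOOD_DENSITY
    a1: float = presets.SST_A1
    beta_star: float = presets.SST_BETA_STAR

    def __post_init__(self) -> None:
        if self.turbulent_kinetic_energy < 0:
            raise ValueError("k must be >= 0")
        if self.specific_dissipation <= 0:
            raise ValueError("omega must be > 0")
        if self.wall_distance <= 0:
            raise ValueError("wall distance must be > 0")
        if self.strain_rate < 0:
            raise ValueError("strain rate must be >= 0")
        if self.kinematic_viscosity <= 0:
            raise ValueError("kinematic viscosity must be > 0")


def sst_arg2(closure: SSTClosureParams) -> float:
    """arg2 = max(2*sqrt(k)/(beta*·omega·d), 500*nu/(omega·d^2))."""
    k = closure.turbulent_kinetic_energy
    w = closure.specific_dissipation
    d = closure.wall_distance
    return max(
        2.0 * np.sqrt(k) / (closure.beta_star * w * d),
        500.0 * closure.kinematic_viscosity / (w * d * d),
    )


def sst_blending_F2(closure: SSTClosureParams) -> float:
    """Second SST blending function F2 = tanh(arg2^2), in (0, 1]."""
    a = sst_arg2(closure)
    return float(np.tanh(a * a))


def turbulent_viscosity(closure: SSTClosureParams, density: float) -> float:
    """SST eddy viscosity mu_t = a1*rho*k / max(a1*omega, S*F2), Pa·s.

    When ``S*F2 <= a1*omega`` the max resolves to a1*omega and the formula
    reduces to the standard k–omega value rho*k/omega.
    """
    if density <= 0:
        raise ValueError("density must be positive")
    f2 = sst_blending_F2(closure)
    a1 = closure.a1
    denom = max(a1 * closure.specific_dissipation, closure.strain_rate * f2)
    return a1 * density * closure.turbulent_kinetic_energy / denom


def turbulent_stress(mu_t: float, velocity_gradient, k: float, density: float):
    """Boussinesq turbulent stress tensor, Pa.

    tau_ij = mu_t (du_i/dx_j + du_j/dx_i - (2/3)(du_k/dx_k) delta_ij)
             - (2/3) rho k delta_ij

    Always symmetric; for a traceless (divergence-free) gradient its trace
    is exactly -2*rho*k.
    """
    grad = np.asarray(velocity_gradient, dtype=float)
    if grad.shape[-1] != grad.shape[-2]:
        raise ValueError("velocity_gradient must be square")
    if not np.all(np.isfinite(grad)):
        raise ValueError("velocity_gradient must be finite")
    n = grad.shape[-1]
    eye = np.eye(n)
    div = np.trace(grad, axis1=-2, axis2=-1)
    tau = mu_t * (grad + np.swapaxes(grad, -1, -2)
                  - (2.0 / 3.0) * div[..., None, None] * eye)
    tau = tau - (2.0 / 3.0) * density * k * eye
    return tau
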