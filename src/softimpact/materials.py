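"""Constitutive laws for the impact solver.

Two material families are supported:

* :class:`ViscoplasticMaterial` — a Norton–Hoff power law generalised with a
  shape coefficient ``s`` and a rate-sensitivity exponent ``m`` that is allowed
  to go negative.  The deviatoric Cauchy stress is

      tau' = s * K * (sqrt(3) * D)**(m - 1) * dev(eps_dot)

  with ``D = sqrt(2/3 * dev(eps_dot) : dev(eps_dot))`` the effective strain
  rate.  ``m = 1`` is a Newtonian fluid of viscosity ``s*K``; ``m = 0`` is a
  perfectly plastic solid whose flow-stress magnitude is rate independent;
  ``m < 0`` produces strain-rate *softening*: the apparent viscosity drops
  faster than the rate grows, which mimics the near-immediate, smoothly
  decaying acceleration observed when brain-like matter hits an obstacle.
  Incompressibility is imposed weakly through a penalty block (``lambda``).

* :class:`ViscoelasticMaterial` — a Kelvin–Voigt comparator (spring and
  dashpot in parallel), sigma = C(E, nu) eps + c * eps_dot.  It is the
  conventional model whose delayed wave response the viscoplastic law is
  meant to improve on; it also serves for purely elastic sub-domains (c = 0),
  e.g. a stiff skull layer.

Voigt convention used everywhere: order (11, 22, 33, 12, 23, 31) with
engineering shear strains (gamma = 2*eps_ij) and tensor shear stresses.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass
from typing import Any

import numpy as np

__all__ = [
    "ViscoplasticMaterial",
    "ViscoelasticMaterial",
    "strain_rate_from_velocity_gradient",
    "effective_rate",
    "deviatoric_stress",
    "apparent_viscosity",
    "penalty_block",
    "viscoelastic_stress",
    "tensor_to_voigt_rate",
    "voigt_rate_to_tensor",
    "isotropic_stiffness",
    "VISCOUS_VOIGT",
    "DEVIATORIC_VISCOUS_VOIGT",
]

logger = logging.getLogger(__name__)

#: Voigt index pairs, order (11, 22, 33, 12, 23, 31).
VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (0, 1), (1, 2), (2, 0))

#: Maps a Voigt engineering-rate vector to tensor stress for unit viscosity:
#: sigma_v = mu * VISCOUS_VOIGT @ rate_v  (shear slots carry the 1/2 from
#: gamma = 2*eps).
VISCOUS_VOIGT = np.diag([1.0, 1.0, 1.0, 0.5, 0.5, 0.5])

#: Same, composed with the deviatoric projector (removes the volumetric part).
_VOL = np.zeros((6, 6))
_VOL[:3, :3] = 1.0 / 3.0
DEVIATORIC_VISCOUS_VOIGT = VISCOUS_VOIGT @ (np.eye(6) - _VOL)

_floor_logged: set[int] = set()


@dataclass
class ViscoplasticMaterial:
    """Parameter bundle for the rate-softening Norton-Hoff law.

    Parameters
    ----------
    K_viscosity : float
        Consistency / viscosity coefficient K, Pa*s.
    m_sensitivity : float
        Rate-sensitivity exponent, in [-1, 1].  Negative values give
        strain-rate softening.
    s_coefficient : float
        Dimensionless shape coefficient multiplying the stress law.
    c_damping : float
        External (absolute-velocity) damping coefficient.  Quoted in the
        dashpot unit N*s/m but applied as a distributed coefficient per unit
        volume (N*s/m^4); the unit mismatch is inherited from the problem
        statement and flagged in the docs.
    rho : float
        Mass density, kg/m^3.
    lambda_penalty : float
        Incompressibility penalty magnitude (Pa*s — penalises div v).
    D_floor : float
        Regularisation floor for the effective rate, 1/s.  The power law is
        singular at D = 0 for m < 1; rates below the floor use the floor
        viscosity, so the regularised law is Bingham-like with a stress
        plateau ~0.54*s*K/sqrt(D_floor).  The default 1e-8 places that
        plateau at the inertial stress scale of a ~7.5 m/s impact (tens of
        kPa), which is what lets s and K shape the response; a much larger
        floor collapses the law into rate-independent behaviour.
    rate_scaling : str
        "sqrt3" (default) reads the equivalent-rate prefactor as sqrt(3)*D,
        the standard Norton-Hoff scaling; "literal3" uses 3*D for
        sensitivity checks.
    """

    K_viscosity: float
    m_sensitivity: float
    s_coefficient: float = 1.0
    c_damping: float = 0.0
    rho: float = 1040.0
    lambda_penalty: float = 1.0e6
    D_floor: float = 1.0e-8
    rate_scaling: str = "sqrt3"

    def __post_init__(self) -> None:
        if not (-1.0 <= self.m_sensitivity <= 1.0):
            raise ValueError(f"m_sensitivity must lie in [-1, 1], got {self.m_sensitivity}")
        for name in ("K_viscosity", "s_coefficient", "rho", "D_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.lambda_penalty < 0:
            raise ValueError("lambda_penalty must be non-negative")
        if self.c_damping < 0:
            raise ValueError("c_damping must be non-negative")
        if self.rate_scaling not in ("sqrt3", "literal3"):
            raise ValueError(f"unknown rate_scaling {self.rate_scaling!r}")

    @property
    def rate_prefactor(self) -> float:
        return np.sqrt(3.0) if self.rate_scaling == "sqrt3" else 3.0

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["kind"] = "viscoplastic"
        return d


@dataclass
class ViscoelasticMaterial:
    """Kelvin-Voigt solid: sigma = C(E, nu) * eps + c * eps_dot.

    ``nu`` defaults to 0 so a uniaxial bar carries waves at sqrt(E/rho)
    exactly; set it for genuinely 3-D elastic layers.
    """

    E_modulus: float
    c_damping: float = 0.0
    rho: float = 1040.0
    nu: float = 0.0

    def __post_init__(self) -> None:
        if self.E_modulus <= 0:
            raise ValueError("E_modulus must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.c_damping < 0:
            raise ValueError("c_damping must be non-negative")
        if not (0.0 <= self.nu < 0.5):
            raise ValueError("nu must lie in [0, 0.5)")

    def stiffness_matrix(self) -> np.ndarray:
        return isotropic_stiffness(self.E_modulus, self.nu)

    def damping_matrix(self) -> np.ndarray:
        return self.c_damping * VISCOUS_VOIGT

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["kind"] = "viscoelastic"
        return d


def material_from_dict(d: dict[str, Any]):
    """Inverse of ``to_dict`` for both material kinds."""
    d = dict(d)
    kind = d.pop("kind")
    if kind == "viscoplastic":
        return ViscoplasticMaterial(**d)
    if kind == "viscoelastic":
        return ViscoelasticMaterial(**d)
    raise ValueError(f"unknown material kind {kind!r}")


def isotropic_stiffness(E: float, nu: float) -> np.ndarray:
    """Isotropic elasticity matrix in engineering Voigt notation."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    C = np.zeros((6, 6))
    C[:3, :3] = lam
    C[:3, :3] += 2 * mu * np.eye(3)
    C[3:, 3:] = mu * np.eye(3)
    return C


def strain_rate_from_velocity_gradient(grad_v: np.ndarray) -> np.ndarray:
    """Symmetric part of the velocity gradient, (grad v + grad v^T) / 2."""
    grad_v = np.asarray(grad_v, dtype=float)
    if grad_v.shape != (3, 3):
        raise ValueError(f"expected a 3x3 velocity gradient, got shape {grad_v.shape}")
    if not np.all(np.isfinite(grad_v)):
        raise ValueError("velocity gradient contains non-finite entries")
    return 0.5 * (grad_v + grad_v.T)


def _deviator(eps: np.ndarray) -> np.ndarray:
    return eps - np.trace(eps) / 3.0 * np.eye(3)


def effective_rate(eps_dot: np.ndarray) -> float:
    """Effective strain rate D = sqrt(2/3 * dev(eps_dot) : dev(eps_dot))."""
    eps_dot = np.asarray(eps_dot, dtype=float)
    if eps_dot.shape != (3, 3):
        raise ValueError("expected a 3x3 strain-rate tensor")
    if not np.allclose(eps_dot, eps_dot.T, rtol=1e-10, atol=1e-14 * max(1.0, np.abs(eps_dot).max())):
        raise ValueError("strain-rate tensor must be symmetric")
    dev = _deviator(eps_dot)
    return float(np.sqrt(2.0 / 3.0 * np.sum(dev * dev)))


def apparent_viscosity(mat: ViscoplasticMaterial, D: float | np.ndarray) -> float | np.ndarray:
    """Apparent shear viscosity s*K*(a*max(D, D_floor))**(m-1), a = sqrt(3).

    Strictly decreasing in D for m < 1 (softening), constant for m = 1.
    """
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("effective rate D must be non-negative")
    if np.any(D < mat.D_floor) and id(mat) not in _floor_logged:
        logger.info(
            "effective rate below regularisation floor %.3g 1/s; viscosity capped", mat.D_floor
        )
        _floor_logged.add(id(mat))
    D_reg = np.maximum(D, mat.D_floor)
    out = mat.s_coefficient * mat.K_viscosity * (mat.rate_prefactor * D_reg) ** (
        mat.m_sensitivity - 1.0
    )
    return out if out.ndim else float(out)


def deviatoric_stress(mat: ViscoplasticMaterial, eps_dot: np.ndarray) -> np.ndarray:
    """Deviatoric Cauchy stress of the generalised Norton-Hoff law.

    tau' = s*K*(sqrt(3)*D)**(m-1) * dev(eps_dot), with D regularised at the
    floor.  For m = 1 this is the Newtonian fluid s*K*eps_dot (isochoric
    rates); for m = 0 the stress magnitude is invariant under rate rescaling.
    """
    eps_dot = np.asarray(eps_dot, dtype=float)
    D = effective_rate(eps_dot)
    if D == 0.0:
        return np.zeros((3, 3))
    return apparent_viscosity(mat, D) * _deviator(eps_dot)


def penalty_block(lambda_penalty: float) -> np.ndarray:
    """Incompressibility penalty matrix Lambda (6x6, Voigt).

    lambda in the upper-left 3x3 block of ones: acting on a Voigt rate vector
    it puts lambda*(div v) in each normal-stress slot, so the quadratic form
    is lambda*(div v)^2 and vanishes on traceless (isochoric) rates.
    """
    if lambda_penalty < 0:
        raise ValueError("lambda_penalty must be non-negative")
    L = np.zeros((6, 6))
    L[:3, :3] = lambda_penalty
    return L


def viscoelastic_stress(
    mat: ViscoelasticMaterial, strain: np.ndarray, strain_rate: np.ndarray
) -> np.ndarray:
    """Kelvin-Voigt stress sigma = C(E, nu) eps + c * eps_dot (Voigt vectors)."""
    strain = np.asarray(strain, dtype=float)
    strain_rate = np.asarray(strain_rate, dtype=float)
    if strain.shape != (6,) or strain_rate.shape != (6,):
        raise ValueError("strain and strain_rate must be Voigt 6-vectors")
    return mat.stiffness_matrix() @ strain + mat.damping_matrix() @ strain_rate


def tensor_to_voigt_rate(t: np.ndarray) -> np.ndarray:
    """Symmetric tensor -> Voigt vector with engineering shear components."""
    t = np.asarray(t, dtype=float)
    return np.array([t[0, 0], t[1, 1], t[2, 2], 2 * t[0, 1], 2 * t[1, 2], 2 * t[2, 0]])


def voigt_rate_to_tensor(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    return np.array(
        [
            [v[0], v[3] / 2, v[5] / 2],
            [v[3] / 2, v[1], v[4] / 2],
            [v[5] / 2, v[4] / 2, v[2]],
        ]
    )
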