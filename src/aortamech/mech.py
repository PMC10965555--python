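"""Kinematics and constitutive law for an incompressible four-fiber-family artery wall.

The stored energy density combines a neo-Hookean term for the elastin-dominated
amorphous matrix with four exponential fiber families (axial, circumferential,
and two diagonals symmetric about the axis):

    W = (c/2) (I_C - 3) + sum_i c1_i / (4 c2_i) * [exp(c2_i (IV_i - 1)^2) - 1]

where ``I_C = tr(C)`` and ``IV_i = M_i . C . M_i`` is the squared stretch along
fiber direction ``M_i = [0, sin(a_i), cos(a_i)]`` (angle from the axial
direction). Incompressibility is enforced kinematically, ``lam_r = 1 / (lam_theta
* lam_z)``, and the radial normal stress is eliminated by the membrane condition
``sigma_rr = 0``, which fixes the Lagrange multiplier.

All stresses are in kPa; stretches are dimensionless; fiber angles are degrees
at the API boundary and radians internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FourFiberParams",
    "DeformationState",
    "deformation_from_stretches",
    "strain_energy",
    "cauchy_stress",
    "material_stiffness",
]

# Below this value the exponential family term is replaced by its exact
# quadratic (Taylor) limit; fitted exponents can legitimately be ~1e-14.
_C2_TINY = 1e-8

# Exponent cap: keeps intermediate evaluations finite when an optimizer or a
# bracketing search probes unphysically large fiber stretches.
_EXP_CAP = 500.0


def _safe_exp(arg: float) -> float:
    return math.exp(min(arg, _EXP_CAP))


@dataclass(frozen=True)
class FourFiberParams:
    """Material parameters of the four-fiber-family stored energy function.

    Parameters
    ----------
    c : float
        Isotropic (elastic-fiber) stiffness-like parameter, kPa.
    c1 : tuple of 4 floats
        Fiber stress-like parameters, kPa, ordered (axial, circumferential,
        diagonal, diagonal). The two diagonal families share parameters.
    c2 : tuple of 4 floats
        Dimensionless fiber exponents, same ordering and sharing.
    alpha0 : float
        Angle of the diagonal families from the axial direction, degrees,
        in [0, 90]. The two diagonal families sit at +alpha0 and -alpha0.
    """

    c: float
    c1: tuple[float, float, float, float]
    c2: tuple[float, float, float, float]
    alpha0: float

    def __post_init__(self) -> None:
        if self.c < 0:
            raise ValueError(f"c must be >= 0, got {self.c}")
        if len(self.c1) != 4 or len(self.c2) != 4:
            raise ValueError("c1 and c2 must each have 4 entries")
        if any(v < 0 for v in self.c1):
            raise ValueError(f"c1 entries must be >= 0, got {self.c1}")
        if any(v < 0 for v in self.c2):
            raise ValueError(f"c2 entries must be >= 0, got {self.c2}")
        if not 0.0 <= self.alpha0 <= 90.0:
            raise ValueError(f"alpha0 must be in [0, 90] degrees, got {self.alpha0}")
        if not math.isclose(self.c1[2], self.c1[3], rel_tol=0, abs_tol=0) or not math.isclose(
            self.c2[2], self.c2[3], rel_tol=0, abs_tol=0
        ):
            raise ValueError("diagonal families 3 and 4 must share c1 and c2")
        object.__setattr__(self, "c1", tuple(float(v) for v in self.c1))
        object.__setattr__(self, "c2", tuple(float(v) for v in self.c2))

    @classmethod
    def from_eight(
        cls,
        c: float,
        c1_axial: float,
        c2_axial: float,
        c1_circ: float,
        c2_circ: float,
        c1_diag: float,
        c2_diag: float,
        alpha0: float,
    ) -> "FourFiberParams":
        """Build from the eight independent parameters (diagonal pair shared)."""
        return cls(
            c=float(c),
            c1=(float(c1_axial), float(c1_circ), float(c1_diag), float(c1_diag)),
            c2=(float(c2_axial), float(c2_circ), float(c2_diag), float(c2_diag)),
            alpha0=float(alpha0),
        )

    def as_vector(self) -> np.ndarray:
        """Eight independent parameters: (c, c1_ax, c2_ax, c1_circ, c2_circ, c1_diag, c2_diag, alpha0)."""
        return np.array(
            [self.c, self.c1[0], self.c2[0], self.c1[1], self.c2[1], self.c1[2], self.c2[2], self.alpha0]
        )

    @classmethod
    def from_vector(cls, v) -> "FourFiberParams":
        v = np.asarray(v, dtype=float)
        return cls.from_eight(v[0], v[1], v[2], v[3], v[4], v[5], v[6], v[7])

    def family_angles_deg(self) -> tuple[float, float, float, float]:
        """Angles of the four families from the axial direction, degrees."""
        return (0.0, 90.0, self.alpha0, -self.alpha0)

    def _trig(self) -> tuple[np.ndarray, np.ndarray]:
        """sin^2 and cos^2 of the family angles (sign of alpha0 is immaterial)."""
        a = np.deg2rad(np.array(self.family_angles_deg()))
        return np.sin(a) ** 2, np.cos(a) ** 2


@dataclass(frozen=True)
class DeformationState:
    """Equibiaxial deformation of an incompressible cylindrical membrane.

    ``lam_r`` is derived from incompressibility (det F = 1); the deformation
    gradient is diagonal in cylindrical coordinates (r, theta, z).
    """

    lam_theta: float
    lam_z: float
    lam_r: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.lam_theta > 0:
            raise ValueError(f"lam_theta must be > 0, got {self.lam_theta}")
        if not self.lam_z > 0:
            raise ValueError(f"lam_z must be > 0, got {self.lam_z}")
        object.__setattr__(self, "lam_r", 1.0 / (self.lam_theta * self.lam_z))

    @property
    def F(self) -> np.ndarray:
        """Deformation gradient diag[lam_r, lam_theta, lam_z]."""
        return np.diag([self.lam_r, self.lam_theta, self.lam_z])

    @property
    def C(self) -> np.ndarray:
        """Right Cauchy-Green tensor F^T F."""
        return np.diag([self.lam_r**2, self.lam_theta**2, self.lam_z**2])

    @property
    def I_C(self) -> float:
        """First invariant tr(C)."""
        return self.lam_r**2 + self.lam_theta**2 + self.lam_z**2

    def fiber_invariants(self, params: FourFiberParams) -> np.ndarray:
        """IV_i = M_i . C . M_i for the four families (squared fiber stretch)."""
        s2, c2 = params._trig()
        return self.lam_theta**2 * s2 + self.lam_z**2 * c2


def deformation_from_stretches(lam_theta: float, lam_z: float) -> DeformationState:
    """Build an incompressible biaxial deformation state from the two in-plane stretches."""
    return DeformationState(lam_theta=float(lam_theta), lam_z=float(lam_z))


def _family_energy(c1: float, c2: float, x: float) -> float:
    """Energy of one family with x = IV - 1; quadratic limit for tiny exponent."""
    if c1 == 0.0:
        return 0.0
    if c2 < _C2_TINY:
        return 0.25 * c1 * x * x
    if c2 * x * x > _EXP_CAP:
        return c1 / (4.0 * c2) * (_safe_exp(c2 * x * x) - 1.0)
    return c1 / (4.0 * c2) * math.expm1(c2 * x * x)


def _family_dW(c1: float, c2: float, x: float) -> float:
    """dW_i/dIV; analytic, well defined at c2 = 0."""
    return 0.5 * c1 * x * _safe_exp(c2 * x * x)


def _family_d2W(c1: float, c2: float, x: float) -> float:
    """d2W_i/dIV^2."""
    return 0.5 * c1 * (1.0 + 2.0 * c2 * x * x) * _safe_exp(c2 * x * x)


def strain_energy(params: FourFiberParams, state: DeformationState) -> float:
    """Stored energy density W (kPa) at the given deformation."""
    W = 0.5 * params.c * (state.I_C - 3.0)
    IV = state.fiber_invariants(params)
    for i in range(4):
        W += _family_energy(params.c1[i], params.c2[i], IV[i] - 1.0)
    return W


def _reduced_derivs(params: FourFiberParams, state: DeformationState):
    """First and second partials of the incompressibility-reduced energy.

    With u = C_thth = lam_theta^2 and v = C_zz = lam_z^2 (and C_rr = 1/(u v)
    eliminated), returns (dW/du, dW/dv, d2W/du2, d2W/dv2, d2W/dudv).
    """
    u = state.lam_theta**2
    v = state.lam_z**2
    s2, co2 = params._trig()
    IV = u * s2 + v * co2
    c = params.c

    Wu = 0.5 * c * (1.0 - 1.0 / (u * u * v))
    Wv = 0.5 * c * (1.0 - 1.0 / (u * v * v))
    Wuu = c / (u**3 * v)
    Wvv = c / (u * v**3)
    Wuv = 0.5 * c / (u * u * v * v)
    for i in range(4):
        x = IV[i] - 1.0
        d1 = _family_dW(params.c1[i], params.c2[i], x)
        d2 = _family_d2W(params.c1[i], params.c2[i], x)
        Wu += d1 * s2[i]
        Wv += d1 * co2[i]
        Wuu += d2 * s2[i] * s2[i]
        Wvv += d2 * co2[i] * co2[i]
        Wuv += d2 * s2[i] * co2[i]
    return Wu, Wv, Wuu, Wvv, Wuv


def cauchy_stress(params: FourFiberParams, state: DeformationState) -> tuple[float, float]:
    """In-plane Cauchy normal stresses (sigma_theta, sigma_z) in kPa.

    sigma = -p I + 2 F (dW/dC) F^T with the Lagrange multiplier p eliminated
    by the membrane condition sigma_rr = 0. Shear components vanish for the
    mirror-symmetric diagonal pair.
    """
    Wu, Wv, *_ = _reduced_derivs(params, state)
    u = state.lam_theta**2
    v = state.lam_z**2
    return 2.0 * u * Wu, 2.0 * v * Wv


def material_stiffness(params: FourFiberParams, state: DeformationState) -> tuple[float, float, float]:
    """Small-on-large linearized stiffness components (C_tttt, C_zzzz, C_ttzz), kPa.

    Components of C_ijkl = sigma_il d_jk + sigma_lj d_ik
    + 4 F_iI F_jJ F_kK F_lL d2W^/dC_IJ dC_KL evaluated at the finite
    deformation, for small deformations superposed on the in-vivo state.
    """
    Wu, Wv, Wuu, Wvv, Wuv = _reduced_derivs(params, state)
    u = state.lam_theta**2
    v = state.lam_z**2
    sig_t = 2.0 * u * Wu
    sig_z = 2.0 * v * Wv
    C_tttt = 2.0 * sig_t + 4.0 * u * u * Wuu
    C_zzzz = 2.0 * sig_z + 4.0 * v * v * Wvv
    C_ttzz = 4.0 * u * v * Wuv
    return C_tttt, C_zzzz, C_ttzz
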