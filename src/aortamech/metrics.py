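"""In-vivo mechanical metrics at diastolic (80 mmHg) and systolic (120 mmHg) pressure.

The constitutive law is closed into a structural pressure-diameter response
through thin-wall equilibrium: at mid-wall stretches (lam_theta, lam_z) the
loaded geometry follows from incompressibility of the wall volume and the
luminal pressure from ``P = sigma_theta h / ri``. Metrics are evaluated at the
subject's estimated in-vivo axial stretch.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import brentq

from .experiment import MMHG_TO_KPA, VesselGeometry
from .mech import (
    FourFiberParams,
    deformation_from_stretches,
    cauchy_stress,
    material_stiffness,
    strain_energy,
)

__all__ = [
    "P_DIA_MMHG",
    "P_SYS_MMHG",
    "loaded_geometry",
    "equilibrium_pressure",
    "state_at_pressure",
    "distensibility",
    "InVivoMetrics",
    "compute_invivo_metrics",
]

P_DIA_MMHG = 80.0
P_SYS_MMHG = 120.0

_LAM_BRACKET = (0.5, 3.0)


class NoSolutionError(ValueError):
    """No circumferential stretch balances the requested pressure."""


def loaded_geometry(geom: VesselGeometry, lam_theta: float, lam_z: float) -> tuple[float, float]:
    """Loaded (ri, h) in um at mid-wall stretch lam_theta and axial stretch lam_z.

    Mid-wall radius maps as ``r_m = lam_theta * R_m`` and the membrane
    thickness as ``h = H / (lam_theta lam_z)``; wall volume is conserved.
    """
    R_m = 0.5 * (geom.Ri_um + geom.Ro_um)
    r_m = lam_theta * R_m
    h = geom.H_um / (lam_theta * lam_z)
    ri = r_m - 0.5 * h
    if ri <= 0:
        raise ValueError(f"non-positive lumen radius at lam_theta={lam_theta}, lam_z={lam_z}")
    return float(ri), float(h)


def equilibrium_pressure(
    params: FourFiberParams, geom: VesselGeometry, lam_theta: float, lam_z: float
) -> float:
    """Luminal pressure (mmHg) balancing the wall at the given stretches."""
    state = deformation_from_stretches(lam_theta, lam_z)
    sigma_theta, _ = cauchy_stress(params, state)
    ri, h = loaded_geometry(geom, lam_theta, lam_z)
    return sigma_theta * h / ri / MMHG_TO_KPA


def state_at_pressure(
    params: FourFiberParams,
    geom: VesselGeometry,
    P_mmHg: float,
    lam_z: float,
    xtol: float = 1e-12,
):
    """Circumferential stretch state balancing pressure P at fixed axial stretch.

    Bracketed root search over lam_theta, then Brent polish; the residual
    pressure is below 1e-8 mmHg. Raises NoSolutionError when no bracket is
    found within the admissible stretch range.
    """

    def resid(lt: float) -> float:
        return equilibrium_pressure(params, geom, lt, lam_z) - P_mmHg

    lo, hi = _LAM_BRACKET
    grid = np.linspace(lo, hi, 61)
    vals = []
    for lt in grid:
        try:
            vals.append(resid(lt))
        except ValueError:
            vals.append(np.nan)
    vals = np.array(vals)
    ok = np.isfinite(vals)
    bracket = None
    for a, b, fa, fb in zip(grid[:-1], grid[1:], vals[:-1], vals[1:]):
        if np.isfinite(fa) and np.isfinite(fb) and fa * fb <= 0:
            bracket = (a, b)
            break
    if bracket is None:
        raise NoSolutionError(
            f"no equilibrium at P={P_mmHg} mmHg, lam_z={lam_z} for lam_theta in "
            f"[{grid[ok][0]:.2f}, {grid[ok][-1]:.2f}]"
        )
    lam_theta = brentq(resid, *bracket, xtol=xtol)
    return deformation_from_stretches(lam_theta, lam_z)


def distensibility(di_sys: float, di_dia: float, P_sys_mmHg: float, P_dia_mmHg: float) -> float:
    """Cyclic distensibility D = (d_sys - d_dia) / (d_dia (P_sys - P_dia)), mmHg^-1.

    An inverse measure of structural stiffness; invariant to the diameter unit.
    """
    if not P_sys_mmHg > P_dia_mmHg > 0:
        raise ValueError("need P_sys > P_dia > 0")
    if di_sys <= 0 or di_dia <= 0:
        raise ValueError("diameters must be positive")
    return (di_sys - di_dia) / (di_dia * (P_sys_mmHg - P_dia_mmHg))


@dataclass(frozen=True)
class InVivoMetrics:
    """Per-sample mechanical metrics at the in-vivo working point.

    Stresses and energy in kPa, stiffness in MPa, diameters/thickness in um,
    distensibility in mmHg^-1 (also exposed x1e3 for display). The normalized
    diameter is filled later by the allometric classifier.
    """

    sample_id: str
    lam_theta_sys: float
    lam_z_iv: float
    sigma_theta_sys_kPa: float
    sigma_z_sys_kPa: float
    C_tttt_sys_MPa: float
    C_zzzz_sys_MPa: float
    C_ttzz_sys_MPa: float
    W_sys_kPa: float
    h_sys_um: float
    di_sys_um: float
    di_dia_um: float
    distensibility_per_mmHg: float
    distensibility_e3: float
    normalized_diameter: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def compute_invivo_metrics(
    params: FourFiberParams,
    geom: VesselGeometry,
    lam_z_iv: float,
    sample_id: str = "",
) -> InVivoMetrics:
    """Evaluate all in-vivo metrics at 80/120 mmHg and the in-vivo axial stretch."""
    try:
        s_dia = state_at_pressure(params, geom, P_DIA_MMHG, lam_z_iv)
        s_sys = state_at_pressure(params, geom, P_SYS_MMHG, lam_z_iv)
    except NoSolutionError as exc:
        raise NoSolutionError(f"sample {sample_id!r}: {exc}") from exc
    ri_d, _ = loaded_geometry(geom, s_dia.lam_theta, lam_z_iv)
    ri_s, h_s = loaded_geometry(geom, s_sys.lam_theta, lam_z_iv)
    st, sz = cauchy_stress(params, s_sys)
    Ct, Cz, Ctz = material_stiffness(params, s_sys)
    D = distensibility(2 * ri_s, 2 * ri_d, P_SYS_MMHG, P_DIA_MMHG)
    return InVivoMetrics(
        sample_id=sample_id,
        lam_theta_sys=s_sys.lam_theta,
        lam_z_iv=lam_z_iv,
        sigma_theta_sys_kPa=st,
        sigma_z_sys_kPa=sz,
        C_tttt_sys_MPa=Ct / 1e3,
        C_zzzz_sys_MPa=Cz / 1e3,
        C_ttzz_sys_MPa=Ctz / 1e3,
        W_sys_kPa=strain_energy(params, s_sys),
        h_sys_um=h_s,
        di_sys_um=2 * ri_s,
        di_dia_um=2 * ri_d,
        distensibility_per_mmHg=D,
        distensibility_e3=D * 1e3,
    )
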