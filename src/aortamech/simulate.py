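"""Synthetic biaxial records and cohorts with the structure the analysis assumes.

Ground-truth vessels obey the four-fiber-family law closed by thin-wall
equilibrium. The simulated protocols mirror the bench ones: cyclic
pressurization 10-140 mmHg at the in-vivo axial stretch and at +/-5% of it,
and axial force-length sweeps at fixed pressures of 10/60/100/140 mmHg
truncated to the -0.5 to 5 g transducer window. Measurement noise is
multiplicative Gaussian on diameter and force (camera / load-cell precision)
and additive jitter on pressure.

``MURINE_ATA_PARAMS`` holds representative best-fit parameter sets for the
murine ascending thoracic aorta by genotype and age (wild-type, perlecan
haploinsufficient Hspg2+/-, Marfan-model mgdlpn, and double mutant), with
printed values indistinguishable from zero (< 1e-3) set to exact zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .experiment import (
    BiaxialDataPoint,
    SubjectRecord,
    VesselGeometry,
    axial_force_from_stress,
    write_metadata_csv,
    write_sample_csv,
)
from .mech import FourFiberParams, cauchy_stress, deformation_from_stretches
from .metrics import equilibrium_pressure, loaded_geometry, state_at_pressure

__all__ = [
    "MURINE_ATA_PARAMS",
    "DEFAULT_GEOMETRY",
    "AllometricTruth",
    "NoiseModel",
    "SimulationSpec",
    "find_force_invariant_stretch",
    "simulate_pd_protocol",
    "simulate_fl_protocol",
    "simulate_subject",
    "simulate_allometric_cohort",
    "simulate_cohort",
]

logger = logging.getLogger(__name__)


class SimulationSpecError(ValueError):
    """Simulated structural response is unusable (e.g. non-monotone P-d)."""


def _p(c, c1a, c2a, c1c, c2c, c1d, c2d, a0) -> FourFiberParams:
    return FourFiberParams.from_eight(c, c1a, c2a, c1c, c2c, c1d, c2d, a0)


#: (genotype, age_weeks) -> representative constitutive parameters
MURINE_ATA_PARAMS: dict[tuple[str, int], FourFiberParams] = {
    ("WT", 4): _p(25.05, 15.85, 0.04, 11.36, 0.0, 11.06, 0.40, 51),
    ("WT", 12): _p(14.46, 12.98, 0.07, 0.03, 1.75, 29.45, 0.20, 53),
    ("WT", 30): _p(21.48, 7.52, 0.0, 9.42, 0.45, 17.52, 0.27, 46),
    ("Hspg2+/-", 12): _p(14.77, 12.69, 0.05, 0.01, 2.09, 32.91, 0.18, 53),
    ("mgdlpn", 4): _p(30.07, 2.79, 0.41, 0.0, 8.57, 13.22, 0.63, 53),
    ("mgdlpn", 12): _p(0.0, 14.79, 0.0, 3.31, 1.05, 23.44, 0.44, 50),
    ("mgdlpn", 30): _p(27.78, 0.0, 0.0, 0.0, 18.59, 21.31, 1.58, 59),
    ("dMut", 12): _p(0.0, 12.88, 0.0, 2.41, 0.63, 30.15, 0.35, 49),
}

#: unloaded geometry yielding loaded dimensions at the murine ATA scale
DEFAULT_GEOMETRY = VesselGeometry(Ro_um=540.0, H_um=90.0, L_mm=4.0)

PD_PRESSURES_MMHG = np.arange(10.0, 141.0, 5.0)  # even resampling grid
FL_PRESSURES_MMHG = (10.0, 60.0, 100.0, 140.0)
FL_FORCE_WINDOW_G = (-0.5, 5.0)


@dataclass(frozen=True)
class AllometricTruth:
    """Generating power law di = alpha * BM^beta with log-normal scatter."""

    alpha: float = 671.7862  # um * g^-beta
    beta: float = 0.2816
    s_log: float = 0.04  # residual SD on the natural-log scale


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: multiplicative CVs and additive pressure jitter."""

    od_cv: float = 0.01
    force_cv: float = 0.02
    pressure_sd_mmHg: float = 0.5

    def __post_init__(self) -> None:
        if min(self.od_cv, self.force_cv, self.pressure_sd_mmHg) < 0:
            raise ValueError("noise magnitudes must be >= 0")

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for one simulated vessel/genotype group."""

    genotype: str = "WT"
    age_weeks: int = 12
    params: FourFiberParams = field(default_factory=lambda: MURINE_ATA_PARAMS[("WT", 12)])
    geometry: VesselGeometry = DEFAULT_GEOMETRY
    geometry_cv: float = 0.05  # sample-to-sample CV on wall thickness and length
    lam_z_iv: float | None = None  # None: use the model's force-invariance point
    n_pd_pressures: int = 27
    n_fl_stretches: int = 28
    dilatation_multiplier: float = 1.0
    noise: NoiseModel = field(default_factory=NoiseModel)

    def resolve_lam_z_iv(self) -> float:
        if self.lam_z_iv is not None:
            return self.lam_z_iv
        return find_force_invariant_stretch(self.params, self.geometry)

    @classmethod
    def from_yaml(cls, path) -> "SimulationSpec":
        """Load a spec from YAML; ``params`` is the 8-vector
        (c, c1_ax, c2_ax, c1_circ, c2_circ, c1_diag, c2_diag, alpha0) or a
        (genotype, age_weeks) reference key; ``geometry`` is {Ro_um, H_um, L_mm}."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        kwargs = dict(raw)
        if "params" in kwargs:
            p = kwargs["params"]
            if isinstance(p, (list, tuple)):
                kwargs["params"] = FourFiberParams.from_vector(p)
            else:
                kwargs["params"] = MURINE_ATA_PARAMS[(p["genotype"], int(p["age_weeks"]))]
        if "geometry" in kwargs:
            kwargs["geometry"] = VesselGeometry(**kwargs["geometry"])
        if "noise" in kwargs:
            kwargs["noise"] = NoiseModel(**kwargs["noise"])
        return cls(**kwargs)


def _axial_force_g(
    params: FourFiberParams, geom: VesselGeometry, P_mmHg: float, lam_z: float
) -> tuple[float, float, float]:
    """(force_g, ri, h) at equilibrium under pressure P and axial stretch lam_z."""
    state = state_at_pressure(params, geom, P_mmHg, lam_z)
    _, sigma_z = cauchy_stress(params, state)
    ri, h = loaded_geometry(geom, state.lam_theta, lam_z)
    return axial_force_from_stress(sigma_z, P_mmHg, ri, h), ri, h


def find_force_invariant_stretch(
    params: FourFiberParams,
    geom: VesselGeometry,
    lam_z_range: tuple[float, float] = (1.15, 2.3),
    pressures: tuple[float, ...] = FL_PRESSURES_MMHG,
    n_grid: int = 24,
) -> float:
    """Axial stretch at which axial force is invariant to pressurization.

    The least-squares slope of force vs pressure is evaluated on a stretch
    grid and its zero crossing refined by a bracketed root search.
    """
    P = np.asarray(pressures)

    def slope(lam_z: float) -> float:
        f = np.array([_axial_force_g(params, geom, p, lam_z)[0] for p in P])
        return float(np.polyfit(P, f, 1)[0])

    grid = np.linspace(*lam_z_range, n_grid)
    slopes = np.full_like(grid, np.nan)
    for i, lz in enumerate(grid):
        try:
            slopes[i] = slope(lz)
        except ValueError:
            # stretch outside the structurally admissible range for this vessel
            continue
    ok = np.isfinite(slopes)
    sign_change = [
        i
        for i in range(len(grid) - 1)
        if ok[i] and ok[i + 1] and slopes[i] * slopes[i + 1] <= 0
    ]
    if not sign_change:
        raise SimulationSpecError(
            f"no force-invariance point in lam_z range {lam_z_range} "
            f"(valid slopes {slopes[ok][:1]}..{slopes[ok][-1:]})"
        )
    j = sign_change[0]
    return float(brentq(slope, grid[j], grid[j + 1], xtol=1e-10))


def _apply_noise(rng: np.random.Generator, noise: NoiseModel, od, f, P):
    od = od * (1.0 + noise.od_cv * rng.standard_normal(np.shape(od)))
    f = f * (1.0 + noise.force_cv * rng.standard_normal(np.shape(f)))
    P = P + noise.pressure_sd_mmHg * rng.standard_normal(np.shape(P))
    return od, f, P


def simulate_pd_protocol(
    spec: SimulationSpec,
    lam_z: float,
    protocol: str,
    rng: np.random.Generator | None = None,
) -> list[BiaxialDataPoint]:
    """Pressure-diameter sweep at fixed axial stretch, on an even pressure grid.

    The structural response is first swept over circumferential stretch to
    verify monotonicity of pressure, then each grid pressure is solved exactly.
    """
    params, geom = spec.params, spec.geometry
    rng = rng or np.random.default_rng(0)
    P_grid = np.linspace(PD_PRESSURES_MMHG[0], PD_PRESSURES_MMHG[-1], spec.n_pd_pressures)
    lo = state_at_pressure(params, geom, P_grid[0], lam_z).lam_theta
    hi = state_at_pressure(params, geom, P_grid[-1], lam_z).lam_theta
    sweep = np.linspace(lo, hi, 60)
    P_sweep = np.array([equilibrium_pressure(params, geom, lt, lam_z) for lt in sweep])
    if np.any(np.diff(P_sweep) <= 0):
        raise SimulationSpecError(
            f"non-monotone pressure-diameter response at lam_z={lam_z:.3f}"
        )
    od, f = [], []
    for P in P_grid:
        fz, ri, h = _axial_force_g(params, geom, P, lam_z)
        od.append(2.0 * (ri + h))
        f.append(fz)
    od, f, P_out = _apply_noise(rng, spec.noise, np.array(od), np.array(f), P_grid)
    length = lam_z * geom.L_mm
    return [
        BiaxialDataPoint(
            pressure_mmHg=float(P_out[i]),
            outer_diameter_um=float(od[i]),
            axial_length_mm=float(length),
            axial_force_g=float(f[i]),
            protocol=protocol,
            cycle=2,
        )
        for i in range(len(P_grid))
    ]


def simulate_fl_protocol(
    spec: SimulationSpec,
    P_mmHg: float,
    lam_z_iv: float,
    rng: np.random.Generator | None = None,
) -> list[BiaxialDataPoint]:
    """Force-length sweep at fixed pressure, truncated to the transducer window."""
    params, geom = spec.params, spec.geometry
    rng = rng or np.random.default_rng(0)
    lam_z_grid = np.round(
        lam_z_iv * np.linspace(0.85, 1.12, spec.n_fl_stretches), 6
    )
    rows = []
    for lam_z in lam_z_grid:
        try:
            fz, ri, h = _axial_force_g(params, geom, P_mmHg, lam_z)
        except ValueError:
            # stretch outside the structurally admissible range at this pressure
            continue
        rows.append((lam_z, fz, 2.0 * (ri + h)))
    if not rows:
        raise SimulationSpecError(f"no admissible stretch at P={P_mmHg} mmHg")
    lam_z_arr = np.array([r[0] for r in rows])
    f = np.array([r[1] for r in rows])
    od = np.array([r[2] for r in rows])
    od, f, P_out = _apply_noise(rng, spec.noise, od, f, np.full_like(f, P_mmHg))
    keep = (f >= FL_FORCE_WINDOW_G[0]) & (f <= FL_FORCE_WINDOW_G[1])
    tag = f"fl_{int(P_mmHg)}"
    return [
        BiaxialDataPoint(
            pressure_mmHg=float(P_out[i]),
            outer_diameter_um=float(od[i]),
            axial_length_mm=float(lam_z_arr[i] * geom.L_mm),
            axial_force_g=float(f[i]),
            protocol=tag,
            cycle=2,
        )
        for i in np.flatnonzero(keep)
    ]


def simulate_subject(
    spec: SimulationSpec,
    sample_id: str = "sim-001",
    body_mass_g: float = 22.0,
    seed: int | np.random.Generator = 0,
) -> SubjectRecord:
    """Full simulated biaxial record: three P-d protocols and four f-l protocols."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lam_z_iv = spec.resolve_lam_z_iv()
    points: list[BiaxialDataPoint] = []
    for tag, factor in (("pd_iv", 1.0), ("pd_plus5", 1.05), ("pd_minus5", 0.95)):
        points.extend(simulate_pd_protocol(spec, lam_z_iv * factor, tag, rng))
    for P in FL_PRESSURES_MMHG:
        points.extend(simulate_fl_protocol(spec, P, lam_z_iv, rng))
    return SubjectRecord(
        sample_id=sample_id,
        genotype=spec.genotype,
        age_weeks=spec.age_weeks,
        body_mass_g=body_mass_g,
        geometry=spec.geometry,
        points=points,
    )


def simulate_allometric_cohort(
    n: int,
    truth: AllometricTruth = AllometricTruth(),
    dilatation_multiplier: float = 1.0,
    mass_range_g: tuple[float, float] = (15.0, 35.0),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Body-mass / systolic-luminal-diameter pairs following the power law.

    ln(di) = ln(alpha) + beta ln(BM) + ln(multiplier) + N(0, s_log). Cheap
    (no mechanics); used for classifier calibration and to target cohort
    diameters.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = mass_range_g
    bm = rng.uniform(lo, hi, size=n)
    noise = rng.normal(0.0, truth.s_log, size=n)
    di = truth.alpha * bm**truth.beta * dilatation_multiplier * np.exp(noise)
    return pd.DataFrame({"body_mass_g": bm, "di_um": di})


def _scaled_geometry(
    spec: SimulationSpec, target_di_um: float, lam_z_iv: float, rng: np.random.Generator
) -> VesselGeometry:
    """Scale the unloaded radii so the model's systolic lumen matches target_di.

    The equilibrium stretch solution is invariant under a uniform radial
    scaling (h/ri is preserved), so the loaded diameter scales linearly.
    """
    base = spec.geometry
    s_sys = state_at_pressure(spec.params, base, 120.0, lam_z_iv)
    ri, _ = loaded_geometry(base, s_sys.lam_theta, lam_z_iv)
    scale = target_di_um / (2.0 * ri)
    cv = spec.geometry_cv
    H = base.H_um * scale * (1.0 + cv * rng.standard_normal())
    L = base.L_mm * (1.0 + cv * rng.standard_normal())
    return VesselGeometry(Ro_um=base.Ro_um * scale, H_um=H, L_mm=L)


def simulate_cohort(
    specs: dict[str, SimulationSpec],
    n_per_group: int,
    truth: AllometricTruth = AllometricTruth(),
    seed: int = 0,
    outdir: str | Path | None = None,
) -> list[SubjectRecord]:
    """Simulate a multi-genotype cohort; optionally write the CSV schemas.

    Each sample's systolic luminal diameter is drawn from the allometric law
    times the genotype's dilatation multiplier, and its unloaded geometry is
    scaled so the mechanical model reproduces that diameter. Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    records: list[SubjectRecord] = []
    for genotype in sorted(specs):
        spec = specs[genotype]
        lam_z_iv = spec.resolve_lam_z_iv()
        targets = simulate_allometric_cohort(
            n_per_group, truth, spec.dilatation_multiplier, seed=rng
        )
        for k in range(n_per_group):
            bm = float(targets.body_mass_g[k])
            geom = _scaled_geometry(spec, float(targets.di_um[k]), lam_z_iv, rng)
            # the bench estimates the working length per vessel: re-resolve the
            # force-invariance point for this sample's perturbed geometry
            sample_spec = replace(spec, geometry=geom, lam_z_iv=None)
            sid = f"{genotype.replace('+/-', '_het').replace('/', '_')}-{k:03d}"
            records.append(simulate_subject(sample_spec, sid, bm, rng))
            logger.info("simulated %s (BM %.1f g)", sid, bm)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_metadata_csv(outdir / "cohort_metadata.csv", records)
        for rec in records:
            write_sample_csv(outdir / f"{rec.sample_id}.csv", rec)
    return records
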