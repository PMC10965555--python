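"""Data model and reduction of raw biaxial inflation-extension records.

Raw records are per-sample CSV tables of (pressure, outer diameter, axial
length, axial force) acquired under two protocol sets: pressure-diameter
sweeps at the in-vivo axial stretch and at +/-5% of it, and force-length
sweeps at fixed pressures of 10/60/100/140 mmHg. Reduction maps each point
to mid-wall stretches and mean wall stresses assuming incompressibility of
the wall volume.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MMHG_TO_KPA",
    "GF_TO_MN",
    "PD_PROTOCOLS",
    "FL_PROTOCOLS",
    "VesselGeometry",
    "BiaxialDataPoint",
    "SubjectRecord",
    "current_geometry",
    "experimental_wall_stress",
    "estimate_invivo_stretch",
    "reduce_record",
    "read_sample_csv",
    "write_sample_csv",
    "read_metadata_csv",
    "write_metadata_csv",
]

logger = logging.getLogger(__name__)

MMHG_TO_KPA = 0.1333224  # 1 mmHg in kPa
GF_TO_MN = 9.80665  # 1 gram-force in mN

#: protocol tags: pressure-diameter at the in-vivo stretch and +/-5%,
#: force-length at fixed pressure (mmHg)
PD_PROTOCOLS = ("pd_iv", "pd_plus5", "pd_minus5")
FL_PROTOCOLS = ("fl_10", "fl_60", "fl_100", "fl_140")

_P_SANITY = (0.0, 200.0)  # mmHg
_F_SANITY = (-2.0, 10.0)  # g


class InconsistentMeasurementError(ValueError):
    """Measured diameter incompatible with incompressible wall volume."""


class NoCrossoverError(ValueError):
    """Force-pressure slopes do not change sign over the tested stretches."""


@dataclass(frozen=True)
class VesselGeometry:
    """Traction-free (unloaded) geometry: outer radius and wall thickness in um, length in mm."""

    Ro_um: float
    H_um: float
    L_mm: float

    def __post_init__(self) -> None:
        if not 0 < self.H_um < self.Ro_um:
            raise ValueError(f"need 0 < H < Ro, got H={self.H_um}, Ro={self.Ro_um}")
        if not self.L_mm > 0:
            raise ValueError(f"unloaded length must be > 0, got {self.L_mm}")

    @property
    def Ri_um(self) -> float:
        """Unloaded inner radius."""
        return self.Ro_um - self.H_um


@dataclass(frozen=True)
class BiaxialDataPoint:
    """One acquired point of a biaxial test."""

    pressure_mmHg: float
    outer_diameter_um: float
    axial_length_mm: float
    axial_force_g: float
    protocol: str
    cycle: int = 1

    def validate(self) -> str | None:
        """Return a rejection reason, or None if the point passes sanity bands."""
        if self.outer_diameter_um <= 0:
            return "non-positive outer diameter"
        if self.axial_length_mm <= 0:
            return "non-positive axial length"
        if not _P_SANITY[0] <= self.pressure_mmHg <= _P_SANITY[1]:
            return f"pressure outside sanity band {_P_SANITY} mmHg"
        if not _F_SANITY[0] <= self.axial_force_g <= _F_SANITY[1]:
            return f"axial force outside sanity band {_F_SANITY} g"
        return None


@dataclass
class SubjectRecord:
    """One animal: metadata, unloaded geometry, and its protocol data series."""

    sample_id: str
    genotype: str
    age_weeks: float
    body_mass_g: float
    geometry: VesselGeometry
    points: list[BiaxialDataPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.body_mass_g > 0:
            raise ValueError(f"body mass must be > 0, got {self.body_mass_g}")

    def protocol_points(self, protocol: str) -> list[BiaxialDataPoint]:
        """Points of one protocol, restricted to its last recorded cycle."""
        pts = [p for p in self.points if p.protocol == protocol]
        if not pts:
            return []
        last = max(p.cycle for p in pts)
        return [p for p in pts if p.cycle == last]

    def protocols(self) -> list[str]:
        return sorted({p.protocol for p in self.points})

    def has_fitting_data(self) -> bool:
        """At least one pressure-diameter and one force-length protocol."""
        tags = set(self.protocols())
        return bool(tags & set(PD_PROTOCOLS)) and bool(tags & set(FL_PROTOCOLS))


def current_geometry(geom: VesselGeometry, od_um: float, lam_z: float) -> tuple[float, float]:
    """Loaded inner radius and wall thickness (um) from outer diameter and axial stretch.

    Conservation of wall volume under incompressibility gives
    ``ri = sqrt(ro^2 - (Ro^2 - Ri^2)/lam_z)`` with ``ro = od/2``.
    """
    ro = 0.5 * od_um
    rad = ro * ro - (geom.Ro_um**2 - geom.Ri_um**2) / lam_z
    if rad < 0:
        raise InconsistentMeasurementError(
            f"outer diameter {od_um} um too small for wall volume at lam_z={lam_z}"
        )
    ri = np.sqrt(rad)
    return float(ri), float(ro - ri)


def mid_wall_stretch(geom: VesselGeometry, ri_um: float, ro_um: float) -> float:
    """Circumferential stretch of the mid-wall radius."""
    return (ri_um + ro_um) / (geom.Ri_um + geom.Ro_um)


def experimental_wall_stress(
    P_mmHg: float, f_g: float, ri_um: float, h_um: float
) -> tuple[float, float]:
    """Mean wall stresses (sigma_theta, sigma_z) in kPa from load-cell data.

    Thin-wall hoop equilibrium ``sigma_theta = P ri / h`` and axial force
    balance ``sigma_z = (f + P pi ri^2) / (pi h (2 ri + h))``, with the
    transducer force augmented by the pressure acting on the closed end.
    """
    if ri_um <= 0 or h_um <= 0:
        raise ValueError("ri and h must be positive")
    P_kPa = P_mmHg * MMHG_TO_KPA
    f_mN = f_g * GF_TO_MN
    sigma_theta = P_kPa * ri_um / h_um
    # kPa = mN/mm^2; convert um^2 areas to mm^2
    lumen_mm2 = np.pi * ri_um**2 * 1e-6
    wall_mm2 = np.pi * h_um * (2.0 * ri_um + h_um) * 1e-6
    sigma_z = (f_mN + P_kPa * lumen_mm2) / wall_mm2
    return float(sigma_theta), float(sigma_z)


def axial_force_from_stress(
    sigma_z_kPa: float, P_mmHg: float, ri_um: float, h_um: float
) -> float:
    """Transducer axial force (g) from the mean axial wall stress; inverse of the force balance."""
    P_kPa = P_mmHg * MMHG_TO_KPA
    lumen_mm2 = np.pi * ri_um**2 * 1e-6
    wall_mm2 = np.pi * h_um * (2.0 * ri_um + h_um) * 1e-6
    f_mN = sigma_z_kPa * wall_mm2 - P_kPa * lumen_mm2
    return float(f_mN / GF_TO_MN)


def _ascending_limb(pts: list[BiaxialDataPoint]) -> list[BiaxialDataPoint]:
    """Points up to (and including) the pressure maximum: the loading limb."""
    if not pts:
        return pts
    imax = int(np.argmax([p.pressure_mmHg for p in pts]))
    return pts[: imax + 1]


def reduce_record(record: SubjectRecord) -> pd.DataFrame:
    """Reduce raw points to stretches and experimental wall stresses.

    Returns one row per retained point with columns: protocol, pressure_mmHg,
    axial_force_g, lam_theta (mid-wall), lam_z, ri_um, h_um, sigma_theta_kPa,
    sigma_z_kPa. Pressure-diameter protocols keep the loading limb of the last
    cycle; force-length protocols keep the last cycle. Rows failing sanity
    bands or the wall-volume consistency check are dropped and logged.
    """
    geom = record.geometry
    rows = []
    n_rejected = 0
    for tag in record.protocols():
        pts = record.protocol_points(tag)
        if tag in PD_PROTOCOLS:
            pts = _ascending_limb(pts)
        for p in pts:
            reason = p.validate()
            if reason is None:
                try:
                    lam_z = p.axial_length_mm / geom.L_mm
                    ri, h = current_geometry(geom, p.outer_diameter_um, lam_z)
                    lam_t = mid_wall_stretch(geom, ri, ri + h)
                    st, sz = experimental_wall_stress(p.pressure_mmHg, p.axial_force_g, ri, h)
                except InconsistentMeasurementError as exc:
                    reason = str(exc)
            if reason is not None:
                n_rejected += 1
                logger.warning("%s/%s: rejected point (%s)", record.sample_id, tag, reason)
                continue
            rows.append(
                dict(
                    protocol=tag,
                    pressure_mmHg=p.pressure_mmHg,
                    axial_force_g=p.axial_force_g,
                    lam_theta=lam_t,
                    lam_z=lam_z,
                    ri_um=ri,
                    h_um=h,
                    sigma_theta_kPa=st,
                    sigma_z_kPa=sz,
                )
            )
    df = pd.DataFrame(rows)
    logger.info("%s: reduced %d points (%d rejected)", record.sample_id, len(df), n_rejected)
    return df


def estimate_invivo_stretch(record: SubjectRecord) -> float:
    """In-vivo axial stretch from the force-invariance criterion.

    At the energetically preferred working length the axial force does not
    change with pressure. For each axial stretch sampled by the force-length
    protocols, the slope of force vs pressure is fitted by least squares;
    the returned stretch is where the slope crosses zero (linear interpolation
    between neighbouring stretches).
    """
    L = record.geometry.L_mm
    # force samples keyed by rounded stretch so the same actuator position
    # lines up across the fixed-pressure protocols
    by_stretch: dict[float, list[tuple[float, float]]] = {}
    for tag in FL_PROTOCOLS:
        for p in record.protocol_points(tag):
            lam_z = round(p.axial_length_mm / L, 6)
            by_stretch.setdefault(lam_z, []).append((p.pressure_mmHg, p.axial_force_g))
    stretches, slopes = [], []
    for lam_z in sorted(by_stretch):
        samples = by_stretch[lam_z]
        if len({P for P, _ in samples}) < 3:
            continue
        P = np.array([s[0] for s in samples])
        f = np.array([s[1] for s in samples])
        slopes.append(np.polyfit(P, f, 1)[0])
        stretches.append(lam_z)
    if len(stretches) < 3:
        raise ValueError(
            f"{record.sample_id}: need force-pressure data at >= 3 axial stretches, "
            f"got {len(stretches)}"
        )
    stretches = np.array(stretches)
    slopes = np.array(slopes)
    sign = np.sign(slopes)
    crossings = np.where(sign[:-1] * sign[1:] <= 0)[0]
    if slopes.min() > 0 or slopes.max() < 0:
        raise NoCrossoverError(
            f"{record.sample_id}: force-pressure slopes all "
            f"{'positive' if slopes.min() > 0 else 'negative'}; tested stretch range "
            f"[{stretches[0]:.3f}, {stretches[-1]:.3f}] does not bracket the in-vivo point"
        )
    exact = np.where(slopes == 0.0)[0]
    if exact.size:
        return float(stretches[exact[0]])
    j = int(crossings[0])
    s0, s1 = slopes[j], slopes[j + 1]
    t = s0 / (s0 - s1)
    return float(stretches[j] + t * (stretches[j + 1] - stretches[j]))


# ---------------------------------------------------------------------------
# CSV I/O

_SAMPLE_COLUMNS = [
    "sample_id",
    "protocol",
    "cycle",
    "pressure_mmHg",
    "outer_diameter_um",
    "axial_length_mm",
    "axial_force_g",
]
_META_COLUMNS = ["sample_id", "genotype", "age_weeks", "body_mass_g", "Ro_um", "H_um", "L_mm"]


def write_sample_csv(path, record: SubjectRecord) -> None:
    """Write one sample's raw data points to the per-sample CSV schema."""
    df = pd.DataFrame(
        [
            dict(
                sample_id=record.sample_id,
                protocol=p.protocol,
                cycle=p.cycle,
                pressure_mmHg=p.pressure_mmHg,
                outer_diameter_um=p.outer_diameter_um,
                axial_length_mm=p.axial_length_mm,
                axial_force_g=p.axial_force_g,
            )
            for p in record.points
        ],
        columns=_SAMPLE_COLUMNS,
    )
    df.to_csv(path, index=False)
    logger.info("wrote %d rows to %s", len(df), path)


def read_sample_csv(path, metadata_row: pd.Series | dict) -> SubjectRecord:
    """Read one sample's raw CSV, pairing it with its cohort-metadata row."""
    m = dict(metadata_row)
    geom = VesselGeometry(Ro_um=float(m["Ro_um"]), H_um=float(m["H_um"]), L_mm=float(m["L_mm"]))
    df = pd.read_csv(path)
    missing = set(_SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    points = [
        BiaxialDataPoint(
            pressure_mmHg=float(r.pressure_mmHg),
            outer_diameter_um=float(r.outer_diameter_um),
            axial_length_mm=float(r.axial_length_mm),
            axial_force_g=float(r.axial_force_g),
            protocol=str(r.protocol),
            cycle=int(r.cycle),
        )
        for r in df.itertuples()
    ]
    logger.info("read %d rows from %s", len(points), path)
    return SubjectRecord(
        sample_id=str(m["sample_id"]),
        genotype=str(m["genotype"]),
        age_weeks=float(m["age_weeks"]),
        body_mass_g=float(m["body_mass_g"]),
        geometry=geom,
        points=points,
    )


def write_metadata_csv(path, records: list[SubjectRecord]) -> None:
    df = pd.DataFrame(
        [
            dict(
                sample_id=r.sample_id,
                genotype=r.genotype,
                age_weeks=r.age_weeks,
                body_mass_g=r.body_mass_g,
                Ro_um=r.geometry.Ro_um,
                H_um=r.geometry.H_um,
                L_mm=r.geometry.L_mm,
            )
            for r in records
        ],
        columns=_META_COLUMNS,
    )
    df.to_csv(path, index=False)
    logger.info("wrote %d metadata rows to %s", len(df), path)


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_META_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    logger.info("read %d metadata rows from %s", len(df), path)
    return df
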