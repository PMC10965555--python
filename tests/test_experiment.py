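"""Data reduction: loaded geometry, wall stresses, unit handling, in-vivo stretch."""

import numpy as np
import pytest

from aortamech.experiment import (
    GF_TO_MN,
    MMHG_TO_KPA,
    BiaxialDataPoint,
    InconsistentMeasurementError,
    NoCrossoverError,
    SubjectRecord,
    VesselGeometry,
    current_geometry,
    estimate_invivo_stretch,
    experimental_wall_stress,
    read_metadata_csv,
    read_sample_csv,
    reduce_record,
    write_metadata_csv,
    write_sample_csv,
)
from aortamech.metrics import loaded_geometry
from aortamech.simulate import DEFAULT_GEOMETRY


def test_geometry_validation():
    with pytest.raises(ValueError):
        VesselGeometry(Ro_um=100, H_um=100, L_mm=4)
    with pytest.raises(ValueError):
        VesselGeometry(Ro_um=100, H_um=10, L_mm=0)
    g = VesselGeometry(Ro_um=540, H_um=90, L_mm=4)
    assert g.Ri_um == 450


def test_current_geometry_unloaded_state():
    g = VesselGeometry(Ro_um=500, H_um=100, L_mm=4)
    ri, h = current_geometry(g, od_um=1000, lam_z=1.0)
    assert ri == pytest.approx(g.Ri_um, rel=1e-12)
    assert h == pytest.approx(g.H_um, rel=1e-12)


def test_current_geometry_stretched():
    g = VesselGeometry(Ro_um=500, H_um=100, L_mm=4)
    ri, h = current_geometry(g, od_um=1100, lam_z=1.5)
    assert ri == pytest.approx(np.sqrt(302500 - 60000), rel=1e-9)  # 492.44 um


def test_current_geometry_conserves_wall_volume():
    g = VesselGeometry(Ro_um=540, H_um=90, L_mm=4)
    for od, lam_z in [(1200, 1.3), (1500, 1.7), (1100, 1.9)]:
        ri, h = current_geometry(g, od, lam_z)
        v_loaded = ((ri + h) ** 2 - ri**2) * lam_z * g.L_mm
        v_unloaded = (g.Ro_um**2 - g.Ri_um**2) * g.L_mm
        assert v_loaded == pytest.approx(v_unloaded, rel=1e-9)


def test_current_geometry_flags_inconsistent_diameter():
    g = VesselGeometry(Ro_um=500, H_um=100, L_mm=4)
    with pytest.raises(InconsistentMeasurementError):
        current_geometry(g, od_um=200, lam_z=1.0)


def test_current_geometry_inverts_forward_geometry():
    """Reduction recovers the simulator's loaded geometry exactly (no noise)."""
    g = DEFAULT_GEOMETRY
    for lt, lz in [(1.3, 1.5), (1.6, 1.75), (1.1, 1.9)]:
        ri_f, h_f = loaded_geometry(g, lt, lz)
        ri_b, h_b = current_geometry(g, 2 * (ri_f + h_f), lz)
        assert ri_b == pytest.approx(ri_f, rel=1e-12)
        assert h_b == pytest.approx(h_f, rel=1e-12)


def test_unit_conversions_round_trip():
    assert 100.0 * MMHG_TO_KPA / MMHG_TO_KPA == pytest.approx(100.0, rel=1e-12)
    assert 2.5 * GF_TO_MN / GF_TO_MN == pytest.approx(2.5, rel=1e-12)
    assert 1.0 * MMHG_TO_KPA == pytest.approx(0.1333224)
    assert 1.0 * GF_TO_MN == pytest.approx(9.80665)


def test_wall_stress_zero_load():
    assert experimental_wall_stress(0, 0, 600, 40) == (0, 0)


def test_wall_stress_hoop_value():
    st, _ = experimental_wall_stress(100.0, 0.0, 600.0, 40.0)
    assert st == pytest.approx(13.33224 * 15, rel=1e-6)  # 199.98 kPa


def test_wall_stress_axial_value():
    _, sz = experimental_wall_stress(100.0, 1.0, 600.0, 40.0)
    P_kPa = 100 * MMHG_TO_KPA
    f_mN = GF_TO_MN
    expected = (f_mN + P_kPa * np.pi * 0.6**2) / (np.pi * 0.04 * (2 * 0.6 + 0.04))
    assert sz == pytest.approx(expected, rel=1e-9)
    assert sz == pytest.approx(159.7, abs=0.3)


def _fl_record(slopes, stretches):
    """Record whose f-vs-P least-squares slopes at each stretch are prescribed."""
    geom = VesselGeometry(Ro_um=540, H_um=90, L_mm=4)
    pts = []
    for slope, lam_z in zip(slopes, stretches):
        for P in (10.0, 60.0, 100.0, 140.0):
            pts.append(
                BiaxialDataPoint(
                    pressure_mmHg=P,
                    outer_diameter_um=1200.0,
                    axial_length_mm=lam_z * 4.0,
                    axial_force_g=1.0 + slope * P,
                    protocol=f"fl_{int(P)}",
                    cycle=2,
                )
            )
    return SubjectRecord("s", "WT", 12, 22.0, geom, pts)


def test_invivo_stretch_exact_zero_slope_node():
    rec = _fl_record([-0.001, 0.0, 0.001], [1.4, 1.5, 1.6])
    assert estimate_invivo_stretch(rec) == pytest.approx(1.5)


def test_invivo_stretch_interpolates_crossing():
    rec = _fl_record([-0.002, -0.0005, 0.001], [1.4, 1.5, 1.6])
    # crossing between 1.5 and 1.6 at t = 0.0005/0.0015
    assert estimate_invivo_stretch(rec) == pytest.approx(1.5 + 0.1 / 3, rel=1e-6)


def test_invivo_stretch_no_crossover_error():
    rec = _fl_record([0.001, 0.0005, 0.0001], [1.4, 1.5, 1.6])
    with pytest.raises(NoCrossoverError):
        estimate_invivo_stretch(rec)


def test_invivo_stretch_recovers_simulator_truth(wt12_record, wt12_params, geometry):
    """Estimated stretch within 1% of a dense grid search over df/dP = 0."""
    from aortamech.simulate import find_force_invariant_stretch

    est = estimate_invivo_stretch(wt12_record)
    # brute-force oracle: fine grid, pointwise slopes, zero crossing
    truth = find_force_invariant_stretch(
        wt12_params, geometry, lam_z_range=(1.5, 2.0), n_grid=120
    )
    assert est == pytest.approx(truth, rel=0.01)


def test_reduce_record_matches_constitutive_stress(wt12_record, wt12_params):
    """Reduced experimental stresses reproduce the generating law (noise-free)."""
    from aortamech.mech import cauchy_stress, deformation_from_stretches

    df = reduce_record(wt12_record)
    assert len(df) >= 100
    for row in df.sample(25, random_state=0).itertuples():
        st_m, sz_m = cauchy_stress(
            wt12_params, deformation_from_stretches(row.lam_theta, row.lam_z)
        )
        assert row.sigma_theta_kPa == pytest.approx(st_m, rel=0.03)
        assert row.sigma_z_kPa == pytest.approx(sz_m, rel=0.03)


def test_reduce_record_keeps_last_cycle_and_drops_bad_rows(caplog):
    geom = VesselGeometry(Ro_um=540, H_um=90, L_mm=4)
    pts = [
        BiaxialDataPoint(50, 1200, 6.0, 1.0, "pd_iv", cycle=1),
        BiaxialDataPoint(60, 1210, 6.0, 1.0, "pd_iv", cycle=2),
        BiaxialDataPoint(70, 1220, 6.0, 1.0, "pd_iv", cycle=2),
        BiaxialDataPoint(300, 1230, 6.0, 1.0, "pd_iv", cycle=2),  # pressure out of band
    ]
    rec = SubjectRecord("s", "WT", 12, 22.0, geom, pts)
    df = reduce_record(rec)
    assert set(df.pressure_mmHg) == {60, 70}  # cycle 1 and bad row dropped


def test_csv_round_trip(tmp_path, wt12_record):
    write_metadata_csv(tmp_path / "cohort_metadata.csv", [wt12_record])
    write_sample_csv(tmp_path / "wt12.csv", wt12_record)
    meta = read_metadata_csv(tmp_path / "cohort_metadata.csv")
    back = read_sample_csv(tmp_path / "wt12.csv", meta.iloc[0])
    assert back.sample_id == wt12_record.sample_id
    assert back.geometry == wt12_record.geometry
    assert len(back.points) == len(wt12_record.points)
    p0, q0 = back.points[0], wt12_record.points[0]
    assert p0.pressure_mmHg == pytest.approx(q0.pressure_mmHg)
    assert p0.outer_diameter_um == pytest.approx(q0.outer_diameter_um)
    assert p0.protocol == q0.protocol
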