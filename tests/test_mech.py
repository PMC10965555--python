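"""Constitutive kernel: kinematics, energy, stress, and linearized stiffness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aortamech.mech import (
    DeformationState,
    FourFiberParams,
    cauchy_stress,
    deformation_from_stretches,
    material_stiffness,
    strain_energy,
)
from conftest import random_params

ISO_10 = FourFiberParams.from_eight(10.0, 0, 0, 0, 0, 0, 0, 45.0)

stretches = st.floats(0.7, 1.9)
angles = st.floats(0.0, 90.0)


# --- kinematics -----------------------------------------------------------


@pytest.mark.parametrize(
    "lt, lz, lam_r, I_C",
    [
        (1.0, 1.0, 1.0, 3.0),
        (1.2, 1.5, 1 / 1.8, 1.44 + 2.25 + 0.308642),
        (2.0, 0.5, 1.0, None),
    ],
)
def test_deformation_kinematics(lt, lz, lam_r, I_C):
    s = deformation_from_stretches(lt, lz)
    assert s.lam_r == pytest.approx(lam_r, rel=1e-6)
    assert abs(np.linalg.det(s.F) - 1.0) < 1e-12
    if I_C is not None:
        assert s.I_C == pytest.approx(I_C, rel=1e-6)


def test_identity_invariants():
    s = deformation_from_stretches(1.0, 1.0)
    assert s.I_C == pytest.approx(3.0)
    assert np.allclose(s.fiber_invariants(ISO_10), 1.0)


@pytest.mark.parametrize("lt, lz", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -0.2)])
def test_non_positive_stretch_rejected(lt, lz):
    with pytest.raises(ValueError, match="lam_theta|lam_z"):
        deformation_from_stretches(lt, lz)


@given(lt=stretches, lz=stretches)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_incompressibility_holds(lt, lz):
    s = deformation_from_stretches(lt, lz)
    assert abs(np.linalg.det(s.F) - 1.0) < 1e-12
    assert np.all(s.fiber_invariants(ISO_10) >= 0)


# --- parameter validation --------------------------------------------------


def test_params_validation():
    with pytest.raises(ValueError):
        FourFiberParams.from_eight(-1, 0, 0, 0, 0, 0, 0, 45)
    with pytest.raises(ValueError):
        FourFiberParams.from_eight(1, -1, 0, 0, 0, 0, 0, 45)
    with pytest.raises(ValueError):
        FourFiberParams.from_eight(1, 0, 0, 0, 0, 0, 0, 120)
    with pytest.raises(ValueError, match="share"):
        FourFiberParams(c=1, c1=(0, 0, 1, 2), c2=(0, 0, 0, 0), alpha0=45)


# --- strain energy ---------------------------------------------------------


def test_energy_zero_at_identity(rng):
    s = deformation_from_stretches(1.0, 1.0)
    for _ in range(10):
        assert strain_energy(random_params(rng), s) == pytest.approx(0.0, abs=1e-14)


def test_energy_isotropic_value():
    s = deformation_from_stretches(1.2, 1.5)
    assert strain_energy(ISO_10, s) == pytest.approx(5 * 0.998642, rel=1e-5)


def test_energy_single_circumferential_family():
    p = FourFiberParams.from_eight(0, 0, 0, 1.0, 1.0, 0, 0, 45)
    s = deformation_from_stretches(1.1, 1.0)
    # IV = 1.21, W = 0.25 (e^0.0441 - 1)
    assert strain_energy(p, s) == pytest.approx(0.25 * math.expm1(0.21**2), rel=1e-10)
    assert strain_energy(p, s) == pytest.approx(0.011272, abs=1e-6)


def test_tiny_exponent_quadratic_limit():
    """c2 -> 0 reduces each family term to (c1/4)(IV-1)^2 without 0/0."""
    s = deformation_from_stretches(1.3, 1.1)
    p_zero = FourFiberParams.from_eight(0, 0, 0, 2.0, 0.0, 0, 0, 45)
    p_tiny = FourFiberParams.from_eight(0, 0, 0, 2.0, 2.32e-14, 0, 0, 45)
    x = s.fiber_invariants(p_zero)[1] - 1.0
    expected = 0.25 * 2.0 * x * x
    assert strain_energy(p_zero, s) == pytest.approx(expected, rel=1e-12)
    assert strain_energy(p_tiny, s) == pytest.approx(expected, rel=1e-9)
    assert np.isfinite(cauchy_stress(p_zero, s)).all()


@given(lt=stretches, lz=stretches, a0=angles)
@settings(max_examples=50, deadline=None, derandomize=True)
def test_energy_nonnegative(lt, lz, a0):
    p = FourFiberParams.from_eight(5.0, 3.0, 0.5, 4.0, 0.2, 6.0, 1.0, a0)
    assert strain_energy(p, deformation_from_stretches(lt, lz)) >= -1e-12


# --- Cauchy stress ---------------------------------------------------------


def test_stress_zero_at_identity(rng):
    s = deformation_from_stretches(1.0, 1.0)
    for _ in range(10):
        st_, sz = cauchy_stress(random_params(rng), s)
        assert st_ == pytest.approx(0.0, abs=1e-10)
        assert sz == pytest.approx(0.0, abs=1e-10)


def test_stress_isotropic_closed_form():
    s = deformation_from_stretches(1.2, 1.5)
    st_, sz = cauchy_stress(ISO_10, s)
    assert st_ == pytest.approx(10 * (1.44 - s.lam_r**2), abs=1e-10)
    assert sz == pytest.approx(10 * (2.25 - s.lam_r**2), abs=1e-10)
    assert st_ == pytest.approx(11.3136, abs=1e-4)
    assert sz == pytest.approx(19.4136, abs=1e-4)


def _fd_stress(params, lt, lz, h=1e-7):
    """Independent oracle: sigma_ii = lam_i dW^/dlam_i by central differences."""

    def W(a, b):
        return strain_energy(params, deformation_from_stretches(a, b))

    st_ = lt * (W(lt + h, lz) - W(lt - h, lz)) / (2 * h)
    sz = lz * (W(lt, lz + h) - W(lt, lz - h)) / (2 * h)
    return st_, sz


def test_stress_matches_energy_derivative_oracle(rng):
    """Stress equals the stretch-derivative of the energy on 100 random draws."""
    for _ in range(100):
        p = random_params(rng)
        lt, lz = rng.uniform(1.05, 1.7, 2)
        got = cauchy_stress(p, deformation_from_stretches(lt, lz))
        want = _fd_stress(p, lt, lz)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=1e-6, abs=1e-6)


def test_diagonal_mirror_symmetry(rng):
    """alpha0 -> -alpha0 leaves all outputs unchanged (families 3/4 swap)."""
    p = random_params(rng)
    s = deformation_from_stretches(1.3, 1.4)
    a = np.deg2rad([p.alpha0, -p.alpha0])
    assert np.allclose(np.sin(a) ** 2, np.sin(a[::-1]) ** 2)
    IV = s.fiber_invariants(p)
    assert IV[2] == pytest.approx(IV[3], rel=1e-14)


# --- material stiffness ----------------------------------------------------


def _fd_stiffness_from_stress(params, lt, lz, h=1e-6):
    """Route A: differentiate cauchy_stress under superposed biaxial strains."""

    def sig(a, b):
        return cauchy_stress(params, deformation_from_stretches(a, b))

    C_tttt = lt * (sig(lt + h, lz)[0] - sig(lt - h, lz)[0]) / (2 * h)
    C_zzzz = lz * (sig(lt, lz + h)[1] - sig(lt, lz - h)[1]) / (2 * h)
    C_ttzz = lz * (sig(lt, lz + h)[0] - sig(lt, lz - h)[0]) / (2 * h)
    return C_tttt, C_zzzz, C_ttzz


def _fd_stiffness_from_energy(params, lt, lz, du=1e-5):
    """Route B: assemble from second differences of the reduced energy in C."""
    u, v = lt * lt, lz * lz

    def W(uu, vv):
        return strain_energy(params, deformation_from_stretches(math.sqrt(uu), math.sqrt(vv)))

    Wuu = (W(u + du, v) - 2 * W(u, v) + W(u - du, v)) / du**2
    Wvv = (W(u, v + du) - 2 * W(u, v) + W(u, v - du)) / du**2
    Wuv = (W(u + du, v + du) - W(u + du, v - du) - W(u - du, v + du) + W(u - du, v - du)) / (
        4 * du * du
    )
    st_, sz = cauchy_stress(params, deformation_from_stretches(lt, lz))
    return 2 * st_ + 4 * u * u * Wuu, 2 * sz + 4 * v * v * Wvv, 4 * u * v * Wuv


def test_stiffness_matches_two_independent_oracles(rng):
    """Both finite-difference assemblies agree with the analytic components."""
    for _ in range(100):
        p = random_params(rng)
        lt, lz = rng.uniform(1.1, 1.6, 2)
        got = material_stiffness(p, deformation_from_stretches(lt, lz))
        rA = _fd_stiffness_from_stress(p, lt, lz)
        rB = _fd_stiffness_from_energy(p, lt, lz)
        scale = max(abs(g) for g in got) + 1.0
        for g, a, b in zip(got, rA, rB):
            assert abs(g - a) / scale < 1e-4
            assert abs(g - b) / scale < 1e-4


def test_stiffness_minor_symmetry(rng):
    """C_ttzz equals C_zztt: the coupling is symmetric in its index pairs."""
    for _ in range(20):
        p = random_params(rng)
        lt, lz = rng.uniform(1.05, 1.7, 2)
        # lam_z d sigma_t / d lam_z and lam_t d sigma_z / d lam_t are the two
        # orders of the mixed derivative; both must equal the returned coupling
        h = 1e-6

        def sig(a, b):
            return cauchy_stress(p, deformation_from_stretches(a, b))

        r1 = lz * (sig(lt, lz + h)[0] - sig(lt, lz - h)[0]) / (2 * h)
        r2 = lt * (sig(lt + h, lz)[1] - sig(lt - h, lz)[1]) / (2 * h)
        C_ttzz = material_stiffness(p, deformation_from_stretches(lt, lz))[2]
        assert r1 == pytest.approx(r2, rel=1e-4, abs=1e-4)
        assert C_ttzz == pytest.approx(r1, rel=1e-4, abs=1e-4)


def test_isotropic_stiffness_symmetry_at_identity():
    s = deformation_from_stretches(1.0, 1.0)
    Ct, Cz, _ = material_stiffness(ISO_10, s)
    assert Ct == pytest.approx(Cz, rel=1e-12)


def test_circumferential_stiffening_monotone():
    """A circumferential-family-dominated wall stiffens with hoop stretch."""
    p = FourFiberParams.from_eight(5.0, 0, 0, 20.0, 1.5, 0, 0, 45)
    grid = np.linspace(1.0, 1.8, 30)
    vals = [material_stiffness(p, deformation_from_stretches(lt, 1.4))[0] for lt in grid]
    assert np.all(np.diff(vals) >= 0)
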