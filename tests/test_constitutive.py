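"""GOH constitutive model: frozen oracles, limits, consistency, objectivity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reappose import (ConstitutiveError, DeformationState, GOHParameters,
                      biaxial_cauchy_stress, goh_energy,
                      plane_strain_stress_tangent)
from reappose.constitutive import pk1_stress_tangent, read_parameter_csv


def test_energy_zero_at_identity(all_params):
    for p in all_params.values():
        st_ = DeformationState.biaxial(p, 1.0, 1.0)
        assert goh_energy(p, st_) == pytest.approx(0.0, abs=1e-12)


def test_energy_nonnegative_all_rows(all_params):
    gen = np.random.default_rng(3)
    for p in all_params.values():
        for _ in range(20):
            lc, la = 1.0 + 0.3 * gen.random(2)
            assert goh_energy(p, DeformationState.biaxial(p, lc, la)) >= 0.0


def test_energy_value_frozen_oracle(flap_params):
    # high-precision arithmetic evaluation of the closed form, pig #1 mid flap
    p = flap_params["mid_1"]
    st_ = DeformationState.biaxial(p, 1.10, 1.05)
    assert goh_energy(p, st_) == pytest.approx(5881.0757043546347, rel=1e-12)


def test_biaxial_stress_frozen_oracle(flap_params):
    # central-difference-of-energy oracle (high-precision), pig #3 mid flap
    scc, saa = biaxial_cauchy_stress(flap_params["mid_3"], 1.15, 1.10)
    assert scc == pytest.approx(103839.89057352703, rel=1e-10)
    assert saa == pytest.approx(85490.544860470366, rel=1e-10)


def test_stress_free_reference(flap_params):
    scc, saa = biaxial_cauchy_stress(flap_params["mid_2"], 1.0, 1.0)
    assert scc == pytest.approx(0.0, abs=1e-9)
    assert saa == pytest.approx(0.0, abs=1e-9)


def test_equibiaxial_symmetry_at_45_degrees():
    p = GOHParameters(c10=5e4, k1=1e5, k2=3.0, alpha_deg=45.0, kappa=0.0,
                      thickness_mm=1.0)
    scc, saa = biaxial_cauchy_stress(p, 1.15, 1.15)
    assert scc == pytest.approx(saa, rel=1e-12)


def test_kappa_third_is_alpha_independent():
    """kappa = 1/3 makes the fiber term isotropic (depends only on I1)."""
    base = dict(c10=6e4, k1=2e5, k2=4.0, kappa=1.0 / 3.0, thickness_mm=1.0)
    vals = []
    for alpha in (0.0, 37.0, 90.0):
        p = GOHParameters(alpha_deg=alpha, **base)
        vals.append(goh_energy(p, DeformationState.biaxial(p, 1.2, 1.0)))
        vals.append(biaxial_cauchy_stress(p, 1.2, 1.07)[0])
    assert np.ptp(np.asarray(vals).reshape(3, 2), axis=0) == pytest.approx(
        [0.0, 0.0], abs=1e-7)


def test_kappa_zero_pure_fiber_limit():
    """kappa = 0: fiber strain reduces to I4 - 1 (no I1 contribution)."""
    p = GOHParameters(c10=6e4, k1=2e5, k2=4.0, alpha_deg=0.0, kappa=0.0,
                      thickness_mm=1.0)
    # stretching only axially leaves circumferential fibers unstretched:
    # the axial stress must be purely the matrix response
    iso = GOHParameters(c10=6e4, k1=0.0, k2=4.0, alpha_deg=0.0, kappa=0.0,
                        thickness_mm=1.0)
    st_a = biaxial_cauchy_stress(p, 1.0, 1.2)[1]
    st_b = biaxial_cauchy_stress(iso, 1.0, 1.2)[1]
    assert st_a == pytest.approx(st_b, rel=1e-12)


def test_tension_only_fiber_switch():
    """Compressed fibers (E <= 0) contribute nothing: matrix-only stress."""
    p = GOHParameters(c10=6e4, k1=5e5, k2=4.0, alpha_deg=0.0, kappa=0.0,
                      thickness_mm=1.0)
    mat = GOHParameters(c10=6e4, k1=0.0, k2=4.0, alpha_deg=0.0, kappa=0.0,
                        thickness_mm=1.0)
    # circumferential compression, axial extension: I4 < 1 at the fibers
    s_p = biaxial_cauchy_stress(p, 0.98, 1.25)
    s_m = biaxial_cauchy_stress(mat, 0.98, 1.25)
    assert s_p == pytest.approx(s_m, rel=1e-12)


@pytest.mark.parametrize("label", ["mid_1", "mid_5", "distal_2", "distal_4"])
def test_stress_energy_consistency(all_params, label):
    """Analytic biaxial stresses match numeric differentiation of Psi."""
    p = all_params[label]
    gen = np.random.default_rng(11)
    h = 1e-6
    for _ in range(25):
        lc, la = 1.0 + 0.25 * gen.random(2)
        def psi(a, b):
            return goh_energy(p, DeformationState.biaxial(p, a, b))
        scc_fd = lc * (psi(lc + h, la) - psi(lc - h, la)) / (2 * h)
        saa_fd = la * (psi(lc, la + h) - psi(lc, la - h)) / (2 * h)
        scc, saa = biaxial_cauchy_stress(p, lc, la)
        assert scc == pytest.approx(scc_fd, rel=2e-5, abs=1e-3)
        assert saa == pytest.approx(saa_fd, rel=2e-5, abs=1e-3)


def test_plane_strain_identity_and_rotation(flap_params):
    p = flap_params["mid_1"]
    kv = 1e4 * p.c10
    s, _ = plane_strain_stress_tangent(p, np.eye(2), kv)
    assert np.abs(s).max() == pytest.approx(0.0, abs=1e-8)
    th = np.deg2rad(30)
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    s, _ = plane_strain_stress_tangent(p, R, kv)
    assert np.abs(s).max() == pytest.approx(0.0, abs=1e-6)


def test_plane_strain_tangent_matches_finite_differences(flap_params):
    """Consistent tangent vs central differences of the PK1 stress."""
    p = flap_params["distal_1"]
    kv = 1e4 * p.c10
    gen = np.random.default_rng(0)
    circ = (0.6, 0.8)
    checked = 0
    while checked < 5:
        F = np.eye(2) + 0.08 * gen.standard_normal((2, 2))
        if np.linalg.det(F) < 0.9 or np.linalg.det(F) > 1.1:
            continue
        checked += 1
        P, A = pk1_stress_tangent(p, F, kv, circ_dir=circ)
        h = 1e-6
        for k in range(2):
            for l in range(2):
                Fp, Fm = F.copy(), F.copy()
                Fp[k, l] += h
                Fm[k, l] -= h
                fd = (pk1_stress_tangent(p, Fp, kv, circ_dir=circ)[0]
                      - pk1_stress_tangent(p, Fm, kv, circ_dir=circ)[0]) / (2 * h)
                assert np.abs(fd - A[:, :, k, l]).max() <= 1e-4 * np.abs(A).max()


def test_plane_strain_cauchy_symmetric(flap_params):
    p = flap_params["mid_4"]
    F = np.array([[1.05, 0.03], [-0.02, 0.98]])
    s, _ = plane_strain_stress_tangent(p, F, 1e4 * p.c10)
    assert s[0, 1] == pytest.approx(s[1, 0], rel=1e-12)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(th=st.floats(-np.pi, np.pi), lc=st.floats(1.0, 1.25),
       la=st.floats(1.0, 1.2))
def test_objectivity_under_rotation(th, lc, la):
    """Energy density is invariant under superposed in-plane rigid rotation."""
    p = GOHParameters(c10=7e4, k1=2e5, k2=6.0, alpha_deg=40.0, kappa=0.15,
                      thickness_mm=1.0)
    from reappose.constitutive import _plane_strain_core
    F = np.diag([lc, la])
    R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    kv = 1e4 * p.c10
    s1, _ = plane_strain_stress_tangent(p, F, kv)
    s2, _ = plane_strain_stress_tangent(p, R @ F, kv)
    # Cauchy stress rotates with the body: R s1 R^T == s2
    assert np.allclose(R @ s1 @ R.T, s2, rtol=1e-9, atol=1e-6)


def test_parameter_validation_errors():
    with pytest.raises(ConstitutiveError, match="c10"):
        GOHParameters(c10=-1.0, k1=1.0, k2=1.0, alpha_deg=10, kappa=0.1,
                      thickness_mm=1.0)
    with pytest.raises(ConstitutiveError, match="kappa"):
        GOHParameters(c10=1.0, k1=1.0, k2=1.0, alpha_deg=10, kappa=0.5,
                      thickness_mm=1.0)
    with pytest.raises(ConstitutiveError):
        DeformationState.biaxial(
            GOHParameters(c10=1.0, k1=0.0, k2=1.0, alpha_deg=0, kappa=0.0,
                          thickness_mm=1.0), -1.0, 1.0)


def test_overflow_guard():
    from reappose import OverflowStateError
    p = GOHParameters(c10=1e4, k1=1e6, k2=50.0, alpha_deg=0.0, kappa=0.0,
                      thickness_mm=1.0)
    with pytest.raises(OverflowStateError):
        biaxial_cauchy_stress(p, 8.0, 1.0)


def test_parameter_csv_round_trip(tmp_path, flap_params):
    from reappose import write_parameter_csv
    path = tmp_path / "params.csv"
    rows = [flap_params["mid_1"], flap_params["distal_3"]]
    write_parameter_csv(path, rows)
    back = read_parameter_csv(path)
    for p in rows:
        q = back[p.label]
        assert q.c10 == p.c10 and q.kappa == p.kappa \
            and q.thickness_mm == p.thickness_mm
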