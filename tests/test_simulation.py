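"""Plane-strain contact solver: verification oracles and small invariants.

Heavy verification (thin-ring Laplace, closed-form ring expansion, full
re-apposition sweeps) lives in the acceptance tests; here the solver is
exercised on small, fast configurations.
"""

import numpy as np
import pytest

from reappose import (DissectionGeometry, ExpansionMember, FEModel,
                      GOHParameters, SolverOptions, biaxial_cauchy_stress,
                      build_cross_section, expand_member, pressurize,
                      radial_pressure_from_contact, run_reapposition)
from reappose.constitutive import MMHG_TO_PA, PA_TO_MMHG


@pytest.fixture(scope="module")
def ring_setup():
    mat = GOHParameters(c10=80e3, k1=200e3, k2=5.0, alpha_deg=30.0, kappa=0.2,
                        thickness_mm=0.5, label="ring")
    geo = DissectionGeometry.intact_ring(10.0, 0.5)
    mesh = build_cross_section(geo, h=0.5)
    return mat, geo, mesh


def test_zero_pressure_zero_displacement(ring_setup):
    mat, _, mesh = ring_setup
    st = pressurize(mesh, {"tl_wall": mat}, 0.0)
    assert np.abs(st.u).max() == 0.0


def test_ring_inflation_matches_laplace(ring_setup):
    """Thin ring t/R = 0.05 at 100 mmHg: mean hoop stress within 2 % of p r/t."""
    mat, _, mesh = ring_setup
    opt = SolverOptions(newton_tol=1e-8)
    st = pressurize(mesh, {"tl_wall": mat}, 100.0, opt)
    x = mesh.nodes + st.u.reshape(-1, 2)
    rho = np.hypot(*x.T)
    r_in, r_out = rho.min(), rho.max()
    lam = 0.5 * (r_in + r_out) / 10.25
    p = 100.0 * MMHG_TO_PA
    laplace = p * 0.5 * (r_in + r_out) / (r_out - r_in)
    model_sigma, _ = biaxial_cauchy_stress(mat, lam, 1.0)
    assert model_sigma == pytest.approx(laplace, rel=0.02)
    jlo, jhi = st.jbar_range()
    assert abs(jlo - 1.0) < 1e-3 and abs(jhi - 1.0) < 1e-3


def test_member_expansion_matches_ring_closed_form(ring_setup):
    """Rigid member expanding an unpressurized ring: average contact pressure
    equals the thin-wall hyperelastic pressure-radius relation within 3 %."""
    mat, _, mesh = ring_setup
    opt = SolverOptions(newton_tol=1e-7, member_step_mm=0.3)
    st = pressurize(mesh, {"tl_wall": mat}, 0.0, opt)
    res = expand_member(st, ExpansionMember(radius=9.0), options=opt,
                        target_radius=11.0)
    x = mesh.nodes + st.u.reshape(-1, 2)
    rho = np.hypot(*x.T)
    lam = 0.5 * (rho.min() + rho.max()) / 10.25
    sigma, _ = biaxial_cauchy_stress(mat, lam, 1.0)
    q_exact = sigma * 0.5 / (lam**2 * 10.25) * PA_TO_MMHG  # sigma t /(lam^2 R)
    assert res.radial_pressure_mmhg == pytest.approx(q_exact, rel=0.03)


def test_energy_balance_ring(ring_setup):
    """External work equals stored strain + penalty energy within 1 % on the
    frictionless quasi-static path (pressurization + member expansion)."""
    mat, _, mesh = ring_setup
    # fine increments: the trapezoidal work integral is first order across
    # contact-force jumps at each member-radius increment
    opt = SolverOptions(newton_tol=1e-8, load_steps=10, member_step_mm=0.025)
    st = pressurize(mesh, {"tl_wall": mat}, 30.0, opt)
    expand_member(st, ExpansionMember(radius=10.5), options=opt,
                  target_radius=11.8)
    w_ext = st.work_pressure + st.work_member
    stored = st.strain_energy() + st.penalty_energy()
    assert w_ext == pytest.approx(stored, rel=0.01)


def test_pressurize_rejects_negative_pressure(ring_setup):
    mat, _, mesh = ring_setup
    with pytest.raises(ValueError):
        pressurize(mesh, {"tl_wall": mat}, -5.0)


def test_contact_average_trivial_cases(ring_setup):
    """Uniform field averages to itself; half-coverage at equal weights to q/2."""
    mat, _, mesh = ring_setup
    model = FEModel(mesh, {"tl_wall": mat})
    st = pressurize(mesh, {"tl_wall": mat}, 0.0, model=model)
    mem = ExpansionMember(radius=5.0)
    n = 10
    q0 = 2000.0  # Pa

    def fake_contact(u, member, frozen=None):
        info = dict(nodes=np.arange(n), pressure=np.full(n, q0),
                    trib=np.ones(n), energy=0.0, frozen=None)
        return np.zeros(model.ndof), (np.empty(0, int), np.empty(0, int),
                                      np.empty(0)), info

    model.member_contact = fake_contact
    st.member = mem
    assert radial_pressure_from_contact(st, mem) == pytest.approx(
        q0 * PA_TO_MMHG, rel=1e-12)

    half = np.concatenate([np.full(n // 2, q0), np.zeros(n // 2)])

    def fake_half(u, member, frozen=None):
        info = dict(nodes=np.arange(n), pressure=half, trib=np.ones(n),
                    energy=0.0, frozen=None)
        return np.zeros(model.ndof), (np.empty(0, int), np.empty(0, int),
                                      np.empty(0)), info

    model.member_contact = fake_half
    # contacting-surface average counts only loaded nodes -> q0
    assert radial_pressure_from_contact(st, mem) == pytest.approx(
        q0 * PA_TO_MMHG, rel=1e-9)
    # full-perimeter average halves it (equal weights over the half model)
    got = radial_pressure_from_contact(st, mem, include_noncontacting=True)
    per = np.pi * mem.radius
    assert got == pytest.approx(q0 * (n // 2) / per * PA_TO_MMHG, rel=1e-9)


def test_contact_average_empty_set_errors(ring_setup):
    from reappose import SolverError
    mat, _, mesh = ring_setup
    st = pressurize(mesh, {"tl_wall": mat}, 0.0)
    with pytest.raises(SolverError, match="contact"):
        radial_pressure_from_contact(st, ExpansionMember(radius=1.0))


def test_apposed_flap_zero_radial_pressure(mid_geometry, flap_params,
                                           wall_params):
    """Unpressurized, zero-gap flap: nothing to re-appose, pressure ~ 0."""
    mats = {"flap": flap_params["mid_1"], "fl_wall": wall_params["mid_fl_wall"],
            "tl_wall": wall_params["tl_wall"]}
    res = run_reapposition(mid_geometry, mats, 0.0, h=0.6)
    assert res.radial_pressure_mmhg < 0.5
    assert res.contact_fraction_history[-1] >= 1.0 - 1e-6


def test_solver_options_validation():
    with pytest.raises(ValueError):
        SolverOptions(gap_tol_fraction=0.2)
    with pytest.raises(ValueError):
        SolverOptions(newton_tol=-1.0)


def test_determinism_ring_expansion(ring_setup):
    """Identical inputs give bit-identical results (no stochastic elements)."""
    mat, _, mesh = ring_setup
    opt = SolverOptions(newton_tol=1e-7)
    out = []
    for _ in range(2):
        st = pressurize(mesh, {"tl_wall": mat}, 30.0, opt)
        res = expand_member(st, ExpansionMember(radius=10.6), options=opt,
                            target_radius=11.8)
        out.append((res.radial_pressure_mmhg, res.final_inner_diameter_mm))
    assert out[0] == out[1]
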