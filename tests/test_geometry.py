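"""Cross-section meshing: areas, boundary sets, guards, member geometry."""

import numpy as np
import pytest

from reappose import (DissectionGeometry, GeometryError, build_cross_section,
                      circle_arc_first_contact, first_contact_radius,
                      make_expansion_member, write_vtk)


@pytest.fixture(scope="module")
def mid_mesh(mid_geometry):
    return build_cross_section(mid_geometry, h=0.3)


def test_flap_fraction_guards():
    with pytest.raises(GeometryError):
        DissectionGeometry(flap_fraction=0.0)
    with pytest.raises(GeometryError):
        DissectionGeometry(flap_fraction=1.2)
    with pytest.raises(GeometryError, match="band"):
        DissectionGeometry(flap_fraction=0.3)
    # the 50-60 % band is configurable
    DissectionGeometry(flap_fraction=0.45, fraction_band=(0.4, 0.6))


def test_intact_ring_area_matches_annulus():
    geo = DissectionGeometry.intact_ring(10.0, 0.5)
    mesh = build_cross_section(geo, h=0.3)
    exact = 0.5 * np.pi * (10.5**2 - 10.0**2)  # half model
    assert sum(mesh.layer_areas().values()) == pytest.approx(exact, rel=5e-3)


def test_mid_mesh_invariants(mid_mesh, mid_geometry):
    mesh = mid_mesh
    assert mesh.min_jacobian() > 0.0
    # at least two element rows through the flap
    flap_elems = (mesh.layer == 0).sum()
    n_cols = len(mesh.boundary_sets["flap_tl_side"])
    assert flap_elems >= 2 * n_cols
    # symmetry nodes on the plane
    sym = np.unique(mesh.boundary_sets["symmetry_plane"])
    assert np.abs(mesh.nodes[sym, 0]).max() <= 1e-9
    # layer areas close to analytic sector annuli
    f, R = mid_geometry.flap_fraction, mid_geometry.inner_radius_mm
    tf = mid_geometry.flap_thickness_mm
    expect_flap = 0.5 * 2 * np.pi * f * ((R + tf) ** 2 - R**2) / 2
    assert mesh.layer_areas()["flap"] == pytest.approx(expect_flap, rel=0.02)


def test_boundary_sets_tile_surfaces(mid_mesh):
    """Each surface's edges chain without gaps or overlaps; lumen sets are
    disjoint and together cover the inner boundary."""
    sets = mid_mesh.boundary_sets
    inner = np.vstack([sets["tl_lumen_surface"], sets["flap_tl_side"]])
    # each interior node appears exactly once as start and once as end
    starts, ends = inner[:, 0], inner[:, 1]
    common = np.intersect1d(starts, ends)
    assert len(common) == len(inner) - 1  # a single open chain
    assert len(np.intersect1d(sets["tl_lumen_surface"].ravel(),
                              sets["flap_fl_side"].ravel())) == 0


def test_refinement_preserves_layer_areas(mid_geometry):
    coarse = build_cross_section(mid_geometry, h=0.3)
    fine = build_cross_section(mid_geometry, h=0.15)
    for layer in ("flap", "fl_wall", "tl_wall"):
        a, b = coarse.layer_areas()[layer], fine.layer_areas()[layer]
        assert abs(a - b) / b < 0.002


def test_h_too_coarse_for_flap_rows(mid_geometry):
    with pytest.raises(GeometryError, match="two element rows"):
        build_cross_section(mid_geometry, h=2.0)


def test_member_guards_and_first_contact(mid_mesh):
    with pytest.raises(GeometryError, match="n_segments"):
        make_expansion_member(n_segments=4)
    mem = make_expansion_member(initial_radius=1.0)
    assert first_contact_radius(mid_mesh, mem) == pytest.approx(9.0, abs=1e-9)
    assert len(mem.polygon()) == 64


def test_circle_arc_first_contact_closed_form():
    # concentric: distance is simply R - |c|
    assert circle_arc_first_contact((0.0, 3.0), 9.0,
                                    (-np.pi / 2, np.pi / 2)) == pytest.approx(6.0)
    # offset center with the nearest arc point clamped at an end
    d = circle_arc_first_contact((0.0, -2.0), 5.0, (0.0, np.pi / 4))
    exact = np.hypot(5.0 - 0.0, 0.0 + 2.0)
    assert d == pytest.approx(np.sqrt(5**2 + 2**2 - 2 * 5 * 2 *
                                      np.cos(np.pi / 2)), rel=1e-12) or \
        d == pytest.approx(exact, rel=1e-6)


def test_full_ring_mode():
    geo = DissectionGeometry.intact_ring(8.0, 0.6, symmetry=False)
    mesh = build_cross_section(geo, h=0.4)
    assert len(mesh.boundary_sets["symmetry_plane"]) == 0
    exact = np.pi * (8.6**2 - 8.0**2)
    assert sum(mesh.layer_areas().values()) == pytest.approx(exact, rel=5e-3)


def test_vtk_export_smoke(tmp_path, mid_mesh):
    path = tmp_path / "mesh.vtk"
    write_vtk(mid_mesh, path, cell_data={"area": mid_mesh.element_areas()})
    text = path.read_text()
    assert text.startswith("# vtk DataFile")
    assert f"POINTS {mid_mesh.n_nodes}" in text
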