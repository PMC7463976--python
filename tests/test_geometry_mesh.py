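"""Domain construction and mesh generation: tags, grading, quality."""

import numpy as np
import pytest

from neksim.geometry_mesh import (
    BoundaryTag,
    GeometryError,
    Mesh,
    build_domain,
    generate_mesh,
    mesh_quality,
    structured_rectangle_mesh,
)
from neksim.model_params import (
    ElectrolyteParams,
    SimulationGeometry,
    baseline_parameters,
    debye_length,
    numerics_profile,
)


@pytest.fixture(scope="module")
def coarse():
    return baseline_parameters(numerics=numerics_profile("coarse"))


@pytest.fixture(scope="module")
def coarse_mesh(coarse):
    dom = build_domain(coarse.geometry)   # y_p = -300 bp
    return dom, generate_mesh(dom, coarse.numerics, coarse.electrolyte)


class TestDomain:
    def test_boundary_groups_include_all_seven_tags(self, coarse):
        dom = build_domain(coarse.geometry)
        assert set(dom.boundary_groups()) == set(BoundaryTag)
        assert len(dom.boundary_groups()) == 7

    def test_particle_fully_in_lower_reservoir_at_start(self, coarse):
        g = coarse.geometry
        assert g.y_p + g.L_p / 2 < -g.h / 2   # entirely below the membrane

    def test_symmetric_domain_at_pore_centre(self, coarse):
        dom = build_domain(coarse.geometry.with_position_bp(0.0))
        # signed distance symmetric under y -> -y
        r = np.linspace(0, dom.r_max, 25)
        y = np.linspace(-dom.y_top, dom.y_top, 51)
        R, Y = np.meshgrid(r, y)
        pts = np.column_stack([R.ravel(), Y.ravel()])
        mirrored = pts * np.array([1.0, -1.0])
        assert np.allclose(dom.sdf(pts), dom.sdf(mirrored), atol=1e-15)

    def test_particle_beyond_reservoir_is_geometry_error(self, coarse):
        with pytest.raises(GeometryError, match="beyond the reservoir"):
            build_domain(coarse.geometry.with_position_bp(-1100.0))

    def test_off_axis_particle_rejected(self, coarse):
        import dataclasses

        geom = dataclasses.replace(coarse.geometry, x_p=1e-9)
        with pytest.raises(GeometryError, match="on-axis"):
            build_domain(geom)

    def test_unknown_mode_rejected(self, coarse):
        with pytest.raises(GeometryError, match="mode"):
            build_domain(coarse.geometry, mode="3d")


class TestMeshGeneration:
    def test_coarse_profile_smoke(self, coarse_mesh):
        _, mesh = coarse_mesh
        q = mesh_quality(mesh)
        assert q.n_triangles >= 2000
        assert q.min_angle_deg > 15.0
        assert q.n_bl_violations == 0
        # exactly the six geometric boundary groups are present
        present = {BoundaryTag(t) for t in np.unique(mesh.edge_tags)}
        assert present == {
            BoundaryTag.TOP_WALL, BoundaryTag.BOTTOM_WALL,
            BoundaryTag.SIDE_BOUNDARY, BoundaryTag.MEMBRANE_WALL,
            BoundaryTag.PARTICLE_SURFACE, BoundaryTag.AXIS,
        }
        # the OPEN_EDGE group is the union of the driven walls
        assert len(mesh.edge_ids(BoundaryTag.OPEN_EDGE)) == len(
            mesh.edge_ids(BoundaryTag.TOP_WALL)
        ) + len(mesh.edge_ids(BoundaryTag.BOTTOM_WALL))

    def test_meshed_area_matches_analytic(self, coarse_mesh):
        dom, mesh = coarse_mesh
        assert mesh.area() == pytest.approx(dom.analytic_area(), rel=5e-3)

    def test_default_profile_reaches_production_resolution(self):
        ps = baseline_parameters(numerics=numerics_profile("default"))
        dom = build_domain(ps.geometry)
        mesh = generate_mesh(dom, ps.numerics, ps.electrolyte)
        q = mesh_quality(mesh)
        assert q.n_triangles >= 20000
        assert q.min_angle_deg > 15.0
        assert q.n_bl_violations == 0

    def test_boundary_layer_refinement_doubles_edge_count(self, coarse):
        import dataclasses

        elec = coarse.electrolyte
        lam = debye_length(elec)
        dom = build_domain(coarse.geometry)

        def band_edges(mesh):
            return int(mesh.edge_in_band.sum())

        m1 = generate_mesh(dom, coarse.numerics, elec)
        num_half = dataclasses.replace(coarse.numerics, bl_fraction=0.5)
        m2 = generate_mesh(dom, num_half, elec)
        ratio = band_edges(m2) / band_edges(m1)
        assert 1.4 < ratio < 4.0

    def test_determinism(self, coarse):
        dom = build_domain(coarse.geometry)
        m1 = generate_mesh(dom, coarse.numerics, coarse.electrolyte)
        m2 = generate_mesh(dom, coarse.numerics, coarse.electrolyte)
        assert np.array_equal(m1.points, m2.points)
        assert np.array_equal(m1.triangles, m2.triangles)

    def test_clearance_guard(self):
        # pore barely wider than the particle: below two boundary-layer elements
        geom = SimulationGeometry(b=2.3e-9, a=1e-9)
        ps = baseline_parameters(numerics=numerics_profile("coarse"))
        dom = build_domain(geom)
        with pytest.raises(GeometryError, match="clearance"):
            generate_mesh(dom, ps.numerics, ps.electrolyte)

    def test_particle_free_domain(self, coarse):
        dom = build_domain(coarse.geometry, include_particle=False)
        mesh = generate_mesh(dom, coarse.numerics, coarse.electrolyte)
        assert len(mesh.edge_ids(BoundaryTag.PARTICLE_SURFACE)) == 0
        assert mesh.area() == pytest.approx(dom.analytic_area(), rel=5e-3)


class TestMeshQuality:
    def test_handmade_sliver_flagged(self):
        # one very thin triangle: 5-ish degree minimum angle
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.04]])
        tris = np.array([[0, 1, 2]])
        edges = np.array([[0, 1], [1, 2], [2, 0]])
        mesh = Mesh(
            points=pts, triangles=tris, edges=edges,
            edge_tags=np.array([1, 4, 4]), mode="planar2d", domain=None,
            lambda_D=np.inf, bl_limit=np.inf,
            edge_in_band=np.zeros(3, dtype=bool), all_edges=edges,
        )
        q = mesh_quality(mesh)
        assert q.min_angle_deg < 15.0
        assert not q.passing

    def test_structured_mesh_tags(self):
        m = structured_rectangle_mesh(
            np.linspace(0, 1e-8, 4), np.linspace(0, 2e-8, 5)
        )
        assert set(np.unique(m.edge_tags)) == {
            int(BoundaryTag.AXIS), int(BoundaryTag.SIDE_BOUNDARY),
            int(BoundaryTag.TOP_WALL), int(BoundaryTag.BOTTOM_WALL),
        }
        assert m.area() == pytest.approx(1e-8 * 2e-8, rel=1e-12)

    def test_mirror_symmetry_of_tags_at_centre(self, coarse):
        """At y_p = 0 the mesh is statistically symmetric top/bottom."""
        dom = build_domain(coarse.geometry.with_position_bp(0.0))
        ps = baseline_parameters(numerics=numerics_profile("coarse"))
        mesh = generate_mesh(dom, ps.numerics, ps.electrolyte)
        n_top = len(mesh.edge_ids(BoundaryTag.TOP_WALL))
        n_bot = len(mesh.edge_ids(BoundaryTag.BOTTOM_WALL))
        assert abs(n_top - n_bot) <= max(3, 0.4 * max(n_top, n_bot))
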