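"""Poisson / Nernst-Planck solves against closed-form electrokinetics."""

import dataclasses
import math

import numpy as np
import pytest

from neksim._fem import FemContext
from neksim.analytic_benchmarks import grahame_zeta
from neksim.geometry_mesh import BoundaryTag, structured_rectangle_mesh
from neksim.model_params import (
    DriveParams,
    ElectrolyteParams,
    ParticleProps,
    SimulationGeometry,
    debye_length,
)
from neksim.pnp_solver import (
    NernstPlanckSystem,
    PoissonSystem,
    ResolutionError,
    solve_nernst_planck,
    solve_poisson,
    species_flux,
)


@pytest.fixture(scope="module")
def channel():
    """Empty straight channel (no particle, no membrane): x across, y along."""
    x = np.linspace(0.0, 50e-9, 6)
    y = np.linspace(-202.5e-9, 202.5e-9, 41)
    mesh = structured_rectangle_mesh(
        x, y, mode="planar2d",
        tag_left=BoundaryTag.AXIS, tag_right=BoundaryTag.SIDE_BOUNDARY,
        tag_bottom=BoundaryTag.BOTTOM_WALL, tag_top=BoundaryTag.TOP_WALL,
    )
    return mesh, FemContext(mesh)


class TestPoisson:
    def test_laplace_in_straight_channel_gives_uniform_field(self, channel):
        mesh, ctx = channel
        elec = ElectrolyteParams()
        geom = SimulationGeometry()
        drive = DriveParams.from_phi_0(0.405, geom)   # 1 MV/m over 405 nm
        phi = solve_poisson(mesh, elec, drive, ParticleProps(sigma_p=0.0), ctx=ctx)
        E = -ctx.p1_grad(phi) / 1e-9
        assert np.allclose(E[:, 0], 0.0, atol=1.0)
        assert np.allclose(np.abs(E[:, 1]), 1e6, rtol=1e-9)
        # Dirichlet values exact on the walls
        top = mesh.node_ids(BoundaryTag.TOP_WALL)
        bot = mesh.node_ids(BoundaryTag.BOTTOM_WALL)
        assert np.allclose(phi[top], 0.405, rtol=0, atol=1e-15)
        assert np.allclose(phi[bot], 0.0, atol=1e-15)

    def test_negative_surface_charge_gives_negative_wall_potential(self, edl_slab):
        mesh, ctx, phi_s, c_s, elec, sigma = edl_slab
        wall = mesh.points[:, 0] < 1e-15
        assert phi_s[wall].mean() < 0.0
        # decays away from the wall
        far = mesh.points[:, 0] > 10 * debye_length(elec)
        assert np.abs(phi_s[far]).max() < 1e-2 * np.abs(phi_s[wall]).max()

    def test_debye_huckel_profile_within_tolerance(self):
        """Linear-response slab: numerical wall layer matches zeta exp(-x/lam)."""
        elec = ElectrolyteParams()
        lam = debye_length(elec)
        from neksim.geometry_mesh import geometric_spacing

        sigma = -2e-3    # |zeta| ~ 8.7 mV: Debye-Hueckel regime
        x = geometric_spacing(0.0, 12 * lam, 70, lam / 15)
        mesh = structured_rectangle_mesh(
            x, np.linspace(0, 2e-9, 3), mode="planar2d",
            tag_left=BoundaryTag.PARTICLE_SURFACE, tag_right=BoundaryTag.TOP_WALL,
            tag_bottom=BoundaryTag.SIDE_BOUNDARY, tag_top=BoundaryTag.SIDE_BOUNDARY,
        )
        ctx = FemContext(mesh)
        psys = PoissonSystem(
            ctx, elec, DriveParams(0.0, 0.0, 1.0), ParticleProps(sigma_p=sigma)
        )
        npsys = NernstPlanckSystem(ctx, elec)
        c = np.ones((2, ctx.n_p1))
        phi = psys.drive_solution()
        for _ in range(120):
            phi = 0.5 * (psys.solve_scaled(c, phi_old=phi) + phi)
            c_new = npsys.solve_scaled(phi, None, 0.0)
            if np.abs(c_new - c).max() < 1e-12:
                break
            c = 0.5 * (c_new + c)
        zeta = grahame_zeta(sigma, elec)
        psi_exact = zeta * np.exp(-mesh.points[:, 0] / lam)
        err = np.abs(phi * elec.thermal_voltage - psi_exact).max() / abs(zeta)
        assert err < 0.01

    def test_grahame_wall_potential_within_3pc(self, edl_slab):
        mesh, ctx, phi_s, c_s, elec, sigma = edl_slab
        zeta = grahame_zeta(sigma, elec)
        wall = mesh.points[:, 0] < 1e-15
        num = phi_s[wall].mean() * elec.thermal_voltage
        assert num == pytest.approx(zeta, rel=0.03)


class TestNernstPlanck:
    def test_uniform_potential_gives_bulk_concentrations(self, channel):
        mesh, ctx = channel
        elec = ElectrolyteParams()
        c = solve_nernst_planck(mesh, np.zeros(ctx.n_p1), elec, ctx=ctx)
        assert np.allclose(c[0], 10.0, rtol=1e-12)
        assert np.allclose(c[1], 10.0, rtol=1e-12)

    def test_boltzmann_equilibrium_within_1pc(self, edl_slab):
        mesh, ctx, phi_s, c_s, elec, sigma = edl_slab
        for k, z in enumerate((1.0, -1.0)):
            boltz = np.exp(-z * phi_s)
            assert np.abs(c_s[k] - boltz).max() / boltz.max() < 0.01

    def test_polarity_reversal_swaps_species(self):
        """sigma, phi_0 -> -: (phi, c1, c2) -> (-phi, c2, c1) for equal D."""
        elec = dataclasses.replace(
            ElectrolyteParams(),
            species=(
                dataclasses.replace(ElectrolyteParams().species[0], D=2e-9),
                dataclasses.replace(ElectrolyteParams().species[1], D=2e-9),
            ),
        )
        lam = debye_length(elec)
        from neksim.geometry_mesh import geometric_spacing

        x = geometric_spacing(0.0, 10 * lam, 50, lam / 10)
        mesh = structured_rectangle_mesh(
            x, np.linspace(0, 2e-9, 3), mode="planar2d",
            tag_left=BoundaryTag.PARTICLE_SURFACE, tag_right=BoundaryTag.TOP_WALL,
            tag_bottom=BoundaryTag.SIDE_BOUNDARY, tag_top=BoundaryTag.SIDE_BOUNDARY,
        )
        ctx = FemContext(mesh)

        def equilibrate(sigma):
            psys = PoissonSystem(
                ctx, elec, DriveParams(0.0, 0.0, 1.0), ParticleProps(sigma_p=sigma)
            )
            npsys = NernstPlanckSystem(ctx, elec)
            c = np.ones((2, ctx.n_p1))
            phi = psys.drive_solution()
            for _ in range(100):
                phi = 0.5 * (psys.solve_scaled(c, phi_old=phi) + phi)
                c_new = npsys.solve_scaled(phi, None, 0.0)
                if np.abs(c_new - c).max() < 1e-13:
                    break
                c = 0.5 * (c_new + c)
            return phi, c

        phi_m, c_m = equilibrate(-0.005)
        phi_p, c_p = equilibrate(+0.005)
        assert np.allclose(phi_p, -phi_m, atol=1e-8)
        assert np.allclose(c_p[0], c_m[1], atol=1e-8)
        assert np.allclose(c_p[1], c_m[0], atol=1e-8)

    def test_negative_concentration_guard(self):
        elec = ElectrolyteParams()
        ctx = FemContext(
            structured_rectangle_mesh(np.linspace(0, 1e-8, 3), np.linspace(0, 1e-8, 3))
        )
        sys_ = NernstPlanckSystem(ctx, elec)
        bad = np.full((2, ctx.n_p1), 1.0)
        bad[0, 0] = -1e-3
        with pytest.raises(ResolutionError, match="undershoot"):
            sys_.check_positive(bad)


class TestSpeciesFlux:
    def test_no_driving_terms_no_flux(self, channel):
        mesh, ctx = channel
        elec = ElectrolyteParams()
        c = np.full((2, ctx.n_p1), 10.0)
        N = species_flux(mesh, np.zeros(ctx.n_p1), c, elec, ctx=ctx)
        assert np.abs(N).max() < 1e-20

    def test_pure_migration_term_exact(self, channel):
        mesh, ctx = channel
        elec = ElectrolyteParams()
        # linear potential: uniform grad phi along y
        grad = 1e6                      # V/m
        phi = grad * mesh.points[:, 1]
        c = np.full((2, ctx.n_p1), 10.0)
        N = species_flux(mesh, phi, c, elec, ctx=ctx)
        for k, s in enumerate(elec.species):
            expected = -(s.z * s.D * elec.F / (elec.R * elec.T)) * 10.0 * grad
            assert np.allclose(N[k][:, 1], expected, rtol=1e-10)
            assert np.allclose(N[k][:, 0], 0.0, atol=abs(expected) * 1e-10)

    def test_equilibrium_flux_cancellation(self, edl_slab):
        mesh, ctx, phi_s, c_s, elec, sigma = edl_slab
        phi = phi_s * elec.thermal_voltage
        c = c_s * 10.0
        N = species_flux(mesh, phi, c, elec, ctx=ctx)
        grad_phi = ctx.p1_grad(phi) / 1e-9
        drift = (
            elec.species[0].D * elec.F / (elec.R * elec.T)
            * np.abs(c).max() * np.abs(grad_phi).max()
        )
        assert np.abs(N).max() / drift < 1e-2


class TestConservation:
    def test_global_species_balance_at_steady_state(self, sol_baseline):
        """Total Dirichlet-wall influx equals outflux per species."""
        sol = sol_baseline
        npsys = sol.nernst_planck
        top = npsys.wall_outflux_scaled(sol.c_s, BoundaryTag.TOP_WALL)
        bot = npsys.wall_outflux_scaled(sol.c_s, BoundaryTag.BOTTOM_WALL)
        for k in range(2):
            scale = max(abs(top[k]), abs(bot[k]))
            assert abs(top[k] + bot[k]) / scale < 1e-6
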