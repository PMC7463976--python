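"""Shared fixtures: oracle configurations and the expensive trajectory sweeps.

The sweep fixtures are session-scoped because several test modules (physics
invariants, monotonicity properties, acceptance checks) read the same
trajectories; each sweep takes a couple of minutes at the coarse profile.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pytest

from neksim import (
    baseline_parameters,
    numerics_profile,
    solve_steady,
    force_free_velocity,
    sweep_trajectory,
)
from neksim.geometry_mesh import (
    BoundaryTag,
    geometric_spacing,
    structured_rectangle_mesh,
)
from neksim._fem import FemContext
from neksim.model_params import (
    DriveParams,
    ElectrolyteParams,
    ParticleProps,
    Species,
    debye_length,
)
from neksim.pnp_solver import NernstPlanckSystem, PoissonSystem

logging.getLogger("neksim").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def coarse_params():
    return baseline_parameters(E_nom=2e6, numerics=numerics_profile("coarse"))


@pytest.fixture(scope="session")
def sol_baseline(coarse_params):
    """Coupled solve at the far-field start position, zero particle velocity."""
    return solve_steady(coarse_params, y_p=-300 * 0.34e-9)


@pytest.fixture(scope="session")
def ff_baseline(coarse_params):
    """Force-free state at the far-field start position (E = 2 MV/m)."""
    return force_free_velocity(coarse_params, y_p=-300 * 0.34e-9)


def _sweep(E_nom, L_bp, grid=None):
    params = baseline_parameters(
        E_nom=E_nom, L_p_bp=L_bp, numerics=numerics_profile("coarse")
    )
    return sweep_trajectory(params, grid_bp=grid)


@pytest.fixture(scope="session")
def sweep_e1():
    return _sweep(1e6, 200.0)


@pytest.fixture(scope="session")
def sweep_e2():
    return _sweep(2e6, 200.0)


@pytest.fixture(scope="session")
def sweep_e3():
    return _sweep(3e6, 200.0)


@pytest.fixture(scope="session")
def sweeps_by_E(sweep_e1, sweep_e2, sweep_e3):
    return {1: sweep_e1, 2: sweep_e2, 3: sweep_e3}


_L_GRID = np.concatenate([[-300.0], np.arange(-150.0, 151.0, 15.0)])


@pytest.fixture(scope="session")
def sweeps_by_L(sweep_e2):
    """Length study at 2 MV/m; the entry/pore region plus the far-field
    reference position (enough for peak-velocity and blockade-depth
    comparisons at a fraction of the full-sweep cost)."""
    out = {200: sweep_e2}
    for L in (50, 100, 150):
        out[L] = _sweep(2e6, float(L), grid=_L_GRID)
    return out


# ---------------------------------------------------------------------------
# closed-form benchmark configurations

@pytest.fixture(scope="session")
def edl_slab():
    """Equilibrium double layer next to a charged planar wall (1-D slab).

    Returns (mesh, ctx, phi_scaled, c_scaled, elec, sigma) at the baseline
    surface-charge density.
    """
    elec = ElectrolyteParams()
    lam = debye_length(elec)
    x = geometric_spacing(0.0, 12 * lam, 70, lam / 15)
    y = np.linspace(0.0, 2e-9, 3)
    mesh = structured_rectangle_mesh(
        x, y, mode="planar2d",
        tag_left=BoundaryTag.PARTICLE_SURFACE, tag_right=BoundaryTag.TOP_WALL,
        tag_bottom=BoundaryTag.SIDE_BOUNDARY, tag_top=BoundaryTag.SIDE_BOUNDARY,
    )
    ctx = FemContext(mesh)
    sigma = -0.01
    psys = PoissonSystem(
        ctx, elec, DriveParams(0.0, 0.0, 1.0), ParticleProps(sigma_p=sigma)
    )
    npsys = NernstPlanckSystem(ctx, elec)
    c = np.ones((2, ctx.n_p1))
    phi = psys.drive_solution()
    for _ in range(120):
        phi = 0.5 * (psys.solve_scaled(c, phi_old=phi) + phi)
        c_new = npsys.solve_scaled(phi, None, 0.0)
        dc = np.abs(c_new - c).max()
        c = 0.5 * (c_new + c)
        if dc < 1e-12:
            break
    return mesh, ctx, phi, c, elec, sigma


@pytest.fixture(scope="session")
def eof_slit():
    """Electroosmotic plug flow in a charged-wall slit (thin EDL).

    Returns (flow, ctx, elec, E, wall_gap, lam): converged planar EOF at
    1 MV/m with C0 = 100 mol/m^3 so that the double layer is thin compared
    with the 25 nm half-width.
    """
    from neksim.stokes_solver import StokesSystem, electric_body_force, solve_stokes
    from neksim._fem import USTAR

    C0 = 100.0
    elec = dataclasses.replace(
        ElectrolyteParams(),
        species=(Species(1.0, 1.95e-9, C0), Species(-1.0, 2.03e-9, C0)),
    )
    lam = debye_length(elec)
    Wh, Lc = 25e-9, 200e-9
    xs = (Wh - geometric_spacing(0.0, Wh, 40, lam / 8))[::-1].copy()
    ys = np.linspace(-Lc / 2, Lc / 2, 41)
    mesh = structured_rectangle_mesh(
        xs, ys, mode="planar2d",
        tag_left=BoundaryTag.AXIS, tag_right=BoundaryTag.PARTICLE_SURFACE,
        tag_bottom=BoundaryTag.BOTTOM_WALL, tag_top=BoundaryTag.TOP_WALL,
    )
    ctx = FemContext(mesh)
    E = 1e6
    psys = PoissonSystem(
        ctx, elec, DriveParams(E * Lc, E, Lc), ParticleProps(sigma_p=-0.01)
    )
    npsys = NernstPlanckSystem(ctx, elec)
    ssys = StokesSystem(ctx, elec)
    c = np.ones((2, ctx.n_p1))
    phi = psys.drive_solution()
    u = None
    flow = None
    for _ in range(80):
        phi = 0.5 * (psys.solve_scaled(c, phi_old=phi) + phi)
        c_new = npsys.solve_scaled(phi, u, 0.0)
        dc = np.abs(c_new - c).max()
        c = 0.5 * (c_new + c)
        f = electric_body_force(mesh, phi * elec.thermal_voltage, c * C0, elec, ctx=ctx)
        flow = solve_stokes(mesh, f, 0.0, elec, ctx=ctx, system=ssys)
        u = flow.u / USTAR
        if dc < 1e-9:
            break
    return flow, ctx, elec, E, Wh, lam
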