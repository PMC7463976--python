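"""Picard coupling of the Poisson, Nernst-Planck and Stokes solves.

One call to :func:`solve_steady` produces the self-consistent steady fields
at a single particle position and prescribed particle velocity.  The loop
follows the staggered order (1) Poisson with the current concentrations,
(2) Nernst-Planck with the current potential and flow, (3) electric body
force, (4) Stokes, each update under-relaxed by the factor ``omega``; it
stops when the largest relative L2 change of (phi, c_i, u) drops below the
Picard tolerance (default 0.005).

The Poisson step linearises the ionic screening response about the previous
potential (see :class:`~neksim.pnp_solver.PoissonSystem`), which keeps the
fixed point unchanged but makes the iteration a damped Newton scheme for
the equilibrium double layer -- without it the exponential Boltzmann
response makes the staggered loop diverge for surface potentials beyond a
few kT.  Sweeps warm-start each position from the previous converged
solution, interpolated onto the new mesh.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator

from ._fem import LSTAR, USTAR, FemContext
from .geometry_mesh import Mesh, build_domain, generate_mesh
from .model_params import ParameterSet
from .pnp_solver import (
    IonicField,
    NernstPlanckSystem,
    PoissonSystem,
    ionic_field,
)
from .stokes_solver import FlowField, StokesSystem, electric_body_force

__all__ = ["ConvergenceError", "FieldSolution", "solve_steady"]

log = logging.getLogger("neksim")


class ConvergenceError(RuntimeError):
    """The Picard loop exhausted its iteration budget."""

    def __init__(self, message: str, history: list[tuple[int, float]]):
        super().__init__(message)
        self.history = history


@dataclass
class FieldSolution:
    """Converged coupled state at one particle position and velocity.

    Scaled fields (thermal-voltage / C0 / mm-per-s units) are kept for
    warm starts and force evaluation; SI views are provided as properties.
    """

    params: ParameterSet
    mesh: Mesh
    ctx: FemContext
    poisson: PoissonSystem
    nernst_planck: NernstPlanckSystem
    stokes: StokesSystem
    phi_s: np.ndarray            # (N,) thermal-voltage units
    c_s: np.ndarray              # (ns, N) C0 units
    u_s: np.ndarray              # (2, n_p2) u* units
    p_s: np.ndarray              # (N,) mu u*/L* units
    f_qp_s: np.ndarray           # (M, nq, 2) scaled body force at qpoints
    particle_velocity: float     # m/s
    history: list[tuple[int, float]] = field(default_factory=list)
    converged: bool = False
    iterations: int = 0

    @property
    def y_p(self) -> float:
        return self.params.geometry.y_p

    @property
    def phi(self) -> np.ndarray:
        """Potential, volts, at P1 nodes."""
        return self.phi_s * self.params.electrolyte.thermal_voltage

    @property
    def c(self) -> np.ndarray:
        """Concentrations, mol/m^3, at P1 nodes."""
        return self.c_s * self.poisson.c0

    @property
    def u(self) -> np.ndarray:
        """Velocity, m/s, at P2 nodes."""
        return self.u_s * USTAR

    @property
    def p(self) -> np.ndarray:
        """Pressure, Pa, at P1 nodes."""
        e = self.params.electrolyte
        return self.p_s * (e.mu * USTAR / LSTAR)

    @property
    def flow(self) -> FlowField:
        return FlowField(
            u=self.u,
            p=self.p,
            particle_velocity=self.particle_velocity,
            divergence_norm=self.stokes.divergence_norm(self.u_s),
        )

    @property
    def ionic(self) -> IonicField:
        return ionic_field(
            self.mesh, self.phi, self.c, self.params.electrolyte,
            u=self.u, ctx=self.ctx,
        )


def _interp_to(
    old_points: np.ndarray, values: np.ndarray, new_points: np.ndarray,
    fill_nearest: bool = True,
) -> np.ndarray:
    """Linear interpolation of nodal data between meshes (nearest fallback)."""
    lin = LinearNDInterpolator(old_points, values)
    out = lin(new_points)
    bad = ~np.isfinite(out)
    if np.any(bad) and fill_nearest:
        near = NearestNDInterpolator(old_points, values)
        out[bad] = near(new_points[bad])
    return out


def _rel_change(new: np.ndarray, old: np.ndarray, floor: float = 1.0) -> float:
    num = np.linalg.norm(new - old)
    den = max(np.linalg.norm(old), floor * np.sqrt(max(old.size, 1)))
    return float(num / den)


def solve_steady(
    params: ParameterSet,
    y_p: float | None = None,
    particle_velocity: float = 0.0,
    initial_guess: FieldSolution | None = None,
    mode: str = "axisymmetric",
    mesh: Mesh | None = None,
) -> FieldSolution:
    """Self-consistent PNP-Stokes state at one position and particle velocity.

    ``y_p`` (metres, pore-centre origin) overrides the position stored in
    ``params``; ``initial_guess`` warm-starts the Picard loop from another
    converged solution (its fields are interpolated onto the new mesh).
    Raises :class:`ConvergenceError` when the iteration budget is exhausted.
    """
    if y_p is not None:
        params = params.at_position_bp(y_p / params.geometry.bp_length)
    num = params.numerics
    t0 = time.perf_counter()
    if mesh is None:
        domain = build_domain(params.geometry, mode)
        mesh = generate_mesh(domain, num, params.electrolyte)
    ctx = FemContext(mesh)
    psys = PoissonSystem(ctx, params.electrolyte, params.drive, params.particle)
    npsys = NernstPlanckSystem(ctx, params.electrolyte)
    ssys = StokesSystem(ctx, params.electrolyte)

    ns = len(params.electrolyte.species)
    if initial_guess is not None:
        op = initial_guess.mesh.points
        c = np.stack(
            [_interp_to(op, ci, mesh.points) for ci in initial_guess.c_s]
        )
        c = np.clip(c, 0.0, None)
        phi = _interp_to(op, initial_guess.phi_s, mesh.points)
    else:
        c = np.ones((ns, ctx.n_p1))
        phi = psys.drive_solution()
    u = None
    p = np.zeros(ctx.n_p1)
    f_qp = None
    U_s = particle_velocity / USTAR
    omega = num.omega
    history: list[tuple[int, float]] = []
    converged = False
    for it in range(1, num.picard_max_iter + 1):
        phi_new = psys.solve_scaled(c, phi_old=phi)
        phi_next = omega * phi_new + (1.0 - omega) * phi
        c_new = npsys.solve_scaled(phi_next, u, U_s)
        c_next = omega * c_new + (1.0 - omega) * c
        rho_qp = np.einsum(
            "s,smq->mq", psys.z, np.stack([ctx.p1_at_qp(ci) for ci in c_next])
        )
        grad_phi = ctx.p1_grad(phi_next)
        kf = (
            params.electrolyte.F * psys.c0 * psys.phi_star * LSTAR
            / (params.electrolyte.mu * USTAR)
        )
        f_qp = -kf * rho_qp[:, :, None] * grad_phi[:, None, :]
        u_new, p_new = ssys.solve_scaled(f_qp, U_s)
        if u is None:
            u_next, p_next = u_new, p_new
        else:
            u_next = omega * u_new + (1.0 - omega) * u
            p_next = omega * p_new + (1.0 - omega) * p
        res = max(
            _rel_change(phi_next, phi),
            max(_rel_change(c_next[k], c[k]) for k in range(ns)),
            _rel_change(u_next, u if u is not None else np.zeros_like(u_next)),
        )
        history.append((it, res))
        phi, c, u, p = phi_next, c_next, u_next, p_next
        if res < num.picard_tol:
            converged = True
            break
    # final Nernst-Planck solve at the converged potential/flow: the stored
    # concentrations are then the exact discrete solution of the stored
    # operators (consistent-flux readings conserve species exactly)
    c = npsys.solve_scaled(phi, u, U_s)
    npsys.check_positive(c)
    sol = FieldSolution(
        params=params, mesh=mesh, ctx=ctx,
        poisson=psys, nernst_planck=npsys, stokes=ssys,
        phi_s=phi, c_s=c, u_s=u, p_s=p, f_qp_s=f_qp,
        particle_velocity=particle_velocity,
        history=history, converged=converged, iterations=len(history),
    )
    log.info(
        '{"event": "solve_steady", "y_p_bp": %.2f, "U_p_mm_s": %.4f, '
        '"iterations": %d, "residual": %.3e, "elements": %d, "wall_s": %.2f}',
        params.geometry.y_p_bp, particle_velocity * 1e3,
        len(history), history[-1][1] if history else float("nan"),
        mesh.n_triangles, time.perf_counter() - t0,
    )
    if not converged:
        raise ConvergenceError(
            f"Picard loop did not reach tol {num.picard_tol} in "
            f"{num.picard_max_iter} iterations (last residual "
            f"{history[-1][1]:.3e})",
            history,
        )
    return sol
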