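"""Poisson and steady Nernst-Planck solves on a tagged mesh.

The electric potential obeys  -eps_f lap(phi) = F sum_i z_i c_i  with the
driven/grounded walls as Dirichlet boundaries, the particle surface charge
as a Neumann condition (-n.grad phi = sigma_p / eps_f with n the outward
particle normal) and insulation elsewhere.  Each ionic species obeys
div(N_i) = 0 with N_i = u c_i - D_i grad c_i - (z_i D_i F / RT) c_i grad phi,
bulk concentrations imposed on the driven walls, a purely convective normal
flux on the (rigidly moving) particle surface and zero normal flux on the
membrane.

Internally both solves are performed in thermal-voltage / bulk-concentration
units on the shared :class:`~neksim._fem.FemContext`; the advective velocity
seen by a species is  Pe u - z grad(phi~),  which is SUPG-stabilised where
element Peclet numbers approach unity.  The public functions accept and
return SI fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._fem import LSTAR, USTAR, FemContext, LinearSolver, apply_dirichlet
from .geometry_mesh import BoundaryTag, Mesh
from .model_params import DriveParams, ElectrolyteParams, ParticleProps

__all__ = [
    "SolverError",
    "ResolutionError",
    "IonicField",
    "PoissonSystem",
    "NernstPlanckSystem",
    "solve_poisson",
    "solve_nernst_planck",
    "species_flux",
]


class SolverError(RuntimeError):
    """A linear solve failed or produced a non-finite field."""


class ResolutionError(SolverError):
    """Concentrations undershot below tolerance; the boundary layer needs a
    finer mesh."""


@dataclass
class IonicField:
    """Converged electric/ionic state in SI units on mesh nodes/elements."""

    phi: np.ndarray          # (N,) V
    c: np.ndarray            # (ns, N) mol/m^3
    E: np.ndarray            # (M, 2) V/m, per element (-grad phi)
    flux: np.ndarray         # (ns, M, 2) mol/(m^2 s), per element

    def charge_density(self, elec: ElectrolyteParams) -> np.ndarray:
        """Nodal net charge density F sum z_i c_i, C/m^3."""
        z = np.array([s.z for s in elec.species])
        return elec.F * np.einsum("s,sn->n", z, self.c)


def _c0_ref(elec: ElectrolyteParams) -> float:
    return max(s.c0 for s in elec.species)


class PoissonSystem:
    """Scaled Poisson operator for one mesh; LU is reused across solves."""

    def __init__(
        self,
        ctx: FemContext,
        elec: ElectrolyteParams,
        drive: DriveParams,
        particle: ParticleProps,
    ):
        self.ctx = ctx
        self.elec = elec
        self.phi_star = elec.thermal_voltage
        self.c0 = _c0_ref(elec)
        self.alpha = (
            elec.F**2 * self.c0 * LSTAR**2 / (elec.eps_f * elec.R * elec.T)
        )
        self.z = np.array([s.z for s in elec.species])
        K = ctx.p1_stiffness()
        b = np.zeros(ctx.n_p1)
        # particle surface charge: load  sigma~ * int v r ds
        sigma_scaled = particle.sigma_p * LSTAR / (elec.eps_f * self.phi_star)
        ed = ctx.edge_data(BoundaryTag.PARTICLE_SURFACE)
        if len(ed.edges):
            b += ctx.edge_load_p1(ed, sigma_scaled)
        top = ctx.mesh.node_ids(BoundaryTag.TOP_WALL)
        bot = ctx.mesh.node_ids(BoundaryTag.BOTTOM_WALL)
        if top.size == 0 and bot.size == 0:
            raise SolverError(
                "no Dirichlet wall present: the Poisson system would be singular"
            )
        self._dir_nodes = np.concatenate([top, bot])
        self._dir_vals = np.concatenate(
            [np.full(top.size, drive.phi_0 / self.phi_star), np.zeros(bot.size)]
        )
        self._K = K
        self._b_neumann = b
        A, self._b0 = apply_dirichlet(K, b, self._dir_nodes, self._dir_vals)
        self._lu = LinearSolver(A)
        self._drive: np.ndarray | None = None

    def drive_solution(self) -> np.ndarray:
        """Charge-free, surface-charge-free potential (pure applied drive).

        Serves as the initial guess the screened fixed-point iteration
        linearises about; without it the first screened solve would collapse
        the applied field (screening about phi = 0) or, unscreened, blow up
        the double layer (no screening of sigma_p at all).
        """
        if self._drive is None:
            A, b = apply_dirichlet(
                self._K, np.zeros(self.ctx.n_p1), self._dir_nodes, self._dir_vals
            )
            self._drive = LinearSolver(A).solve(b)
        return self._drive

    def solve_scaled(
        self, c_scaled: np.ndarray, phi_old: np.ndarray | None = None
    ) -> np.ndarray:
        """Potential (thermal-voltage units) for concentrations in C0 units.

        With ``phi_old`` given, the Boltzmann response of the ions is
        linearised about the previous potential (screening term
        alpha sum z_i^2 c_i (phi - phi_old) added to both sides), which turns
        the outer fixed-point iteration into a damped Newton scheme for the
        equilibrium double layer; the fixed point itself is unchanged.
        """
        c_qp = np.stack([self.ctx.p1_at_qp(ci) for ci in c_scaled])
        rho_qp = np.einsum("s,smq->mq", self.z, c_qp)
        if phi_old is None:
            b = self._b0 + self._mask_dirichlet(self.ctx.p1_load(self.alpha * rho_qp))
            phi = self._lu.solve(b)
        else:
            scr_qp = self.alpha * np.einsum("s,smq->mq", self.z**2, c_qp)
            phi_old_qp = self.ctx.p1_at_qp(phi_old)
            A = self._K + self.ctx.p1_mass(scr_qp)
            rhs = self._b_neumann + self.ctx.p1_load(
                self.alpha * rho_qp + scr_qp * phi_old_qp
            )
            A, rhs = apply_dirichlet(A, rhs, self._dir_nodes, self._dir_vals)
            phi = LinearSolver(A).solve(rhs)
        if not np.all(np.isfinite(phi)):
            raise SolverError("Poisson solve produced non-finite potential")
        return phi

    def _mask_dirichlet(self, v: np.ndarray) -> np.ndarray:
        v = v.copy()
        v[self._dir_nodes] = 0.0
        return v


class NernstPlanckSystem:
    """Scaled steady Nernst-Planck solver (one linear solve per species)."""

    def __init__(self, ctx: FemContext, elec: ElectrolyteParams):
        self.ctx = ctx
        self.elec = elec
        self.c0 = _c0_ref(elec)
        self.species = elec.species
        self.Pe = np.array([USTAR * LSTAR / s.D for s in elec.species])
        top = ctx.mesh.node_ids(BoundaryTag.TOP_WALL)
        bot = ctx.mesh.node_ids(BoundaryTag.BOTTOM_WALL)
        self._dir_nodes = np.concatenate([top, bot])
        self._K = ctx.p1_stiffness()
        self._ed_particle = ctx.edge_data(BoundaryTag.PARTICLE_SURFACE)
        # raw operators of the last solve, for consistent boundary-flux readings
        self.last_raw: list[tuple[sp.csr_matrix, np.ndarray]] = []

    def solve_scaled(
        self,
        phi_scaled: np.ndarray,
        u_scaled: np.ndarray | None,
        particle_velocity_scaled: float,
    ) -> np.ndarray:
        """Concentrations (C0 units) given the scaled potential and velocity.

        ``u_scaled`` is the (2, n_p2) nodal P2 velocity in u* units or None
        for a quiescent fluid; ``particle_velocity_scaled`` is the rigid
        axial particle velocity entering the convective surface flux.
        """
        ctx = self.ctx
        grad_phi = ctx.p1_grad(phi_scaled)              # (M, 2)
        if u_scaled is not None:
            u_qp = np.stack(
                [ctx.p2_at_qp(u_scaled[0]), ctx.p2_at_qp(u_scaled[1])], axis=-1
            )                                           # (M, nq, 2)
        else:
            u_qp = np.zeros((ctx.t.shape[0], ctx.qp.shape[1], 2))
        h_e = 1.52 * np.sqrt(np.maximum(ctx.area, 1e-300))
        out = np.empty((len(self.species), ctx.n_p1))
        self.last_raw = []
        for k, spec_k in enumerate(self.species):
            # -int grad(v).N~ = (K + adv_T(b)) c  with  b = z grad(phi) - Pe u;
            # the drift velocity of the species is -b (SUPG is sign-agnostic)
            b_qp = spec_k.z * grad_phi[:, None, :] - self.Pe[k] * u_qp
            A = self._K + self._advection_T(b_qp)
            A = A + self._supg(b_qp, h_e)
            if len(self._ed_particle.edges):
                coeff = (
                    self.Pe[k]
                    * particle_velocity_scaled
                    * self._ed_particle.normals[:, 1:2]
                )
                A = A + self.ctx.edge_mass_p1(
                    self._ed_particle, np.broadcast_to(coeff, self._ed_particle.weights.shape)
                )
            b = np.zeros(ctx.n_p1)
            Abc, bbc = apply_dirichlet(A, b, self._dir_nodes, 1.0)
            c = LinearSolver(Abc).solve(bbc)
            if not np.all(np.isfinite(c)):
                raise SolverError("Nernst-Planck solve produced non-finite field")
            self.last_raw.append((A, b))
            out[k] = c
        return out

    def _advection_T(self, a_qp: np.ndarray) -> sp.csr_matrix:
        # int ((a . grad v) c) == transpose of the advection form
        return self.ctx.p1_advection(a_qp).T.tocsr()

    def _supg(self, a_qp: np.ndarray, h_e: np.ndarray) -> sp.csr_matrix:
        amag = np.linalg.norm(a_qp.mean(axis=1), axis=1)
        alpha = 0.5 * amag * h_e
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            xi = np.where(
                alpha > 1e-3, 1.0 / np.tanh(np.minimum(alpha, 50.0)) - 1.0 / np.maximum(alpha, 1e-300), alpha / 3.0
            )
            tau = np.where(amag > 1e-12, 0.5 * h_e * xi / np.maximum(amag, 1e-300), 0.0)
        return self.ctx.p1_supg(a_qp, tau)

    def check_positive(self, c_scaled: np.ndarray, tol_rel: float = 1e-6) -> None:
        if c_scaled.min() < -tol_rel:
            raise ResolutionError(
                f"concentration undershoot {c_scaled.min():.3e} (C0 units) exceeds "
                f"-{tol_rel:g}; refine the boundary-layer mesh"
            )

    def wall_outflux_scaled(self, c_scaled: np.ndarray, tag: BoundaryTag) -> np.ndarray:
        """Consistent species flux leaving the domain through a Dirichlet wall.

        Returns, per species, the scaled boundary integral of N_i . n_out
        over the wall, computed from the residual of the unconstrained
        operator (superconvergent flux recovery).
        """
        nodes = self.ctx.mesh.node_ids(tag)
        out = np.empty(len(self.last_raw))
        for k, (A, b) in enumerate(self.last_raw):
            res = A @ c_scaled[k] - b
            out[k] = -res[nodes].sum()
        return out


# ---------------------------------------------------------------------------
# SI-facing operation wrappers

def solve_poisson(
    mesh: Mesh,
    elec: ElectrolyteParams,
    drive: DriveParams,
    particle: ParticleProps,
    c: np.ndarray | None = None,
    ctx: FemContext | None = None,
) -> np.ndarray:
    """Potential phi (V) at mesh nodes for given nodal concentrations (SI).

    ``c`` has shape (n_species, n_nodes) in mol/m^3; omit it for an
    uncharged fluid (Laplace problem with the particle's surface charge).
    """
    ctx = ctx or FemContext(mesh)
    system = PoissonSystem(ctx, elec, drive, particle)
    if c is None:
        c_scaled = np.zeros((len(elec.species), ctx.n_p1))
    else:
        c_scaled = np.asarray(c, dtype=float) / system.c0
    return system.solve_scaled(c_scaled) * system.phi_star


def solve_nernst_planck(
    mesh: Mesh,
    phi: np.ndarray,
    elec: ElectrolyteParams,
    u: np.ndarray | None = None,
    particle_velocity: float = 0.0,
    ctx: FemContext | None = None,
) -> np.ndarray:
    """Steady species concentrations (mol/m^3) for a frozen potential/flow.

    ``u`` is an optional (2, n_p2) nodal P2 velocity field in m/s;
    ``particle_velocity`` the rigid axial particle speed (m/s).
    """
    ctx = ctx or FemContext(mesh)
    system = NernstPlanckSystem(ctx, elec)
    phi_scaled = np.asarray(phi, dtype=float) / elec.thermal_voltage
    u_scaled = None if u is None else np.asarray(u, dtype=float) / USTAR
    c_scaled = system.solve_scaled(phi_scaled, u_scaled, particle_velocity / USTAR)
    system.check_positive(c_scaled)
    return c_scaled * system.c0


def species_flux(
    mesh: Mesh,
    phi: np.ndarray,
    c: np.ndarray,
    elec: ElectrolyteParams,
    u: np.ndarray | None = None,
    ctx: FemContext | None = None,
) -> np.ndarray:
    """Element-averaged species fluxes N_i (mol m^-2 s^-1), shape (ns, M, 2).

    N_i = u c_i - D_i grad c_i - (z_i D_i F / RT) c_i grad phi.
    """
    ctx = ctx or FemContext(mesh)
    nsp = len(elec.species)
    out = np.empty((nsp, ctx.t.shape[0], 2))
    grad_phi = ctx.p1_grad(np.asarray(phi)) / LSTAR            # V/m
    if u is not None:
        u_qp = np.stack([ctx.p2_at_qp(u[0]), ctx.p2_at_qp(u[1])], axis=-1)
        u_el = np.einsum("q,mqd->md", ctx.qw, u_qp) / ctx.qw.sum()
    else:
        u_el = np.zeros((ctx.t.shape[0], 2))
    for k, s in enumerate(elec.species):
        ck = np.asarray(c[k])
        c_el = ck[ctx.t].mean(axis=1)
        grad_c = ctx.p1_grad(ck) / LSTAR
        mig = (s.z * s.D * elec.F / (elec.R * elec.T)) * c_el[:, None] * grad_phi
        out[k] = u_el * c_el[:, None] - s.D * grad_c - mig
    return out


def ionic_field(
    mesh: Mesh,
    phi: np.ndarray,
    c: np.ndarray,
    elec: ElectrolyteParams,
    u: np.ndarray | None = None,
    ctx: FemContext | None = None,
) -> IonicField:
    """Bundle nodal fields plus derived element fields into an IonicField."""
    ctx = ctx or FemContext(mesh)
    E = -ctx.p1_grad(np.asarray(phi)) / LSTAR
    flux = species_flux(mesh, phi, c, elec, u=u, ctx=ctx)
    return IonicField(phi=np.asarray(phi), c=np.asarray(c), E=E, flux=flux)
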