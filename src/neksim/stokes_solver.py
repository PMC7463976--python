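"""Creeping-flow (Stokes) solver with electric body force.

Inertia-free incompressible flow:  0 = div[-p I + mu (grad u + grad u^T)] + f
with  f = -F (z1 c1 + z2 c2) grad phi,  discretised with inf-sup stable
Taylor-Hood elements (P2 velocity, P1 pressure).  Boundary conditions:
no slip on the membrane, rigid translation (0, U_p) on the particle
surface, zero normal velocity with free tangential traction on the lateral
symmetry boundary and the axis, and open (zero total stress, p -> 0)
top/bottom reservoir edges, which is the natural condition of the
symmetric-gradient weak form.

In axisymmetric mode the weak form carries the 2 pi r Jacobian (the 2 pi is
attached at the SI conversion step), the azimuthal strain u_r / r and the
radial continuity term u_r / r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from ._fem import LSTAR, USTAR, FemContext, LinearSolver
from .geometry_mesh import BoundaryTag, Mesh
from .model_params import ElectrolyteParams

__all__ = [
    "FlowField",
    "StokesSystem",
    "electric_body_force",
    "solve_stokes",
]


@dataclass
class FlowField:
    """Velocity/pressure solution in SI units.

    ``u`` is (2, n_p2) on Taylor-Hood velocity nodes (vertices first, then
    edge midpoints); ``p`` is (n_p1,) on vertices; ``divergence_norm`` the
    relative L2 norm of the discrete divergence.
    """

    u: np.ndarray
    p: np.ndarray
    particle_velocity: float
    divergence_norm: float


def electric_body_force(
    mesh: Mesh,
    phi: np.ndarray,
    c: np.ndarray,
    elec: ElectrolyteParams,
    ctx: FemContext | None = None,
) -> np.ndarray:
    """Element-wise Coulomb body force f = -F (sum z_i c_i) grad phi, N/m^3."""
    ctx = ctx or FemContext(mesh)
    z = np.array([s.z for s in elec.species])
    rho_el = elec.F * np.einsum("s,ms->m", z, np.asarray(c)[:, ctx.t].mean(axis=2).T)
    grad_phi = ctx.p1_grad(np.asarray(phi)) / LSTAR
    return -rho_el[:, None] * grad_phi


class StokesSystem:
    """Taylor-Hood Stokes operator on one mesh; LU cached across solves.

    The matrix is independent of the body force and of the particle
    velocity (both enter the right-hand side), so one factorisation serves
    the whole Picard loop and every force-free velocity probe.
    """

    def __init__(self, ctx: FemContext, elec: ElectrolyteParams):
        self.ctx = ctx
        self.elec = elec
        n2, n1 = ctx.n_p2, ctx.n_p1
        self.n2, self.n1 = n2, n1
        A, D = self._assemble_blocks()
        self.A_raw = A            # (2 n2, 2 n2) viscous block, mu = 1
        self.D_raw = D            # (n1, 2 n2) continuity  int q div(u) r
        K = sp.bmat([[A, -D.T], [-D, None]], format="csr")
        ndof = 2 * n2 + n1
        # Dirichlet velocity nodes
        mem = ctx.p2_nodes_of(BoundaryTag.MEMBRANE_WALL)
        par = ctx.p2_nodes_of(BoundaryTag.PARTICLE_SURFACE)
        side = ctx.p2_nodes_of(BoundaryTag.SIDE_BOUNDARY)
        axis = ctx.p2_nodes_of(BoundaryTag.AXIS)
        ur_zero = np.unique(np.concatenate([mem, par, side, axis]))
        uy_zero = np.unique(np.concatenate([mem]))
        self._ur_fixed = ur_zero
        self._uy_zero = np.setdiff1d(uy_zero, par)
        self._uy_particle = par
        rows = np.concatenate(
            [ur_zero, n2 + self._uy_zero, n2 + par]
        )
        self._dir_rows = rows
        K = K.tolil()
        for r in rows:
            K.rows[r] = [r]
            K.data[r] = [1.0]
        self._lu = LinearSolver(K.tocsr())
        self._ndof = ndof

    # -- assembly ---------------------------------------------------------
    def _assemble_blocks(self) -> tuple[sp.csr_matrix, sp.csr_matrix]:
        ctx = self.ctx
        G = ctx.grad_p2                      # (M, nq, 6, 2)
        N = ctx.basis_p2                     # (nq, 6)
        w = ctx.area[:, None] * ctx.qw[None, :] * ctx.rw   # (M, nq)
        Gr, Gy = G[..., 0], G[..., 1]        # (M, nq, 6)
        axi = ctx.axisym
        if axi:
            inv_r = 1.0 / ctx.qp[:, :, 0]
            Nr = N[None, :, :] * inv_r[:, :, None]          # N_j / r
        Arr = np.einsum("mq,mqi,mqj->mij", w, 2 * Gr, Gr) + np.einsum(
            "mq,mqi,mqj->mij", w, Gy, Gy
        )
        Ayy = np.einsum("mq,mqi,mqj->mij", w, 2 * Gy, Gy) + np.einsum(
            "mq,mqi,mqj->mij", w, Gr, Gr
        )
        Ary = np.einsum("mq,mqi,mqj->mij", w, Gy, Gr)       # v=(Ni,0), u=(0,Nj)
        if axi:
            Arr += 2.0 * np.einsum("mq,mqi,mqj->mij", w, Nr, Nr)
        conn = ctx.conn_p2
        n2 = ctx.n_p2

        def scat(local, shape, rows_conn, cols_conn, roff, coff):
            nl_r, nl_c = local.shape[1], local.shape[2]
            rows = np.repeat(rows_conn, nl_c, axis=1).ravel() + roff
            cols = np.tile(cols_conn, (1, nl_r)).ravel() + coff
            return sp.coo_matrix((local.ravel(), (rows, cols)), shape=shape)

        A = (
            scat(Arr, (2 * n2, 2 * n2), conn, conn, 0, 0)
            + scat(Ayy, (2 * n2, 2 * n2), conn, conn, n2, n2)
            + scat(Ary, (2 * n2, 2 * n2), conn, conn, 0, n2)
            + scat(np.transpose(Ary, (0, 2, 1)), (2 * n2, 2 * n2), conn, conn, n2, 0)
        ).tocsr()
        # continuity: D[k, j] = int psi_k div(phi_j) r
        psi = ctx.basis_p1                   # (nq, 3)
        div_r = Gr.copy()
        if axi:
            div_r = div_r + Nr
        Dr = np.einsum("mq,qk,mqj->mkj", w, psi, div_r)
        Dy = np.einsum("mq,qk,mqj->mkj", w, psi, Gy)
        n1 = ctx.n_p1
        D = (
            scat(Dr, (n1, 2 * n2), ctx.t, conn, 0, 0)
            + scat(Dy, (n1, 2 * n2), ctx.t, conn, 0, n2)
        ).tocsr()
        return A, D

    # -- solving ----------------------------------------------------------
    def rhs_raw(self, f_qp_scaled: np.ndarray | None) -> np.ndarray:
        """Momentum load vector for a body force given at qpoints (M, nq, 2)."""
        ctx = self.ctx
        b = np.zeros(self._ndof)
        if f_qp_scaled is not None:
            w = ctx.area[:, None] * ctx.qw[None, :] * ctx.rw
            N = ctx.basis_p2
            lr = np.einsum("mq,mq,qj->mj", w, f_qp_scaled[..., 0], N)
            ly = np.einsum("mq,mq,qj->mj", w, f_qp_scaled[..., 1], N)
            np.add.at(b[: self.n2], ctx.conn_p2, lr)
            np.add.at(b[self.n2 : 2 * self.n2], ctx.conn_p2, ly)
        return b

    def solve_scaled(
        self, f_qp_scaled: np.ndarray | None, particle_velocity_scaled: float
    ) -> tuple[np.ndarray, np.ndarray]:
        b = self.rhs_raw(f_qp_scaled)
        b[self._dir_rows] = 0.0
        b[self.n2 + self._uy_particle] = particle_velocity_scaled
        x = self._lu.solve(b)
        if not np.all(np.isfinite(x)):
            raise RuntimeError("Stokes solve produced non-finite velocity block")
        u = np.vstack([x[: self.n2], x[self.n2 : 2 * self.n2]])
        p = x[2 * self.n2 :]
        return u, p

    def divergence_norm(self, u_scaled: np.ndarray) -> float:
        du = self.D_raw @ np.concatenate([u_scaled[0], u_scaled[1]])
        scale = max(np.abs(self.D_raw).max() * np.abs(u_scaled).max(), 1e-300)
        return float(np.linalg.norm(du) / (scale * np.sqrt(len(du))))

    def momentum_residual(
        self,
        u_scaled: np.ndarray,
        p_scaled: np.ndarray,
        f_qp_scaled: np.ndarray | None,
    ) -> np.ndarray:
        """Unconstrained momentum residual A u - D^T p - b (for reactions)."""
        uvec = np.concatenate([u_scaled[0], u_scaled[1]])
        return (
            self.A_raw @ uvec
            - self.D_raw.T @ p_scaled
            - self.rhs_raw(f_qp_scaled)[: 2 * self.n2]
        )


def solve_stokes(
    mesh: Mesh,
    f: np.ndarray | None,
    particle_velocity: float,
    elec: ElectrolyteParams,
    ctx: FemContext | None = None,
    system: StokesSystem | None = None,
) -> FlowField:
    """Stokes flow (SI) for an element-wise body force f (N/m^3, shape (M, 2)).

    ``particle_velocity`` is the rigid axial particle speed in m/s.
    """
    ctx = ctx or FemContext(mesh)
    system = system or StokesSystem(ctx, elec)
    f_qp = None
    if f is not None:
        scale = LSTAR**2 / (elec.mu * USTAR)
        f_el = np.asarray(f, dtype=float) * scale
        f_qp = np.repeat(f_el[:, None, :], ctx.qp.shape[1], axis=1)
    u_s, p_s = system.solve_scaled(f_qp, particle_velocity / USTAR)
    div = system.divergence_norm(u_s)
    return FlowField(
        u=u_s * USTAR,
        p=p_s * (elec.mu * USTAR / LSTAR),
        particle_velocity=particle_velocity,
        divergence_norm=div,
    )
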