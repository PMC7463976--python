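"""Forces on the particle, force-free velocity, and trajectory sweeps.

The electric force is the Maxwell stress  eps_p [E E - (E.E)/2 I]  and the
hydrodynamic force the total fluid stress  -p I + mu (grad u + grad u^T),
each integrated over the particle surface.  Both are evaluated through
variationally consistent functionals: the surface integral is rewritten,
via the divergence theorem with a test field that equals the unit axial
vector on the particle surface and vanishes on all other boundaries, as a
volume residual -- the standard consistent-flux (reaction) evaluation,
which converges faster than direct line integration of elementwise
stresses.

Because the particle is inertia-free (density-matched, vanishing Reynolds
number), its velocity at every instant is the velocity at which the net
axial force vanishes.  Trajectories are therefore computed as quasi-static
position sweeps: at each position the force-free velocity is found by
exploiting the linearity of Stokes flow (axial force is affine in the
particle velocity at frozen ionic fields), with outer re-coupling
iterations for the weak convective feedback, and the passage time is
recovered by quadrature of 1/U_p along the path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fem import LSTAR, USTAR
from .coupled_solver import ConvergenceError, FieldSolution, solve_steady
from .geometry_mesh import BoundaryTag, GeometryError, MeshingError
from .model_params import ParameterSet, ParticleProps
from .observables import current_deviation, ionic_current

__all__ = [
    "ForceBreakdown",
    "TrajectoryRecord",
    "electric_force",
    "hydrodynamic_force",
    "force_free_velocity",
    "sweep_trajectory",
    "find_extremum",
]

log = logging.getLogger("neksim")


@dataclass(frozen=True)
class ForceBreakdown:
    """Electric + hydrodynamic force on the particle, newtons.

    Components are (lateral, axial).  In axisymmetric mode the net lateral
    force on an on-axis body vanishes identically (the azimuthal integral
    of the rotating radial unit vector is zero), and is reported as 0.
    """

    electric: np.ndarray
    hydrodynamic: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.electric + self.hydrodynamic


def _particle_hat_p1(sol: FieldSolution) -> np.ndarray:
    w = np.zeros(sol.ctx.n_p1)
    w[sol.mesh.node_ids(BoundaryTag.PARTICLE_SURFACE)] = 1.0
    return w


def electric_force(
    sol: FieldSolution, particle: ParticleProps | None = None
) -> np.ndarray:
    """Maxwell-stress force on the particle, newtons, components (lat, axial).

    Uses the volume identity
    int_Gp (sE . n) w dG = -int_Omega [ (div sE) . w + sE : grad w ] dV
    with w the particle-surface hat field times a unit vector and
    div sE = (eps_p/eps_f) rho_e E.
    """
    particle = particle or sol.params.particle
    ctx = sol.ctx
    psys = sol.poisson
    w = _particle_hat_p1(sol)
    w_qp = ctx.p1_at_qp(w)                      # (M, nq)
    grad_w = ctx.p1_grad(w)                     # (M, 2)
    E = -ctx.p1_grad(sol.phi_s)                 # scaled field, (M, 2)
    E2 = np.einsum("md,md->m", E, E)
    rho_qp = np.einsum(
        "s,smq->mq", psys.z, np.stack([ctx.p1_at_qp(ci) for ci in sol.c_s])
    )
    wq = ctx.area[:, None] * ctx.qw[None, :] * ctx.rw    # (M, nq)
    # axial component
    sE_yy = E[:, 1] * E[:, 1] - 0.5 * E2
    sE_ry = E[:, 0] * E[:, 1]
    vol_y = np.einsum(
        "mq,mq->", wq, psys.alpha * rho_qp * E[:, 1][:, None] * w_qp
    )
    srf_y = np.einsum(
        "mq,m->", wq, sE_ry * grad_w[:, 0] + sE_yy * grad_w[:, 1]
    )
    scale = particle.eps_p * psys.phi_star**2
    if sol.mesh.mode == "axisymmetric":
        F_y = -2.0 * np.pi * scale * (vol_y + srf_y)
        return np.array([0.0, F_y])
    # planar2d meshes the right half of a mirror-symmetric slot: the net
    # lateral force on the (on-axis) particle vanishes identically, the
    # one-sided x-traction being balanced by its mirror image
    F_y = -scale * (vol_y + srf_y)
    return np.array([0.0, F_y])


def hydrodynamic_force(sol: FieldSolution) -> np.ndarray:
    """Total fluid-stress force on the particle, newtons, (lat, axial).

    Consistent reaction evaluation: the unconstrained Stokes momentum
    residual, summed over the particle velocity degrees of freedom, equals
    the surface integral of [-p I + mu (grad u + grad u^T)] . n.
    """
    ctx = sol.ctx
    elec = sol.params.electrolyte
    res = sol.stokes.momentum_residual(sol.u_s, sol.p_s, sol.f_qp_s)
    par = ctx.p2_nodes_of(BoundaryTag.PARTICLE_SURFACE)
    n2 = ctx.n_p2
    # the weak residual tests against the fluid-domain outward normal, which
    # is -n on the particle surface: negate to get the force on the particle
    F_scale = -elec.mu * USTAR * LSTAR
    F_y = res[n2 + par].sum() * F_scale
    if sol.mesh.mode == "axisymmetric":
        return np.array([0.0, 2.0 * np.pi * F_y])
    # half-domain planar mode: net lateral force is zero by mirror symmetry
    return np.array([0.0, F_y])


def particle_forces(sol: FieldSolution) -> ForceBreakdown:
    return ForceBreakdown(
        electric=electric_force(sol), hydrodynamic=hydrodynamic_force(sol)
    )


def _drag_coefficient(sol: FieldSolution) -> float:
    """Axial hydrodynamic force per unit particle velocity (N s/m, < 0).

    One extra Stokes solve with unit particle velocity and no body force on
    the already-factorised operator.
    """
    ctx = sol.ctx
    elec = sol.params.electrolyte
    u1, p1 = sol.stokes.solve_scaled(None, 1.0)
    res = sol.stokes.momentum_residual(u1, p1, None)
    par = ctx.p2_nodes_of(BoundaryTag.PARTICLE_SURFACE)
    F_y = -res[ctx.n_p2 + par].sum() * elec.mu * USTAR * LSTAR
    if sol.mesh.mode == "axisymmetric":
        F_y *= 2.0 * np.pi
    return F_y / USTAR


def force_free_velocity(
    params: ParameterSet,
    y_p: float | None = None,
    initial_guess: FieldSolution | None = None,
    U_init: float | None = None,
    mode: str = "axisymmetric",
    max_outer: int = 10,
) -> tuple[float, FieldSolution]:
    """Particle velocity at which the net axial force vanishes, plus fields.

    Solves the coupled state at a trial velocity, measures the axial force,
    and updates the velocity through the affine force-velocity relation of
    Stokes flow; the weak convective feedback of the velocity on the ionic
    fields is absorbed by re-coupling until the velocity is stationary to
    the configured relative tolerance.
    """
    U = float(U_init) if U_init is not None else 0.0
    tol = params.numerics.velocity_rel_tol
    sol = solve_steady(
        params, y_p=y_p, particle_velocity=U,
        initial_guess=initial_guess, mode=mode,
    )
    k = _drag_coefficient(sol)
    for outer in range(max_outer):
        forces = particle_forces(sol)
        F_tot = forces.total[1]
        dU = -F_tot / k
        U_new = U + dU
        scale = max(abs(U_new), abs(U), 1e-9)
        if abs(U_new - U) < tol * scale:
            U = U_new
            break
        U = U_new
        sol = solve_steady(
            params, y_p=y_p, particle_velocity=U,
            initial_guess=sol, mode=mode, mesh=sol.mesh,
        )
    else:
        raise ConvergenceError(
            f"force-free velocity did not settle in {max_outer} outer "
            f"iterations (last U_p = {U:.4e} m/s)",
            [(outer, abs(F_tot))],
        )
    # final state at the settled velocity on the same mesh
    sol = solve_steady(
        params, y_p=y_p, particle_velocity=U,
        initial_guess=sol, mode=mode, mesh=sol.mesh,
    )
    return U, sol


@dataclass
class TrajectoryRecord:
    """Per-position sweep table plus the metadata needed to re-run it."""

    table: pd.DataFrame          # columns: yp_bp, yp_m, Up_m_per_s, Up_mm_per_s,
    #                              I_A, I_star, t_s, converged
    metadata: dict = field(default_factory=dict)

    def converged_rows(self) -> pd.DataFrame:
        return self.table[self.table["converged"]]

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.metadata.items():
                fh.write(f"# {k}: {v}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectoryRecord":
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
        table = pd.read_csv(path, comment="#")
        return cls(table=table, metadata=meta)


def sweep_trajectory(
    params: ParameterSet,
    grid_bp: np.ndarray | list[float] | None = None,
    mode: str = "axisymmetric",
    current_plane: float = 0.0,
) -> TrajectoryRecord:
    """Force-free velocity, current and I* along a particle-position sweep.

    Positions are given in base pairs; each solve warm-starts from its
    predecessor.  Failing positions are flagged and skipped rather than
    aborting the sweep.  The base current I_0 is the reading at the first
    (far-field) position; time is reconstructed by trapezoidal quadrature
    of 1/U_p over positions with positive velocity.
    """
    g = params.numerics.grid_bp if grid_bp is None else grid_bp
    if g is None:
        g = default_grid_bp()
    grid = np.asarray(sorted(float(v) for v in g))
    rows = []
    prev: FieldSolution | None = None
    U_prev: float | None = None
    for y_bp in grid:
        try:
            U, sol = force_free_velocity(
                params, y_p=y_bp * params.geometry.bp_length,
                initial_guess=prev, U_init=U_prev, mode=mode,
            )
            reading = ionic_current(sol, y_S=_current_plane_for(sol, current_plane))
            rows.append(
                dict(yp_bp=y_bp, yp_m=y_bp * params.geometry.bp_length,
                     Up_m_per_s=U, Up_mm_per_s=U * 1e3,
                     I_A=reading.I, I_star=np.nan, t_s=np.nan, converged=True)
            )
            prev, U_prev = sol, U
        except (ConvergenceError, GeometryError, MeshingError) as exc:
            log.warning("sweep position %.1f bp failed: %s", y_bp, exc)
            rows.append(
                dict(yp_bp=y_bp, yp_m=y_bp * params.geometry.bp_length,
                     Up_m_per_s=np.nan, Up_mm_per_s=np.nan,
                     I_A=np.nan, I_star=np.nan, t_s=np.nan, converged=False)
            )
    table = pd.DataFrame(rows)
    ok = table["converged"].to_numpy()
    if ok.any():
        I0 = table.loc[table.index[ok][0], "I_A"]
        table.loc[ok, "I_star"] = [
            current_deviation(I, I0) for I in table.loc[ok, "I_A"]
        ]
        table.loc[ok, "t_s"] = _reconstruct_time(
            table.loc[ok, "yp_m"].to_numpy(), table.loc[ok, "Up_m_per_s"].to_numpy()
        )
    e, geom, drive, part, num = params
    metadata = dict(
        E_nom_MV_per_m=drive.E_nom / 1e6,
        phi_0_V=drive.phi_0,
        L_p_bp=geom.L_p_bp,
        sigma_p_C_per_m2=part.sigma_p,
        C0_mol_per_m3=max(s.c0 for s in e.species),
        mode=mode,
        bl_fraction=num.bl_fraction,
        h_bulk_nm=num.h_bulk * 1e9,
        I0_A=table.loc[table.index[ok][0], "I_A"] if ok.any() else np.nan,
    )
    return TrajectoryRecord(table=table, metadata=metadata)


def default_grid_bp(
    span: float = 300.0, outer_step: float = 30.0,
    inner_span: float = 150.0, inner_step: float = 15.0,
) -> np.ndarray:
    """Sweep grid: coarse in the reservoirs, refined around the pore."""
    outer_lo = np.arange(-span, -inner_span, outer_step)
    inner = np.arange(-inner_span, inner_span + 1e-9, inner_step)
    outer_hi = np.arange(inner_span + outer_step, span + 1e-9, outer_step)
    return np.unique(np.concatenate([outer_lo, inner, outer_hi, [span, -span]]))


def _current_plane_for(sol: FieldSolution, preferred: float) -> float:
    """Move the reading plane off the particle if the particle straddles it."""
    g = sol.params.geometry
    lo = g.y_p - g.L_p / 2.0
    hi = g.y_p + g.L_p / 2.0
    margin = 2.0 * LSTAR
    if lo - margin < preferred < hi + margin:
        # keep inside the pore if possible, else just past the particle end
        cand = [hi + margin, lo - margin]
        for y in cand:
            if abs(y) < g.H:
                return y
    return preferred


def _reconstruct_time(y: np.ndarray, U: np.ndarray) -> np.ndarray:
    t = np.full(len(y), np.nan)
    if len(y) == 0 or U[0] <= 0:
        return t
    t[0] = 0.0
    for k in range(1, len(y)):
        if U[k] <= 0 or not np.isfinite(U[k]):
            break
        t[k] = t[k - 1] + (y[k] - y[k - 1]) * 0.5 * (1.0 / U[k] + 1.0 / U[k - 1])
    return t


@dataclass(frozen=True)
class Extremum:
    y_bp: float
    value: float
    kind: str
    bracketed: bool


def find_extremum(
    traj: TrajectoryRecord, quantity: str = "Up_mm_per_s", kind: str = "max"
) -> Extremum:
    """Discrete extremum refined by a quadratic fit through its neighbours.

    ``quantity`` is a column of the trajectory table ("Up_mm_per_s" or
    "I_star"); an extremum on the grid boundary is flagged unbracketed.
    """
    rows = traj.converged_rows()
    if len(rows) < 3:
        raise ValueError("need at least 3 converged rows to locate an extremum")
    y = rows["yp_bp"].to_numpy()
    v = rows[quantity].to_numpy()
    idx = int(np.argmax(v) if kind == "max" else np.argmin(v))
    if idx == 0 or idx == len(v) - 1:
        return Extremum(y_bp=float(y[idx]), value=float(v[idx]),
                        kind=kind, bracketed=False)
    y3, v3 = y[idx - 1 : idx + 2], v[idx - 1 : idx + 2]
    denom = (y3[0] - y3[1]) * (y3[0] - y3[2]) * (y3[1] - y3[2])
    a = (
        y3[2] * (v3[1] - v3[0]) + y3[1] * (v3[0] - v3[2]) + y3[0] * (v3[2] - v3[1])
    ) / denom
    b = (
        y3[2] ** 2 * (v3[0] - v3[1])
        + y3[1] ** 2 * (v3[2] - v3[0])
        + y3[0] ** 2 * (v3[1] - v3[2])
    ) / denom
    if a == 0.0:
        return Extremum(float(y3[1]), float(v3[1]), kind, True)
    y_star = -b / (2 * a)
    c0 = v3[0] - a * y3[0] ** 2 - b * y3[0]
    v_star = a * y_star**2 + b * y_star + c0
    return Extremum(y_bp=float(y_star), value=float(v_star), kind=kind,
                    bracketed=True)
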