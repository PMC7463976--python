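"""Ionic current through a cross-section, base current, and the deviation I*.

The pore current is  I = int_S F (sum_i z_i N_i) . n dS  over a horizontal
cross-section (annular in axisymmetric mode), positive along +y.  Because
the species equations are solved to steady state, the reading is
independent of the cross-section up to discretisation error -- the
conservation check across planes is part of the test suite.  The reference
(base) current I_0 is taken with the particle at its far-field starting
position, 300 bp below the pore, and the dimensionless deviation is
I* = (I - I_0)/I_0: negative values are current blockade, positive values
current enhancement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._fem import LSTAR
from .geometry_mesh import BoundaryTag
from .model_params import ParameterSet

__all__ = [
    "CurrentReading",
    "ionic_current",
    "wall_current",
    "base_current",
    "current_deviation",
]


@dataclass(frozen=True)
class CurrentReading:
    """Current through one cross-section, with per-species contributions."""

    y_S: float                   # m
    I: float                     # A (axisym) or A/m (planar2d)
    I_species: np.ndarray        # per species

    def __post_init__(self):
        assert np.isclose(self.I, self.I_species.sum(), rtol=1e-12, atol=0.0)


def ionic_current(sol, y_S: float = 0.0) -> CurrentReading:
    """Current through the horizontal cross-section at height y_S (metres).

    The plane must not intersect the particle; in axisymmetric mode the
    integral runs over the fluid annulus/disc at that height with the
    2 pi r Jacobian.
    """
    g = sol.params.geometry
    if g.y_p - g.L_p / 2.0 < y_S < g.y_p + g.L_p / 2.0:
        raise ValueError(
            f"cross-section y_S = {y_S:g} m intersects the particle "
            f"(spanning {g.y_p - g.L_p / 2:g} .. {g.y_p + g.L_p / 2:g} m); "
            "choose a plane beyond the particle ends"
        )
    elec = sol.params.electrolyte
    ctx = sol.ctx
    pts = ctx.p * LSTAR                       # node coordinates, metres
    tri = ctx.t
    ys = pts[:, 1][tri]                       # (M, 3)
    lo, hi = ys.min(axis=1), ys.max(axis=1)
    cut = np.flatnonzero((lo < y_S) & (hi > y_S))
    if cut.size == 0:
        # plane coincides with a mesh line: nudge by a fraction of an element
        nudge = 1e-3 * float(np.median(hi - lo))
        y_S = y_S + nudge
        cut = np.flatnonzero((lo < y_S) & (hi > y_S))
    if cut.size == 0:
        raise ValueError(f"cross-section y_S = {y_S:g} m lies outside the mesh")

    z = np.array([s.z for s in elec.species])
    D = np.array([s.D for s in elec.species])
    mobility = D * z * elec.F / (elec.R * elec.T)
    I_sp = np.zeros(len(z))
    # 2-point Gauss on each intersection segment
    gp = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
    for m in cut:
        nodes = tri[m]
        P = pts[nodes]
        # segment endpoints: intersections of the triangle edges with y = y_S
        ends = []
        for i, j in ((0, 1), (1, 2), (2, 0)):
            ya, yb = P[i, 1], P[j, 1]
            if (ya - y_S) * (yb - y_S) < 0.0:
                t = (y_S - ya) / (yb - ya)
                ends.append(P[i] + t * (P[j] - P[i]))
            elif ya == y_S:
                ends.append(P[i])
        if len(ends) < 2:
            continue
        ends = np.array(ends[:2])
        x0, x1 = ends[0, 0], ends[1, 0]
        if x1 < x0:
            x0, x1 = x1, x0
        seg = x1 - x0
        if seg <= 0.0:
            continue
        # P1 data on this element
        grad = ctx.grad_p1[m] / LSTAR         # (3, 2), 1/m
        phi_n = sol.phi[nodes]
        gphi_y = (grad[:, 1] * phi_n).sum()
        for tq in gp:
            xq = x0 + tq * seg
            lam = _barycentric(P, np.array([xq, y_S]))
            w = seg * 0.5
            if sol.mesh.mode == "axisymmetric":
                w *= 2.0 * np.pi * xq
            uy = _p2_eval_uy(sol, m, lam)
            for k in range(len(z)):
                c_n = sol.c[k][nodes]
                c_q = (lam * c_n).sum()
                gc_y = (grad[:, 1] * c_n).sum()
                N_y = uy * c_q - D[k] * gc_y - mobility[k] * c_q * gphi_y
                I_sp[k] += w * elec.F * z[k] * N_y
    return CurrentReading(y_S=y_S, I=float(I_sp.sum()), I_species=I_sp)


def _barycentric(P: np.ndarray, x: np.ndarray) -> np.ndarray:
    T = np.column_stack([P[1] - P[0], P[2] - P[0]])
    ab = np.linalg.solve(T, x - P[0])
    return np.array([1.0 - ab.sum(), ab[0], ab[1]])


def _p2_eval_uy(sol, m: int, lam: np.ndarray) -> float:
    from ._fem import _p2_basis

    N = _p2_basis(lam[None, :])[0]
    conn = sol.ctx.conn_p2[m]
    return float((N * sol.u[1][conn]).sum())


def wall_current(sol, tag: BoundaryTag = BoundaryTag.TOP_WALL) -> float:
    """Current leaving the domain through a Dirichlet wall (amperes).

    Consistent-reaction evaluation from the Nernst-Planck residual;
    positive along +y at the top wall.  Used as the conservation partner of
    the cross-section integral.
    """
    elec = sol.params.electrolyte
    out = sol.nernst_planck.wall_outflux_scaled(sol.c_s, tag)
    z = np.array([s.z for s in elec.species])
    D = np.array([s.D for s in elec.species])
    c0 = sol.poisson.c0
    # scaled flux integral -> SI: N* = D_i c0 / L*, area L*^2 (times 2 pi)
    factor = elec.F * c0 * LSTAR * (2.0 * np.pi if sol.mesh.mode == "axisymmetric" else 1.0)
    sign = 1.0 if tag == BoundaryTag.TOP_WALL else -1.0
    return float(sign * factor * (z * D * out).sum())


def base_current(
    params: ParameterSet, mode: str = "axisymmetric", y_ref_bp: float = -300.0
) -> float:
    """Reference current I_0: particle at its far-field start (0, -300 bp).

    Runs the full force-free coupled solve at the reference position and
    reads the current at the pore midplane.
    """
    from .particle_dynamics import force_free_velocity

    _, sol = force_free_velocity(
        params, y_p=y_ref_bp * params.geometry.bp_length, mode=mode
    )
    return ionic_current(sol, y_S=0.0).I


def current_deviation(I: float, I_0: float) -> float:
    """Dimensionless deviation I* = (I - I_0)/I_0."""
    if I_0 == 0.0:
        raise ZeroDivisionError("base current I_0 is zero; I* undefined")
    return (I - I_0) / I_0
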