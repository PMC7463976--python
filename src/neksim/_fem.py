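"""Finite-element plumbing shared by the PNP and Stokes solvers.

Internal module.  Provides P1 (scalar) and P2 (velocity) Lagrange spaces on
the triangular meshes from :mod:`neksim.geometry_mesh`, a degree-4 triangle
quadrature, vectorised sparse assembly, boundary-edge quadrature with
outward normals, and Dirichlet elimination that retains the unconstrained
operator for consistent (reaction-based) flux and force evaluation.

All solver work happens in scaled units: lengths in units of L* = 1 nm,
potential in units of the thermal voltage RT/F, concentrations in units of
the reference bulk concentration, velocities in units of u* = 1 mm/s and
pressure in units of mu u*/L*.  The weight ``r`` (scaled radius) multiplies
every integral in axisymmetric mode; planar mode uses unit weight and the
meridian mesh doubles as the right half of a mirror-symmetric slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry_mesh import BoundaryTag, Mesh

#: internal length scale, metres (nanometre)
LSTAR = 1.0e-9
#: internal velocity scale, m/s (millimetre per second)
USTAR = 1.0e-3

# Dunavant degree-4 rule, 6 points, weights normalised to sum to 1
_QW = np.array([0.223381589678011] * 3 + [0.109951743655322] * 3)
_QBARY = np.array(
    [
        [0.108103018168070, 0.445948490915965, 0.445948490915965],
        [0.445948490915965, 0.108103018168070, 0.445948490915965],
        [0.445948490915965, 0.445948490915965, 0.108103018168070],
        [0.816847572980459, 0.091576213509771, 0.091576213509771],
        [0.091576213509771, 0.816847572980459, 0.091576213509771],
        [0.091576213509771, 0.091576213509771, 0.816847572980459],
    ]
)
_NQ = len(_QW)

# 2-point Gauss on edges (positions in [0,1])
_EDGE_QP = np.array([0.5 - 0.5 / np.sqrt(3.0), 0.5 + 0.5 / np.sqrt(3.0)])
_EDGE_QW = np.array([0.5, 0.5])


def _p2_basis(bary: np.ndarray) -> np.ndarray:
    """P2 basis values at barycentric points; node order (v0,v1,v2,m01,m12,m20)."""
    l1, l2, l3 = bary[:, 0], bary[:, 1], bary[:, 2]
    return np.column_stack(
        [
            l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
            4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1,
        ]
    )


@dataclass
class EdgeData:
    """Quadrature data for a set of boundary edges."""

    edges: np.ndarray        # (K, 2) node ids
    lengths: np.ndarray      # (K,) scaled lengths
    normals: np.ndarray      # (K, 2) outward (out of the fluid) unit normals
    qpoints: np.ndarray      # (K, 2, 2) scaled coordinates of edge Gauss points
    weights: np.ndarray      # (K, 2) quadrature weights incl. length and r-weight
    basis: np.ndarray        # (2, 2) P1 basis values at the two Gauss points


class FemContext:
    """Cached finite-element data for one mesh (scaled coordinates)."""

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        self.axisym = mesh.mode == "axisymmetric"
        self.p = mesh.points / LSTAR          # (N, 2) scaled
        self.t = mesh.triangles
        self.n_p1 = self.p.shape[0]
        d1 = self.p[self.t[:, 1]] - self.p[self.t[:, 0]]
        d2 = self.p[self.t[:, 2]] - self.p[self.t[:, 0]]
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        self.area = 0.5 * det                 # positive (oriented CCW)
        # P1 gradients: grad lambda_k, shape (M, 3, 2)
        g = np.empty((self.t.shape[0], 3, 2))
        p0, p1, p2 = (self.p[self.t[:, k]] for k in range(3))
        g[:, 0, 0] = p1[:, 1] - p2[:, 1]
        g[:, 0, 1] = p2[:, 0] - p1[:, 0]
        g[:, 1, 0] = p2[:, 1] - p0[:, 1]
        g[:, 1, 1] = p0[:, 0] - p2[:, 0]
        g[:, 2, 0] = p0[:, 1] - p1[:, 1]
        g[:, 2, 1] = p1[:, 0] - p0[:, 0]
        self.grad_p1 = g / det[:, None, None]
        # quadrature points in physical coordinates, (M, nq, 2)
        self.qp = np.einsum("qk,mkd->mqd", _QBARY, self.p[self.t])
        self.qw = _QW
        self.rw = self.qp[:, :, 0] if self.axisym else np.ones_like(self.qp[:, :, 0])
        self.basis_p1 = _QBARY                # (nq, 3)

    # -- P2 space ---------------------------------------------------------
    @cached_property
    def _p2(self):
        t = self.t
        e = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        es = np.sort(e, axis=1)
        uniq, inv = np.unique(es, axis=0, return_inverse=True)
        conn = np.hstack([t, self.n_p1 + inv.reshape(3, -1).T])
        coords = np.vstack(
            [self.p, 0.5 * (self.p[uniq[:, 0]] + self.p[uniq[:, 1]])]
        )
        edge_to_mid = {tuple(edge): self.n_p1 + k for k, edge in enumerate(uniq)}
        return conn, coords, edge_to_mid

    @property
    def conn_p2(self) -> np.ndarray:
        return self._p2[0]

    @property
    def coords_p2(self) -> np.ndarray:
        return self._p2[1]

    @property
    def n_p2(self) -> int:
        return self._p2[1].shape[0]

    @cached_property
    def basis_p2(self) -> np.ndarray:
        return _p2_basis(_QBARY)              # (nq, 6)

    @cached_property
    def grad_p2(self) -> np.ndarray:
        """P2 gradients at quadrature points, (M, nq, 6, 2)."""
        lam = _QBARY                          # (nq, 3)
        g = self.grad_p1                      # (M, 3, 2)
        out = np.empty((self.t.shape[0], _NQ, 6, 2))
        for q in range(_NQ):
            l1, l2, l3 = lam[q]
            out[:, q, 0] = (4 * l1 - 1) * g[:, 0]
            out[:, q, 1] = (4 * l2 - 1) * g[:, 1]
            out[:, q, 2] = (4 * l3 - 1) * g[:, 2]
            out[:, q, 3] = 4 * (l1 * g[:, 1] + l2 * g[:, 0])
            out[:, q, 4] = 4 * (l2 * g[:, 2] + l3 * g[:, 1])
            out[:, q, 5] = 4 * (l3 * g[:, 0] + l1 * g[:, 2])
        return out

    def p2_nodes_of(self, tag: BoundaryTag) -> np.ndarray:
        """All P2 node ids (vertices + midpoints) on edges with the given tag."""
        edges = self.mesh.boundary_edges(tag)
        _, _, edge_to_mid = self._p2
        ids = set(edges.ravel().tolist())
        for ea, eb in edges:
            key = (ea, eb) if ea < eb else (eb, ea)
            ids.add(edge_to_mid[key])
        return np.array(sorted(ids), dtype=int)

    # -- boundary edge quadrature ----------------------------------------
    @cached_property
    def _tri_centroids(self) -> np.ndarray:
        return self.p[self.t].mean(axis=1)

    def edge_data(self, tag: BoundaryTag) -> EdgeData:
        mesh = self.mesh
        ids = mesh.edge_ids(tag)
        edges = mesh.edges[ids]
        pa, pb = self.p[edges[:, 0]], self.p[edges[:, 1]]
        vec = pb - pa
        lengths = np.linalg.norm(vec, axis=1)
        nrm = np.column_stack([vec[:, 1], -vec[:, 0]]) / lengths[:, None]
        # orient outward: away from the adjacent triangle centroid
        cent = self._edge_adjacent_centroid(edges)
        mid = 0.5 * (pa + pb)
        flip = np.einsum("kd,kd->k", nrm, mid - cent) < 0
        nrm[flip] *= -1.0
        qpts = pa[:, None, :] + vec[:, None, :] * _EDGE_QP[None, :, None]
        rw = qpts[:, :, 0] if self.axisym else np.ones_like(qpts[:, :, 0])
        weights = lengths[:, None] * _EDGE_QW[None, :] * rw
        # basis[q, i]: value of P1 node i at edge gauss point q
        basis = np.column_stack([1.0 - _EDGE_QP, _EDGE_QP])
        return EdgeData(edges, lengths, nrm, qpts, weights, basis)

    def _edge_adjacent_centroid(self, edges: np.ndarray) -> np.ndarray:
        key = {}
        for m, tri in enumerate(self.t):
            for i, j in ((0, 1), (1, 2), (2, 0)):
                a, b = tri[i], tri[j]
                key[(min(a, b), max(a, b))] = m
        out = np.empty((len(edges), 2))
        for k, (a, b) in enumerate(edges):
            out[k] = self._tri_centroids[key[(min(a, b), max(a, b))]]
        return out

    # -- interpolation helpers -------------------------------------------
    def p1_at_qp(self, nodal: np.ndarray) -> np.ndarray:
        """(M, nq) values of a P1 field at triangle quadrature points."""
        return np.einsum("qk,mk->mq", self.basis_p1, nodal[self.t])

    def p1_grad(self, nodal: np.ndarray) -> np.ndarray:
        """(M, 2) per-element (constant) gradient of a P1 field."""
        return np.einsum("mkd,mk->md", self.grad_p1, nodal[self.t])

    def p2_at_qp(self, nodal: np.ndarray) -> np.ndarray:
        """(M, nq) values of a P2 field at triangle quadrature points."""
        return np.einsum("qk,mk->mq", self.basis_p2, nodal[self.conn_p2])

    # -- assembly ---------------------------------------------------------
    def _scatter(self, local: np.ndarray, rows_conn: np.ndarray,
                 cols_conn: np.ndarray, shape: tuple[int, int]) -> sp.csr_matrix:
        nl_r, nl_c = local.shape[1], local.shape[2]
        rows = np.repeat(rows_conn, nl_c, axis=1).ravel()
        cols = np.tile(cols_conn, (1, nl_r)).ravel()
        return sp.coo_matrix(
            (local.ravel(), (rows, cols)), shape=shape
        ).tocsr()

    def p1_stiffness(self) -> sp.csr_matrix:
        w = self.area * np.einsum("q,mq->m", self.qw, self.rw)
        local = np.einsum("m,mid,mjd->mij", w, self.grad_p1, self.grad_p1)
        return self._scatter(local, self.t, self.t, (self.n_p1, self.n_p1))

    def p1_mass(self, coeff_qp: np.ndarray | float = 1.0) -> sp.csr_matrix:
        """Mass-type matrix with an optional coefficient given at qpoints."""
        c = np.broadcast_to(np.asarray(coeff_qp, dtype=float),
                            (self.t.shape[0], _NQ))
        w = self.area[:, None] * self.qw[None, :] * self.rw * c
        local = np.einsum("mq,qi,qj->mij", w, self.basis_p1, self.basis_p1)
        return self._scatter(local, self.t, self.t, (self.n_p1, self.n_p1))

    def p1_load(self, coeff_qp: np.ndarray | float) -> np.ndarray:
        c = np.broadcast_to(np.asarray(coeff_qp, dtype=float),
                            (self.t.shape[0], _NQ))
        w = self.area[:, None] * self.qw[None, :] * self.rw * c
        local = np.einsum("mq,qi->mi", w, self.basis_p1)
        b = np.zeros(self.n_p1)
        np.add.at(b, self.t, local)
        return b

    def p1_advection(self, a_qp: np.ndarray) -> sp.csr_matrix:
        """Advection matrix  int (a . grad c) v  with a given at qpoints (M,nq,2)."""
        w = self.area[:, None] * self.qw[None, :] * self.rw
        agrad = np.einsum("mqd,mjd->mqj", a_qp, self.grad_p1)  # (M, nq, 3)
        local = np.einsum("mq,qi,mqj->mij", w, self.basis_p1, agrad)
        return self._scatter(local, self.t, self.t, (self.n_p1, self.n_p1))

    def p1_supg(self, a_qp: np.ndarray, tau: np.ndarray) -> sp.csr_matrix:
        """SUPG stabilisation  sum_e tau_e int (a.grad v)(a.grad c)."""
        w = self.area[:, None] * self.qw[None, :] * self.rw * tau[:, None]
        agrad = np.einsum("mqd,mjd->mqj", a_qp, self.grad_p1)
        local = np.einsum("mq,mqi,mqj->mij", w, agrad, agrad)
        return self._scatter(local, self.t, self.t, (self.n_p1, self.n_p1))

    def edge_load_p1(self, ed: EdgeData, coeff: np.ndarray | float) -> np.ndarray:
        """Boundary load  int g v ds  (with r-weight) for P1 test functions."""
        c = np.broadcast_to(np.asarray(coeff, dtype=float), ed.weights.shape)
        contrib = np.einsum("kq,qi->ki", ed.weights * c, ed.basis)
        b = np.zeros(self.n_p1)
        np.add.at(b, ed.edges, contrib)
        return b

    def edge_mass_p1(self, ed: EdgeData, coeff: np.ndarray | float) -> sp.csr_matrix:
        """Boundary matrix  int g v c ds for P1 trial/test functions."""
        c = np.broadcast_to(np.asarray(coeff, dtype=float), ed.weights.shape)
        local = np.einsum("kq,qi,qj->kij", ed.weights * c, ed.basis, ed.basis)
        return self._scatter(local, ed.edges, ed.edges, (self.n_p1, self.n_p1))


def apply_dirichlet(
    A: sp.csr_matrix, b: np.ndarray, nodes: np.ndarray, values: np.ndarray | float
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Row-replacement Dirichlet conditions; returns modified copies."""
    A = A.tolil(copy=True)
    b = b.copy()
    vals = np.broadcast_to(np.asarray(values, dtype=float), nodes.shape)
    for n, v in zip(nodes, vals):
        A.rows[n] = [n]
        A.data[n] = [1.0]
        b[n] = v
    return A.tocsr(), b


class LinearSolver:
    """Sparse LU wrapper; factorisation cached for repeated right-hand sides."""

    def __init__(self, A: sp.spmatrix):
        self.lu = spla.splu(sp.csc_matrix(A))

    def solve(self, b: np.ndarray) -> np.ndarray:
        return self.lu.solve(b)
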