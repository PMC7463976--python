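"""Closed-form electrokinetics oracles.

These are the textbook limits the numerical solvers are checked against:
the Debye-Hueckel screened potential near a weakly charged planar wall,
the Grahame charge/potential relation, the Hueckel and Smoluchowski
electrophoretic-mobility bounds, and a series-resistance (pore + Hall
access) estimate of the open-pore current.  All are pure functions of the
parameter records; none of them call the finite-element machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

from .model_params import (
    ElectrolyteParams,
    ParameterSet,
    bulk_conductivity,
    debye_length,
)

__all__ = [
    "BenchmarkCase",
    "grahame_zeta",
    "grahame_sigma",
    "debye_huckel_profile",
    "smoluchowski_huckel_bounds",
    "ohmic_pore_current",
    "stokes_drag_sphere",
]


@dataclass(frozen=True)
class BenchmarkCase:
    """A named closed-form solution with the tolerance it is trusted to."""

    name: str
    exact: Callable[..., float]
    tolerance: float
    description: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.tolerance <= 0.1):
            raise ValueError("benchmark tolerance must lie in (0, 0.1]")


def grahame_zeta(sigma: float, elec: ElectrolyteParams) -> float:
    """Surface (zeta) potential of a planar wall with charge density sigma.

    Grahame relation for a symmetric 1:1 electrolyte of bulk concentration
    C0:  sigma = sqrt(8 eps_f R T C0) * sinh(F zeta / (2 R T)).
    """
    C0 = _symmetric_c0(elec)
    denom = math.sqrt(8.0 * elec.eps_f * elec.R * elec.T * C0)
    return 2.0 * elec.R * elec.T / elec.F * math.asinh(sigma / denom)


def grahame_sigma(zeta: float, elec: ElectrolyteParams) -> float:
    """Inverse of :func:`grahame_zeta`."""
    C0 = _symmetric_c0(elec)
    denom = math.sqrt(8.0 * elec.eps_f * elec.R * elec.T * C0)
    return denom * math.sinh(elec.F * zeta / (2.0 * elec.R * elec.T))


def _symmetric_c0(elec: ElectrolyteParams) -> float:
    zs = sorted(s.z for s in elec.species)
    if len(elec.species) != 2 or zs != [-1.0, 1.0]:
        raise ValueError("Grahame relation implemented for a 1:1 electrolyte only")
    c0s = {s.c0 for s in elec.species}
    if len(c0s) != 1:
        raise ValueError("Grahame relation needs equal bulk concentrations")
    return c0s.pop()


def debye_huckel_profile(
    elec: ElectrolyteParams,
    zeta: float | None = None,
    sigma: float | None = None,
) -> Callable[[np.ndarray], np.ndarray]:
    """Screened potential psi(x) = zeta * exp(-x / lambda_D) near a planar wall.

    Give either the wall potential ``zeta`` directly or the surface charge
    ``sigma`` (converted through the Grahame relation).  Valid for
    |zeta| <~ 25 mV; x is the distance from the wall in metres.
    """
    if (zeta is None) == (sigma is None):
        raise ValueError("give exactly one of zeta or sigma")
    if zeta is None:
        zeta = grahame_zeta(sigma, elec)
    lam = debye_length(elec)

    def psi(x: np.ndarray) -> np.ndarray:
        return zeta * np.exp(-np.asarray(x, dtype=float) / lam)

    return psi


def smoluchowski_huckel_bounds(
    zeta: float, E: float, elec: ElectrolyteParams
) -> tuple[float, float]:
    """(Hueckel, Smoluchowski) electrophoretic velocity bounds, m/s.

    Hueckel (thick EDL, kappa*a << 1): U = 2 eps_f zeta E / (3 mu);
    Smoluchowski (thin EDL, kappa*a >> 1): U = eps_f zeta E / mu.
    A particle with intermediate kappa*a in an unbounded fluid moves at a
    speed between the two magnitudes.
    """
    u_smol = elec.eps_f * zeta * E / elec.mu
    return (2.0 / 3.0) * u_smol, u_smol


def ohmic_pore_current(params: ParameterSet) -> float:
    """Series-resistance estimate of the open-pore current, amperes.

    Thin-EDL, neutral-channel estimate: the pore cylinder resistance
    h / (sigma pi r^2) in series with one Hall access resistance
    1/(2 sigma d) = 1/(4 sigma r) on each side; I = phi_0 / R_total.
    Used only as an order-of-magnitude gate on the computed base current.
    """
    sigma = bulk_conductivity(params.electrolyte)
    r = params.geometry.b / 2.0
    R_pore = params.geometry.h / (sigma * math.pi * r * r)
    R_access = 2.0 * (1.0 / (4.0 * sigma * r))
    return params.drive.phi_0 / (R_pore + R_access)


def stokes_drag_sphere(mu: float, a: float, U: float) -> float:
    """Unbounded-fluid Stokes drag 6 pi mu a U on a sphere, newtons."""
    return 6.0 * math.pi * mu * a * U
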