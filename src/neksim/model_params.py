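"""Physical constants, material parameters, geometry and numerical controls.

Everything downstream (meshing, the PNP and Stokes solves, trajectory sweeps)
is driven by the five parameter records defined here.  Units are SI
throughout; the only non-SI unit exposed is the base pair (1 bp = 0.34 nm,
the rise per base pair of B-DNA) used for particle lengths and axial
positions.

The baseline parameter set describes a KCl-filled solid-state nanopore:
two reservoirs of width W = 100 nm and height H = 200 nm joined by a pore
of diameter b = 5 nm through a membrane of thickness h = 5 nm, with a
rod-like particle of cap radius a = 1 nm carrying a surface charge density
of -0.01 C/m^2 in 10 mol/m^3 KCl at 300 K.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import yaml

__all__ = [
    "ConfigurationError",
    "ValidationError",
    "Species",
    "ElectrolyteParams",
    "SimulationGeometry",
    "DriveParams",
    "ParticleProps",
    "NumericsParams",
    "ParameterSet",
    "BP_LENGTH",
    "baseline_parameters",
    "load_parameters",
    "dump_parameters",
    "numerics_profile",
    "debye_length",
    "bulk_conductivity",
]

#: rise per base pair of B-DNA, metres
BP_LENGTH = 0.34e-9

GAS_CONSTANT = 8.314       # J/(mol K)
FARADAY = 96485.0          # C/mol


class ConfigurationError(ValueError):
    """A configuration document is missing a key or cannot be parsed."""


class ValidationError(ValueError):
    """A parameter value violates a model invariant."""


def _require_positive(name: str, value: float) -> None:
    if not (value > 0.0) or not math.isfinite(value):
        raise ValidationError(f"{name} must be strictly positive, got {value!r}")


@dataclass(frozen=True)
class Species:
    """One ionic species: valence, diffusivity (m^2/s), bulk concentration (mol/m^3)."""

    z: float
    D: float
    c0: float

    def __post_init__(self) -> None:
        _require_positive("species diffusivity D", self.D)
        _require_positive("species bulk concentration c0", self.c0)
        if not math.isfinite(self.z):
            raise ValidationError("species valence z must be finite")


@dataclass(frozen=True)
class ElectrolyteParams:
    """Fluid and ion constants of the electrolyte filling the pore."""

    eps_f: float = 7.08e-10      # F/m, fluid permittivity
    rho_f: float = 1.0e3         # kg/m^3
    mu: float = 1.0e-3           # Pa s
    T: float = 300.0             # K
    R: float = GAS_CONSTANT      # J/(mol K)
    F: float = FARADAY           # C/mol
    species: tuple[Species, ...] = (
        Species(z=+1.0, D=1.95e-9, c0=10.0),   # K+
        Species(z=-1.0, D=2.03e-9, c0=10.0),   # Cl-
    )

    def __post_init__(self) -> None:
        for name in ("eps_f", "rho_f", "mu", "T", "R", "F"):
            _require_positive(name, getattr(self, name))
        if len(self.species) < 1:
            raise ValidationError("at least one ionic species is required")
        net = sum(s.z * s.c0 for s in self.species)
        scale = max(abs(s.z * s.c0) for s in self.species)
        if abs(net) > 1e-12 * scale:
            raise ValidationError(
                f"bulk electroneutrality violated: sum z_i*c0_i = {net:g}"
            )

    @property
    def thermal_voltage(self) -> float:
        """RT/F in volts (25.9 mV at 300 K)."""
        return self.R * self.T / self.F


@dataclass(frozen=True)
class SimulationGeometry:
    """Reservoir/membrane/pore/particle dimensions, metres.

    ``L_p`` is the end-to-end particle length including both hemispherical
    caps; ``y_p`` is the particle-centre axial position with the origin at
    the pore centre.
    """

    W: float = 100e-9
    H: float = 200e-9
    h: float = 5e-9
    b: float = 5e-9
    a: float = 1e-9
    L_p: float = 200 * BP_LENGTH
    y_p: float = -300 * BP_LENGTH
    x_p: float = 0.0
    bp_length: float = BP_LENGTH

    def __post_init__(self) -> None:
        for name in ("W", "H", "h", "b", "a", "L_p"):
            _require_positive(name, getattr(self, name))
        if not 2.0 * self.a < self.b:
            raise ValidationError(
                f"particle does not fit pore: 2a = {2 * self.a:g} >= b = {self.b:g}"
            )
        if not self.L_p < 2.0 * self.H:
            raise ValidationError(
                f"particle does not fit a reservoir: L_p = {self.L_p:g} >= 2H = {2 * self.H:g}"
            )
        if self.L_p < 2.0 * self.a:
            raise ValidationError(
                f"L_p = {self.L_p:g} shorter than the two caps (2a = {2 * self.a:g})"
            )

    # -- unit helpers ------------------------------------------------------
    @property
    def y_p_bp(self) -> float:
        return self.y_p / self.bp_length

    def with_position_bp(self, y_bp: float) -> "SimulationGeometry":
        return replace(self, y_p=y_bp * self.bp_length)

    @property
    def channel_height(self) -> float:
        """Full channel height 2H + h between the driven walls."""
        return 2.0 * self.H + self.h

    @property
    def L_p_bp(self) -> float:
        return self.L_p / self.bp_length


@dataclass(frozen=True)
class DriveParams:
    """Applied potential phi_0 at the top wall (bottom wall grounded).

    The nominal field strength is defined as the mean field over the full
    channel height: E_nom = phi_0 / (2H + h).  Either quantity determines
    the other; both are stored and checked for consistency.
    """

    phi_0: float
    E_nom: float
    channel_height: float

    def __post_init__(self) -> None:
        _require_positive("channel_height", self.channel_height)
        if abs(self.phi_0 - self.E_nom * self.channel_height) > 1e-12 * max(
            abs(self.phi_0), 1e-300
        ):
            raise ValidationError(
                "phi_0 and E_nom are inconsistent: "
                f"phi_0 = {self.phi_0!r}, E_nom*(2H+h) = {self.E_nom * self.channel_height!r}"
            )

    @classmethod
    def from_E_nom(cls, E_nom: float, geom: SimulationGeometry) -> "DriveParams":
        Lc = geom.channel_height
        return cls(phi_0=E_nom * Lc, E_nom=E_nom, channel_height=Lc)

    @classmethod
    def from_phi_0(cls, phi_0: float, geom: SimulationGeometry) -> "DriveParams":
        Lc = geom.channel_height
        return cls(phi_0=phi_0, E_nom=phi_0 / Lc, channel_height=Lc)


@dataclass(frozen=True)
class ParticleProps:
    """Particle surface charge density (C/m^2) and permittivity (F/m)."""

    sigma_p: float = -0.01
    eps_p: float = 7.08e-10

    def __post_init__(self) -> None:
        if not math.isfinite(self.sigma_p):
            raise ValidationError("sigma_p must be finite")
        _require_positive("eps_p", self.eps_p)


@dataclass(frozen=True)
class NumericsParams:
    """Numerical controls for meshing, the Picard loop and sweeps.

    ``bl_fraction`` sets the boundary-layer element size as a fraction of
    the Debye length (elements within two Debye lengths of the particle or
    membrane are at most ``bl_fraction * lambda_D`` long); ``h_bulk`` is the
    far-field element size.
    """

    bl_fraction: float = 1.0 / 3.0
    h_bulk: float = 2.0e-9
    picard_tol: float = 0.005
    picard_max_iter: int = 100
    omega: float = 0.5
    velocity_rel_tol: float = 1.0e-3
    grid_bp: tuple[float, ...] | None = None
    seed: int = 0    # reserved; the solver itself is deterministic

    def __post_init__(self) -> None:
        for name in ("bl_fraction", "picard_tol", "omega", "velocity_rel_tol"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValidationError(f"{name} must lie in (0, 1], got {v!r}")
        if self.picard_max_iter < 1:
            raise ValidationError("picard_max_iter must be >= 1")
        _require_positive("h_bulk", self.h_bulk)


_PROFILES = {
    # name: (bl_fraction, h_bulk)
    "coarse": (1.0, 6.0e-9),
    "default": (1.0 / 3.0, 1.7e-9),
    "fine": (1.0 / 6.0, 1.5e-9),
    # extra-light profile for smoke tests and quick looks
    "test": (1.0, 14.0e-9),
}


def numerics_profile(name: str, **overrides) -> NumericsParams:
    """Return the named resolution profile (coarse / default / fine / test)."""
    try:
        frac, hb = _PROFILES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown resolution profile {name!r}; choose from {sorted(_PROFILES)}"
        ) from None
    return NumericsParams(bl_fraction=frac, h_bulk=hb, **overrides)


@dataclass(frozen=True)
class ParameterSet:
    """Bundle of the five parameter records describing one simulation."""

    electrolyte: ElectrolyteParams
    geometry: SimulationGeometry
    drive: DriveParams
    particle: ParticleProps
    numerics: NumericsParams

    def __iter__(self) -> Iterator:
        yield self.electrolyte
        yield self.geometry
        yield self.drive
        yield self.particle
        yield self.numerics

    def at_position_bp(self, y_bp: float) -> "ParameterSet":
        return replace(self, geometry=self.geometry.with_position_bp(y_bp))

    def with_E_nom(self, E_nom: float) -> "ParameterSet":
        return replace(self, drive=DriveParams.from_E_nom(E_nom, self.geometry))


def baseline_parameters(
    E_nom: float = 2.0e6,
    L_p_bp: float = 200.0,
    y_p_bp: float = -300.0,
    numerics: NumericsParams | None = None,
) -> ParameterSet:
    """The baseline nanopore configuration (KCl, 10 mol/m^3, 5 nm pore)."""
    geom = SimulationGeometry(L_p=L_p_bp * BP_LENGTH, y_p=y_p_bp * BP_LENGTH)
    return ParameterSet(
        electrolyte=ElectrolyteParams(),
        geometry=geom,
        drive=DriveParams.from_E_nom(E_nom, geom),
        particle=ParticleProps(),
        numerics=numerics or NumericsParams(),
    )


# ---------------------------------------------------------------------------
# configuration I/O

_GEOM_KEYS = ("W", "H", "h", "b", "a", "L_p", "y_p", "x_p")


def load_parameters(config_text: str) -> ParameterSet:
    """Parse a flat key-value (YAML) document into a validated ParameterSet.

    Keys are the field names above in SI units; convenience keys with
    ``_nm``/``_bp`` suffixes and ``E_nom_MV_per_m`` are accepted.  Missing
    keys default to the baseline configuration.
    """
    try:
        doc = yaml.safe_load(io.StringIO(config_text)) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse configuration: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigurationError("configuration must be a flat key-value mapping")
    doc = dict(doc)

    def pop_scaled(base: str, default: float | None = None) -> float | None:
        """Fetch ``base`` or one of its unit-suffixed variants."""
        candidates = [(base, 1.0), (base + "_nm", 1e-9), (base + "_bp", BP_LENGTH)]
        found = [(k, s) for k, s in candidates if k in doc]
        if not found:
            return default
        if len(found) > 1:
            raise ConfigurationError(
                f"conflicting keys for {base!r}: {[k for k, _ in found]}"
            )
        key, scale = found[0]
        return float(doc.pop(key)) * scale

    # electrolyte ---------------------------------------------------------
    elec_kw = {}
    for key in ("eps_f", "rho_f", "mu", "T", "R", "F"):
        if key in doc:
            elec_kw[key] = float(doc.pop(key))
    if "species" in doc:
        raw = doc.pop("species")
        try:
            elec_kw["species"] = tuple(
                Species(z=float(s["z"]), D=float(s["D"]), c0=float(s["c0"]))
                for s in raw
            )
        except (TypeError, KeyError) as exc:
            raise ConfigurationError(
                "species must be a list of {z, D, c0} mappings"
            ) from exc
    elif "C0" in doc:
        C0 = float(doc.pop("C0"))
        D1 = float(doc.pop("D1", 1.95e-9))
        D2 = float(doc.pop("D2", 2.03e-9))
        elec_kw["species"] = (
            Species(z=+1.0, D=D1, c0=C0),
            Species(z=-1.0, D=D2, c0=C0),
        )
    electrolyte = ElectrolyteParams(**elec_kw)

    # geometry ------------------------------------------------------------
    geom_kw = {}
    for key in _GEOM_KEYS:
        v = pop_scaled(key)
        if v is not None:
            geom_kw[key] = v
    geometry = SimulationGeometry(**geom_kw)

    # drive ---------------------------------------------------------------
    phi_0 = doc.pop("phi_0", None)
    E_nom = doc.pop("E_nom", None)
    if "E_nom_MV_per_m" in doc:
        if E_nom is not None:
            raise ConfigurationError("give either E_nom or E_nom_MV_per_m, not both")
        E_nom = float(doc.pop("E_nom_MV_per_m")) * 1e6
    if phi_0 is not None and E_nom is not None:
        drive = DriveParams(
            phi_0=float(phi_0), E_nom=float(E_nom),
            channel_height=geometry.channel_height,
        )
    elif phi_0 is not None:
        drive = DriveParams.from_phi_0(float(phi_0), geometry)
    elif E_nom is not None:
        drive = DriveParams.from_E_nom(float(E_nom), geometry)
    else:
        drive = DriveParams.from_E_nom(2.0e6, geometry)

    # particle ------------------------------------------------------------
    part_kw = {}
    if "sigma_p" in doc:
        part_kw["sigma_p"] = float(doc.pop("sigma_p"))
    part_kw["eps_p"] = float(doc.pop("eps_p", electrolyte.eps_f))
    particle = ParticleProps(**part_kw)

    # numerics ------------------------------------------------------------
    num_kw = {}
    if "profile" in doc:
        base = numerics_profile(str(doc.pop("profile")))
        num_kw["bl_fraction"] = base.bl_fraction
        num_kw["h_bulk"] = base.h_bulk
    for key in (
        "bl_fraction", "h_bulk", "picard_tol", "picard_max_iter",
        "omega", "velocity_rel_tol", "seed",
    ):
        if key in doc:
            cast = int if key in ("picard_max_iter", "seed") else float
            num_kw[key] = cast(doc.pop(key))
    if "grid_bp" in doc:
        num_kw["grid_bp"] = tuple(float(v) for v in doc.pop("grid_bp"))
    numerics = NumericsParams(**num_kw)

    if doc:
        raise ConfigurationError(f"unrecognized configuration keys: {sorted(doc)}")
    return ParameterSet(electrolyte, geometry, drive, particle, numerics)


def dump_parameters(params: ParameterSet) -> str:
    """Serialize a ParameterSet to the flat YAML dialect read by load_parameters."""
    e, g, d, p, n = params
    doc: dict = {
        "eps_f": e.eps_f, "rho_f": e.rho_f, "mu": e.mu,
        "T": e.T, "R": e.R, "F": e.F,
        "species": [{"z": s.z, "D": s.D, "c0": s.c0} for s in e.species],
        "phi_0": d.phi_0, "E_nom": d.E_nom,
        "sigma_p": p.sigma_p, "eps_p": p.eps_p,
        "bl_fraction": n.bl_fraction, "h_bulk": n.h_bulk,
        "picard_tol": n.picard_tol, "picard_max_iter": n.picard_max_iter,
        "omega": n.omega, "velocity_rel_tol": n.velocity_rel_tol,
        "seed": n.seed,
    }
    for key in _GEOM_KEYS:
        doc[key] = getattr(g, key)
    if n.grid_bp is not None:
        doc["grid_bp"] = list(n.grid_bp)
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# derived electrolyte quantities

def debye_length(elec: ElectrolyteParams) -> float:
    """EDL screening length sqrt(eps_f R T / (F^2 sum z_i^2 c0_i)), metres."""
    ionic = sum(s.z**2 * s.c0 for s in elec.species)
    if ionic <= 0:
        raise ValidationError("cannot form a Debye length from uncharged species")
    return math.sqrt(elec.eps_f * elec.R * elec.T / (elec.F**2 * ionic))


def bulk_conductivity(elec: ElectrolyteParams) -> float:
    """Nernst-Einstein bulk conductivity (F^2/RT) sum z_i^2 D_i c0_i, S/m."""
    return (elec.F**2 / (elec.R * elec.T)) * sum(
        s.z**2 * s.D * s.c0 for s in elec.species
    )
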