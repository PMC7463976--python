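# Methods

`neksim` computes the steady electrokinetic state of a charged, rod-like
particle (a coarse surrogate for a short double-stranded DNA fragment)
inside a solid-state nanopore, the velocity at which the particle
translocates, and the ionic-current signature (blockade / enhancement) it
produces.  This note records the model, the numerical choices, and what
the test suite does and does not establish.

## Physical model

The electrolyte (KCl, bulk concentration C0) fills two reservoirs of width
W and height H joined by a cylindrical pore of diameter b through a
membrane of thickness h.  The particle is a rigid cylinder of radius a
with hemispherical end caps, total end-to-end length L_p, carrying uniform
surface charge density sigma_p, centred on the pore axis.  Lengths along
the axis are quoted in base pairs, 1 bp = 0.34 nm (the rise per base pair
of B-DNA).

Three coupled fields are solved on the fluid domain:

* **Potential** phi: `-eps_f lap(phi) = F (z1 c1 + z2 c2)`, driven by a
  potential phi_0 on the top wall with the bottom wall grounded; the
  particle surface carries the Neumann condition
  `-n . grad(phi) = sigma_p / eps_f` (n the outward particle normal), all
  other rigid boundaries are insulating.  The *nominal field* is defined
  as `E_nom = phi_0 / (2H + h)`, the mean field over the 405 nm channel —
  the only mapping consistent with driving the system by wall potentials.
* **Ion transport**: steady Nernst-Planck for each species,
  `div(u c_i - D_i grad c_i - (z_i D_i F / RT) c_i grad phi) = 0`, with
  bulk concentrations on the driven walls, a purely convective normal flux
  on the (moving) particle surface, and zero normal flux on the membrane.
* **Flow**: creeping incompressible flow
  `0 = div[-p I + mu (grad u + grad u^T)] + f`, `div u = 0`, with the
  Coulomb body force `f = -F (z1 c1 + z2 c2) grad phi`; no slip on the
  membrane, rigid translation (0, U_p) on the particle, zero normal
  velocity and zero shear on the lateral symmetry boundary, and open
  (traction-free, p -> 0) reservoir tops.  Inertia is dropped entirely:
  the Reynolds number is ~1e-5 and, in the quasi-static sweep below, the
  time derivative vanishes identically.

Forces on the particle are surface integrals of the Maxwell stress
`eps_p [E E - (E.E)/2 I]` (with eps_p = eps_f in the baseline, making the
choice of stress-side immaterial) and of the total fluid stress.

### Quasi-static trajectories

The particle is density-matched and inertia-free, so at every instant it
moves at the velocity where the net axial force vanishes.  A trajectory is
therefore a *position sweep*: for each axial position y_p the domain is
re-meshed, the coupled fields are converged, and the force-free velocity
is found; passage time is recovered as `t(y) = int dy / U_p(y)` by
trapezoidal quadrature.  This replaces moving-mesh (ALE) time stepping
exactly in the limit of fast double-layer relaxation — here
`lambda_D^2 / D ~ 5 ns` against transit times of microseconds — and
removes mesh-distortion failure modes.

The ionic current through a horizontal cross-section,
`I = int_S F (sum_i z_i N_i) . n dS` (positive along +y), is read at the
pore midplane (shifted past the particle end when the particle straddles
it; steady-state conservation makes the choice immaterial, and the test
suite verifies cross-plane agreement to <1%).  The reference current I_0
is the reading with the particle parked at its far-field start position
(0, -300 bp); it agrees with the particle-absent open pore to <0.3%
(asserted in the suite).  The observable is the relative deviation
`I* = (I - I_0)/I_0` — negative during blockade, positive during
enhancement.

## Discretisation

* **Meshing**: an unstructured triangular mesh of the meridian half-plane
  is generated per particle position by a signed-distance relaxation
  scheme (distmesh-style), with a graded size field: elements within two
  Debye lengths of the particle and membrane are at most
  `bl_fraction * lambda_D` long, hemispherical caps are resolved with
  ~0.45 a elements, and the particle/pore-wall annulus with at most one
  third of the radial gap.  The generator is deterministic for a given
  seed; quality gates (min angle > 15 deg, zero boundary-layer violations)
  trigger a deterministic re-seed when missed.
* **Spaces**: P1 for potential and concentrations; inf-sup-stable
  Taylor-Hood (P2 velocity / P1 pressure) for Stokes — validated against
  plane Poiseuille flow to <1%.  Axisymmetric weak forms carry the 2 pi r
  Jacobian, the azimuthal strain u_r/r and the radial continuity term.
* **Internal scaling**: potentials in units of RT/F (25.86 mV at 300 K),
  concentrations in C0, lengths in nm, velocities in mm/s, pressure in
  mu u*/L*; conversions to SI happen at module boundaries.
* **Stabilisation**: the Nernst-Planck operator is an advection-diffusion
  operator in the drift field `Pe u - z grad(phi~)`; element Peclet
  numbers reach ~1-3 in the pore, so streamline (SUPG) stabilisation with
  the standard coth(alpha)-1/alpha weight is applied.
* **Forces**: evaluated variationally (reaction forces): the surface
  integral is rewritten through the divergence theorem with a hat test
  field equal to the unit axial vector on the particle nodes, which
  converges markedly faster than integrating elementwise stresses along
  the boundary.  The suite checks the drag of a small sphere against
  6 pi mu a U (within 15%, the slack covering residual wall effects) and
  the free electrophoretic velocity against the Hueckel/Smoluchowski
  bounds.

## Solver

The coupled system is solved by a staggered fixed-point (Picard) loop —
Poisson, then Nernst-Planck, then body force, then Stokes — with
under-relaxation factor omega = 0.5 and relative-change tolerance 0.005
(largest relative L2 update among phi, c_i, u).  Two details matter:

* The Poisson step linearises the ionic screening response about the
  previous potential (adds `alpha sum z_i^2 c_i (phi - phi_old)` to both
  sides).  The fixed point is unchanged, but the loop becomes a damped
  Newton scheme for the equilibrium double layer; without the term the
  staggered iteration diverges once surface potentials exceed a few kT.
  The iteration starts from the charge-free drive potential, so the
  applied bias is never screened away spuriously.
* Poisson and Stokes matrices depend only on the mesh; their LU
  factorisations are computed once per position and reused across all
  Picard iterations and force-free velocity probes.

Force-free velocity: the axial force is affine in the particle velocity
at frozen ionic fields (Stokes linearity), so one extra Stokes solve with
unit particle velocity gives the drag slope and the root follows directly;
outer re-coupling iterations absorb the (weak, Pe ~ 0.1) convective
feedback until the velocity is stationary to 1e-3 relative.  Sweeps
warm-start each position from the previous solution interpolated onto the
new mesh, roughly halving Picard iteration counts; warm and cold starts
agree to <0.5% (tested).

## Resolution profiles and problem sizes

| profile | bl fraction of lambda_D | bulk size | elements (baseline) | use |
|---------|------------------------|-----------|---------------------|-----|
| coarse  | 1.0   | 6 nm   | ~2.2k  | sweeps, acceptance runs |
| default | 1/3   | 1.7 nm | ~22k   | production fidelity |
| fine    | 1/6   | 1.5 nm | ~52k   | convergence checks |
| test    | 1.0   | 14 nm  | ~1.5k  | smoke tests |

Trajectory sweeps run y_p from -300 to +300 bp, step 15 bp within
+-150 bp of the pore and 30 bp outside — 31 positions, a few minutes per
sweep on one CPU at the coarse profile.  Peak velocities computed at the
coarse profile agree with the default profile to <1% (the boundary-layer
check in the suite bounds the current change under 2x refinement at 2%).

## Design choices where the problem was open

* **Axisymmetric by default.** The pore has a diameter and the particle is
  a cylinder, so the physical object is a body of revolution; the
  Cartesian (x, y) notation of the problem statement is read as the
  meridian plane.  A planar-2D mode (unit depth, same meridian mesh) is
  retained for comparison; sweep metadata logs the mode used.
* **L_p includes both caps** (end-to-end length), and the particle shape
  is a straight cylinder with hemispherical caps of the same radius.
* **E_nom = phi_0/(2H+h).**  No potential value in volts is stated for
  the nominal fields; the mean-field mapping over the full channel height
  is the only self-consistent definition available.  Peak velocities scale
  almost linearly with phi_0, so this choice directly scales the headline
  numbers.
* **Membrane is charge-free**; only the particle carries sigma_p.
* **I_0 with the particle parked far away** rather than absent (difference
  <0.3%, asserted).

## What the tests show — and what they do not

The suite validates every building block against closed forms
(Debye-Hueckel layer, Grahame relation, Boltzmann equilibrium, Poiseuille,
Helmholtz-Smoluchowski electroosmosis, Stokes drag, Hueckel
electrophoresis) and the assembled pipeline against qualitative
resistive-pulse phenomenology: current blockade while the particle enters,
enhancement as its counterion cloud exits, far-field recovery of I*,
amplification of both with field strength, deeper blockade for longer
particles, and near-identical mid-pore currents across lengths.

Two caveats.  First, the continuum PNP description is stretched at a 5 nm
pore with lambda_D = 3.1 nm: finite ion size, Stern layers, wall slip and
DNA flexibility are all absent, so quantitative agreement with experiments
at this scale is not claimed.  Second, the velocity profile this model
produces for the 200 bp particle is a double-humped plateau whose entrance
and exit humps agree within 1%; concentration polarisation tips the global
maximum slightly to the exit side, so the "peak location" is not a robust
observable of this model even though the peak *value* is.

## Known limitations

* On-axis, translation-only motion: no rotation, tilt, off-axis drift or
  dielectrophoretic alignment; lateral force is reported (zero on-axis by
  symmetry) but never integrated.
* Two monovalent species; the data model permits more, the tests do not
  cover them.
* The quasi-static sweep cannot represent genuinely transient signatures
  (double-layer charging, inertial overshoot); none are expected in the
  parameter range covered.
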