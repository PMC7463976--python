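# neksim

Continuum electrokinetics of nanopore particle translocation: a coupled
Poisson–Nernst–Planck–Stokes (PNPS) simulator for a charged rod-like
particle — a surrogate for a short double-stranded DNA fragment — passing
through a solid-state nanopore, with the resistive-pulse observables used
in nanopore sensing.

## The problem

In resistive-pulse sensing a DC bias drives ionic current through a
nanometre-scale pore; a translocating particle transiently perturbs that
current, and the size, sign and timing of the perturbation encode the
particle's length and charge.  `neksim` models this at the continuum
level.  On the fluid domain (two reservoirs joined by a pore of diameter
*b* through a membrane of thickness *h*, minus a capsule-shaped particle
of cap radius *a* and end-to-end length *L*<sub>p</sub> on the axis):

- electrostatics: −ε<sub>f</sub>∇²φ = F(z₁c₁ + z₂c₂), with applied
  potential φ₀ on the top wall, ground at the bottom, surface-charge
  condition −**n**·∇φ = σ<sub>p</sub>/ε<sub>f</sub> on the particle;
- ion transport: ∇·**N**<sub>i</sub> = 0 with
  **N**<sub>i</sub> = **u**c<sub>i</sub> − D<sub>i</sub>∇c<sub>i</sub> −
  (z<sub>i</sub>D<sub>i</sub>F/RT)c<sub>i</sub>∇φ;
- creeping flow: 0 = ∇·[−p**I** + μ(∇**u** + ∇**u**ᵀ)] + **f**, ∇·**u** = 0,
  with Coulomb body force **f** = −F(z₁c₁ + z₂c₂)∇φ.

The particle is inertia-free, so at each axial position y<sub>p</sub> it
moves at the **force-free velocity** U<sub>p</sub> where the Maxwell-stress
force ε<sub>p</sub>∮[**EE** − ½(**E**·**E**)**I**]·**n** dΓ and the fluid-stress
force ∮[−p**I** + μ(∇**u** + ∇**u**ᵀ)]·**n** dΓ cancel.  Trajectories are
quasi-static position sweeps (re-meshed per position), with passage time
recovered by quadrature.  The current through a cross-section,
I = ∫<sub>S</sub> F(Σz<sub>i</sub>**N**<sub>i</sub>)·**n** dS, is compared
with the far-field reference I₀ through the deviation
**I\* = (I − I₀)/I₀** — negative during blockade, positive during
enhancement.

The baseline configuration is 10 mol/m³ KCl at 300 K in a 5 nm pore
(W = 100 nm, H = 200 nm, h = b = 5 nm, a = 1 nm,
σ<sub>p</sub> = −0.01 C/m², 1 bp = 0.34 nm).  The Debye length is 3.08 nm,
so the pore operates in the overlapped-double-layer regime.

Everything is solved with an in-package finite-element kernel (P1 fields,
Taylor–Hood velocity/pressure) on distmesh-style boundary-refined meshes;
see `docs/methods.md` for the numerics and their validation against
closed-form electrokinetics (Debye–Hückel, Grahame, Boltzmann, Poiseuille,
Helmholtz–Smoluchowski, Stokes drag, Hückel electrophoresis).

## Worked example

```python
from neksim import baseline_parameters, numerics_profile, sweep_trajectory
from neksim.particle_dynamics import find_extremum

params = baseline_parameters(E_nom=2e6, L_p_bp=200,         # 2 MV/m, 200 bp
                             numerics=numerics_profile("coarse"))
traj = sweep_trajectory(params)                              # ~1-2 min
print("I0 = %.3f nA" % (float(traj.metadata["I0_A"]) * 1e9))
for q, k in (("Up_mm_per_s", "max"), ("I_star", "min"), ("I_star", "max")):
    e = find_extremum(traj, q, k)
    print(f"{k} {q}: {e.value:+.3f} at y_p = {e.y_bp:+.1f} bp")
```

prints (coarse profile, axisymmetric mode):

```
I0 = -0.246 nA
max Up_mm_per_s: +192.100 at y_p = +82.6 bp
min I_star: -0.257 at y_p = -88.6 bp
max I_star: +0.081 at y_p = +110.8 bp
```

Read: the open-pore current is 0.246 nA (sign: positive current is defined
along +y, and the field points downward).  The particle accelerates from
~2.7 mm/s far from the pore to a ~180 mm/s plateau while threaded, blocks
about a quarter of the current as it enters (minimum of I\* near −89 bp,
i.e. half inserted) and enhances it ~8% as its counterion cloud exits
(maximum near +111 bp), with I\* returning to zero at ±300 bp.

The same studies are available from the shell, one CSV per sweep:

```sh
neksim run --preset fig3_E2 --profile coarse --out results/
neksim run --preset fig7_L50 --profile coarse --out results/
neksim benchmarks run          # closed-form oracle table
neksim solve --yp-bp -75 --export fields.vtk   # field snapshot for ParaView
```

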