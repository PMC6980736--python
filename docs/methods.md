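# Methods

`protrudesim` simulates single-cell, protrusion-driven (mesenchymal)
migration through a degradable viscoelastic extracellular matrix in a 2D
plane, as a coarse representation of 3D migration. Two coupled models
run in lockstep: an agent-based deformable cell and a particle-based
(SPH) continuum matrix. This note records the model equations as
implemented, the numerical choices, and what the reduced-size test
problems do and do not demonstrate.

Internal units are micrometre, second, nanonewton (stress in
nN/um^2 = kPa); configuration files use the SI units of the published
parameter values.

## Matrix (non-inertial SPH)

The matrix is discretised into particles on a square lattice at spacing
`dp = 2 um` carrying mass, density, an in-plane stress tensor and a
degradation factor `f_degr` in [0, 1]. Field interpolation uses a
Wendland C2 kernel with smoothing length `h = 2.6 um` and support `2h`,
normalised to unit plane integral. At micrometre scales inertia is
negligible, so momentum balance is overdamped: a pairwise Monaghan-type
viscous operator applied to the velocities,

    sum_j a_ij (v_i - v_j),
    a_ij = -m_i m_j (mu_i + mu_j) (x_ij . grad_i W_ij)
           / (rho_i rho_j (|x_ij|^2 + eta^2)),   eta = 0.01 h^2,

equals the symmetric-form divergence of the effective stress,
`m_i sum_j m_j (sigma_i/rho_i^2 + sigma_j/rho_j^2) . grad_i W_ij`, plus
body forces. The operator acts identically on both velocity components,
so each step solves one sparse graph Laplacian (Dirichlet rows for the
fixed rim) for two right-hand sides.

* Density is evaluated by kernel summation (self term included).
* The solid constitutive law is small-strain hypoelastic plane stress
  with a Jaumann spin correction; density, stress and positions advance
  with explicit Euler at `dt = 0.4 s`.
* Degradation multiplies `f_degr` by `exp(-rate*dt)` for targeted
  particles. Particles with `f_degr < 0.05` are classified fully
  degraded (fluid): they carry pure pressure
  `p = K_fluid (rho/rho0 - 1)` and are invisible to cell contact;
  partially degraded material blends
  `f*sigma_solid - (1-f)*p_fluid*I`. `K_fluid = 2 kPa` keeps the
  explicit pressure update stable at the production time step; density
  fluctuations of the fluid are then a few percent rather than <1%, an
  accepted trade-off.
* Stability at `dt = 0.4 s` for stiff parameter corners (400-Pa
  matrices, 10-kPa fiber overlays, contact) is obtained by taking the
  stress, fiber, contact and cell-coupling *tangents* implicitly in the
  velocity solve (a backward-Euler linearisation: the viscous Laplacian
  is augmented with `dt` times a pairwise stiffness bound). This leaves
  equilibria and slow dynamics unchanged and only damps sub-time-step
  transients.
* The solver reaches a relative residual of 1e-8 by conjugate
  gradients, preconditioned with an LU factorisation of a recent
  operator that is refreshed when iteration counts grow. Restarting
  from a snapshot therefore reproduces a run to solver tolerance
  (~1e-7 um over ten steps) rather than bit-for-bit; within one run,
  equal seeds give bitwise identical trajectories.

## Fibrillar overlay (strain stiffening)

Collagen-like nonlinearity is added as pairwise springs between all
solid particle pairs within kernel support of the reference lattice
(optionally only pairs within 30 degrees of a prescribed fiber
direction). The force on particle i is the anchored vector-difference
form

    F_i = - sum_j w_ij (f_degr,i f_degr,j) k_fib(eps_ij) (x_ij - x0_ij),

with `w_ij` the symmetric kernel-support weight and the stiffness
piecewise in the pair's length strain: zero in compression, `k0` up to
the onset strain `eps_s = 0.075`, and `k0 exp((eps-eps_s)/d_s)` with
`d_s = 0.033` beyond it. Numerical regularisations: a linear engagement
ramp over the first 0.5% strain makes the tension-only switch
continuous, and the exponent is capped at 10.

Because the kernel weighting does not by itself normalise the network
to a prescribed bulk modulus, a single coarse-graining factor is
computed from the reference lattice so that the affine, zero-lateral-
contraction secant modulus along the (fiber) direction equals `k0`;
`k0` is therefore interpreted in Pa.

A consequence of the anchored force form is worth recording: the force
always points along `x_ij - x0_ij`, so a uniaxially stretched network
generates **no lateral (Poisson) coupling** and its homogenized
uniaxial response is an affine sum over the discrete lattice
directions. The validation suite therefore compares the
displacement-controlled stretch harness against a hand-derived closed
form of exactly that affine lattice homogenization (matrix carried in
plane stress, lateral contraction from the transverse balance). The
alternative axially-resolved spring force (available behind
`FiberParams.axial_force`) does contract laterally and approaches the
isotropized angular-average law; it is validated qualitatively. The
stretch harness reaches quasi-static equilibrium by damped-Newton
sweeps (pseudo-time steps with implicit matrix/fiber tangents),
terminating when the largest free-particle force is below 1e-6 of the
applied load by default (1e-5 in the routine tests; the measured curve
is insensitive beyond ~1e-3).

## Cell

The cell is a closed ring of 235 boundary particles (radius 15 um,
segment length ~0.4 um) joined by viscoelastic segments. Passive
forces: linear segment springs (stiffness `k_s`, rest lengths `l0`), a
bending penalty `U = k_bend/(2 l0) sum theta_k^2` on the turning
angles, a weak area-conservation force `-k_A (A - A0) grad A`, and a
Hertz-like self-repulsion `k_rep (d_rep - d)^{3/2}` between particles
and non-adjacent segments. The overdamped velocity solve couples ring
neighbours through the axial cortex viscosity `eta_c`, contacting
matrix particles through viscous coefficients `Gamma_ik` (matrix
velocities staggered by one step), and the medium through
`gamma_liquid * l_i` per particle.

Numerical choices for the published time step:

* The stiff passive terms (springs, bending, adhesion springs, contact,
  and the actomyosin tension's geometric term) are linearised into a
  positive-semidefinite stiffness matrix and taken implicitly in the
  velocity solve (backward Euler). Explicit integration would require
  millisecond steps because bending and adhesion stiffnesses far exceed
  the per-particle drag.
* Bending lever arms are floored at half the resolution so bunched
  (slack) boundary particles cannot generate unbounded moments.
* Protrusion weakening of the cortex applies to stretching only;
  weakened segments keep the full stiffness under compression. Without
  this, boundary particles bunch into a slack reservoir that feeds a
  single runaway membrane spike. During maturation the window's
  compression stiffness is reduced to 0.1 `k_s` (a bending-limited
  buckling scale) so that the mechanosensing force loads the adhesion
  spring rather than a parasitic cortex chain to the fixed base.

### Cell-matrix contact (reconstructed)

No standard contact formulation exists for coupling a boundary-particle
cell to an SPH continuum; the implementation uses a Hertz-like normal repulsion
`k_con f_degr (d_c - s)^{3/2}` on solid particles closer than a
standoff `d_c` to the boundary polyline (equal and opposite on the
segment), plus a kernel-weighted viscous coupling
`Gamma = gamma0 max(f_degr, f_fluid) W(|s|)/W(0)` distributed to the
segment endpoints. Fully degraded particles feel no normal force (they
pass freely through the boundary) and only a weak residual drag. The
free constants were set once so that the single-protrusion growth
speed and length fall inside the published bands (1.5-5 um/min,
25-30 um) while the soft-vs-stiff migration trend is preserved:
`d_c = 1.0 um`, `gamma0 = 7e-4 N s/m` and residual fluid fraction
`f_fluid = 0.15`. Wider standoffs improve the growth band but block
body translocation; weaker coupling lets the tip occasionally race
through fluidised pockets. All three are configuration keys under
`contact.*`.

## Protrusion life cycle

The cycle follows the model definition: stochastic initiation at
rate `r_prot` per front particle (window of 41 particles, disjoint from
other protrusions; the first initiation polarizes the cell); growth for
`T_prot = 400 s` with force `F_prot max(0, n_hat . d_prot)` on the 7
central particles, cortex springs weakened a thousandfold, and
ungated tip degradation (rate 0.2/s within 2.4 um of the force
particles); growth-direction deflection toward degraded matrix at rate
`r_defl`, with the sensing disk restricted to the forward half-plane of
the tip (a symmetric disk makes the freshly carved tunnel behind the
tip the target and growth directions curl into loops); adhesion
formation 5 um beyond the tip with normalized kernel weights over solid
particles; maturation for `T_mat = 600 s` with the force-step clock
(step 0.1 `F_am`, threshold 98% of one step's extension, at most 10
steps, base fixed by a 1e6 drag multiplier on the outermost 4 window
particles per side); the final maturation factor
`min(1, 0.1 T_mat k / t_k)` from the k step times; cortex-driven
contraction per segment `min(f_mat,i, f_mat,j) f_curv F_am` with a
Gaussian curvature factor centred on `kappa0 = -0.15`; force-dependent
disassembly `r_off = r_off_min + r_off_0 exp(-zeta_hat |F|/(f_mat
F_am))` with rupture at `|F| >= f_rupt f_mat F_am`; and a 400-s
finishing phase before the window is released.

The dimensionless `zeta_diss = 2e4` of the parameter table is not
dimensionally consistent with the disassembly exponent; the
implementation uses `zeta_hat = zeta_diss/1000 = 20`, which reproduces
the intended qualitative decay (rate near `r_off_min` once the load
exceeds a small fraction of the full contractile force).

Mechanosensing in this implementation discriminates matrix stiffness
dynamically: after each force step the adhesion extension approaches
its new equilibrium from below with a deficit proportional to the
anchor's creep velocity seen through the tip's drag. On stiff matrices
the creep stops quickly and the clock ticks through its ten steps; on
soft matrices sustained creep holds the extension below the 98%
threshold and few or no steps occur. The resulting stiffness response
is steeper (more switch-like across 50-400 Pa) than a gradual
staircase, but preserves the monotone trend: stiffer
matrix, higher final `f_mat`, stronger protrusion, faster migration.

## Synthetic scenarios and problem sizes

All inputs are generated programmatically; the study conditions are
the published parameter table. The routine test suite and the
acceptance script use reduced problem sizes chosen so that a full
analysis remains a desk-scale computation:

* single-protrusion micro-experiments: 50-um matrix disk (~1950
  particles), one seeded protrusion, one growth phase (400 s);
* stiffness-trend replication: 50-um disk, 3000-s migrations, two
  replicates per stiffness at 50 and 200 Pa;
* stretch validation: 40x20-um blocks.

What these show: the mechanics (patch test, stretch curves), the
protrusion cycle, the mechanosensing direction, and the soft-vs-stiff
migration ordering. What they do not show: full 6-hour statistics
(protrusion counts, lifetime distributions, MSD exponents over hours),
the plateau above 200 Pa, or the enforced-count orderings, which
require the full problem size (150-um domain, 12 replicates,
6-hour runs — an overnight computation with this implementation); and
none of the runs say anything about real cells beyond the model's own
assumptions (no contact guidance, no chemotaxis, 2D plane, coarse
fiber homogenization).

## Known limitations

* The growth dynamics is the least constrained part: tip speed emerges
  from the reconstructed contact model together with growth-direction
  wander, and per-seed growth-phase lengths at 200 Pa are bimodal — a
  dominant mode at 22-30 um and a minority of seeds (roughly a third)
  in which the deflection rule chases the protrusion's own degraded
  trail until the direction turns away and growth stalls at 3-12 um.
  Seed means therefore scatter around ~17-24 um against the 25-30 um
  reference band.  Removing the stall mode (outward-axis filters or
  cone clamps on the growth direction) removes the wander that limits
  tip speed in cleared tunnels and produces uniform unphysical runaway
  growth, so the wander-limited rule is kept.
* The cell is only meaningfully hindered where matrix is solid, and
  degradation is fast compared to real proteolysis.
* The fibrillar overlay is a mechanical homogenization: no discrete
  fibers, pores, buckling forces or remodelling.
* Self-intersection of the boundary is discouraged (repulsion) but not
  geometrically impossible under extreme forcing.
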