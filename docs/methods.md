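# Methods

## The model

`macroioncg` models a dilute solution of nanometre-scale macroions — soluble
multi-charged species such as Keplerate polyoxometalates ({Mo72Fe30}-type
clusters), functionalized fullerenes or dendrimers — at coarse-grained (CG)
resolution:

* **Macroion**: a rigid hollow sphere of CG beads on its surface. Beads are
  either uncharged (van der Waals interactions only) or carry one negative
  elementary charge (van der Waals + electrostatics). The surface beads of
  one macroion move as a single rigid body: shape, size and charge layout
  are fixed during dynamics, which matches the rigidity of the molecular
  clusters being modelled. Charge *redistribution* is represented by
  building alternative static layouts, not by mobile surface charges.
* **Counterions**: free beads with charge +1, one per surface charge, so
  every system is exactly electroneutral.
* **Solvent**: free uncharged beads. One solvent bead stands for four water
  molecules (MARTINI-style CG water); surface beads and counterions share
  the solvent's size and LJ parameters, which makes the solvent a good
  solvent for all species.

All interactions are pairwise: the 12-6 Lennard-Jones potential truncated
(not shifted) at `r_c`,

    U_LJ(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ],  r <= r_c;  0 otherwise,

with a single global `eps` and `sigma` for all species pairs, plus the bare
Coulomb interaction `U = k_q q_a q_b / r`, `k_q = 1/(4 pi eps_0)`, handled
in periodic boundary conditions by conventional Ewald summation. Pairs
within one rigid body are excluded from both sums; their contribution is
constant under rigid motion.

## Units

Reduced LJ units with mass, sigma, epsilon and the Boltzmann constant set
to 1. The default physical references are sigma = 5 Å, eps = 4.5 kJ/mol and
a bead mass of 72 g/mol (four waters), giving the time unit
tau = sigma*sqrt(m/eps) = 2 ps, so the reduced timestep 0.005 is 10 fs. The
reduced Coulomb prefactor that follows from vacuum permittivity is
k_q = e²/(4 pi eps_0 eps sigma) ≈ 61.75; this strong coupling (Bjerrum
length ≈ 62 sigma) is what makes counterions condense on the macroion
surface and mediate attraction between like-charged macroions. All three
base references are configurable on `UnitSystem`.

Standard state points, in reduced units: temperature 1.0, pressure 0.1,
timestep 0.005, LJ cutoff 2.5 (12.5 Å).

## Builder

Surface beads are placed by a deterministic golden-angle (Fibonacci)
spiral lattice with the bead count chosen so the mean nearest-neighbour
spacing equals one bead diameter under hexagonal packing,
`N = (8 pi/sqrt(3)) (R/d)²`; a 2.5-sigma-radius macroion gets 91 beads.
The covering is reproducible and quasi-uniform (≥95 % of nearest-neighbour
spacings within [0.8, 1.2] d); the bead count per size is emergent from
this rule, not hard-coded.

Charge layouts:

* `random` — seeded uniform choice of surface beads;
* `equatorial` — n charges snapped to covering beads in the |z| ≤ d/2
  band, evenly spaced in azimuth;
* `equator_plus_tropics` — three rings (equator plus ±30° latitude by
  default, configurable); with n charges the tropics take n//3 each and
  the equator the remainder, an even split for the 20-charge case;
* `icosidodecahedron` — 30 charges at the vertices of the rectified
  icosahedron, the possible charge-site geometry of {Mo72Fe30}. Default
  mode inserts charged beads exactly at the vertices (added to the
  uncharged covering) because snapping to the nearest covering bead
  perturbs the belt-zone counts the analysis is about; a `snap` mode is
  available.
* `cube_vertices` (8 charges) and `all_charged` — isotropic controls.

The canonical icosidodecahedron orientation has a 5-fold axis (pentagonal
face normal) along +z; helper axes for the 3-fold (triangular face) and
2-fold (vertex) directions are provided. For R = 1.25 nm the vertex
z-levels along the 5-fold axis are ±1.063 nm (5 each), ±0.657 nm (5 each)
and 0 (10).

Solution systems are assembled by seeded rejection sampling in an
orthorhombic periodic box: random macroion poses without overlap, then
counterions and solvent inserted uniformly subject to (i) staying out of
every macroion cavity and (ii) a minimum separation of 0.8 bead diameters
from every placed bead. Solvent count = density × (box volume − macroion
excluded volume).

## Engine

* **Electrostatics**: conventional Ewald summation (real-space erfc sum +
  reciprocal structure-factor sum + self term + intra-body exclusion
  corrections), tinfoil boundary conditions, neutral systems only. The
  splitting parameter and k-cutoff follow from one accuracy parameter
  (default 1e-5; 1e-4 in the packaged scenarios):
  `alpha = s/r_cut`, `k_cut = 2 alpha s`, `s = sqrt(-ln(accuracy))`.
  The result is independent of the split (±30 % change in alpha moves the
  energy by < 1e-5 relative) and matches brute-force direct lattice sums
  and the rock-salt Madelung constant to 4 significant figures.
* **Integration**: BAOAB splitting. With zero friction this is exactly
  velocity-Verlet (NVE); with friction it is a Langevin thermostat (NVT)
  applied to free particles and to rigid-body translational and angular
  momenta. Rigid bodies use centre-of-mass + quaternion states with
  principal-frame inertia; during each half-drift the body-frame angular
  velocity is held constant, an excellent approximation for the nearly
  spherical bead shells used here (principal moments differ by < 0.5 %),
  and one that preserves intra-body distances to machine precision.
  Torque-free bodies conserve angular momentum exactly (it is only
  modified by torques).
* **NPT**: an isotropic Berendsen rescaling on top of the Langevin
  thermostat, driven by the instantaneous virial pressure. It is used for
  density equilibration only, as production sampling is NVT. For rigid
  systems the bead-based pair virial is an approximation to the molecular
  virial; for free-particle systems it is exact.
* **Neighbour lists**: periodic k-d-tree Verlet lists with a 0.3 sigma
  skin, rebuilt on a half-skin displacement trigger; Coulomb real-space
  pairs are kept on a separate, longer-cutoff list over charged particles
  only.

### Numerical notes

* The LJ truncation is unshifted, matching the model's stated form. The
  potential therefore jumps by U(r_c) ≈ −0.016 eps whenever a pair crosses
  the cutoff, which injects random-walk energy noise in dense fluids. NVE
  conservation is consequently assessed on a compressed fcc crystal whose
  neighbour shells straddle the cutoff gap (no crossings): drift is then
  < 1e-3 relative over 1e4 steps at dt = 0.005.
* Forces are exact gradients of the total potential (checked against
  central differences at h = 1e-6), and per-step energies decompose into
  LJ, Coulomb real/reciprocal/self/exclusion and kinetic terms.
* Particle pairs closer than 0.1 sigma abort the run (unstable build), and
  NVE runs abort if the total energy changes by > 10 % in one step.

## Analysis

* **RDF**: minimum-image pair histograms normalised by ideal-gas shell
  counts, frame-averaged, with the running coordination number
  n(r) = integral of 4 pi rho r² g. The nearest-neighbour count integrates
  to the first minimum after the second peak; peaks are detected on a
  Savitzky-Golay smoothed g(r) (window 7, order 3, configurable), must
  exceed g = 1.5, and must enclose at least half a neighbour — dilute
  unassembled systems return 0 with a flag.
* **Clusters**: single-linkage components of the macroion graph with an
  edge when the surface-to-surface distance (centre distance − R_i − R_j)
  is within a cutoff. Default cutoff 2.0 sigma = 1.0 nm, the counterion
  mediation distance: macroions are "assembled" when counterions can still
  bridge them. Cluster sizes always partition the macroion set.
* **Surface gaps**: per clustered macroion, the gap to its nearest
  clustered neighbour.
* **Belt anisotropy**: the belt is the spherical zone |r·axis| ≤ w/2 with
  the exact zone area 2 pi R w; the boundary is inclusive, which matters
  because icosidodecahedron vertex levels fall exactly on or near the
  0.7 nm half-width for the 1.4 nm belt. With 30 vertex charges at
  R = 1.25 nm: 20/30 charges in the belt on the 5-fold axis (+57.1 %
  density vs the rest) and 12/30 on the 3-fold axis (−47.6 %). The belt
  width itself comes from the two-sphere parabolic gap model
  gap(y) ≈ g0 + y²/R: with equilibrium gap 0.6 nm and mediation range
  1.0 nm, width = 2 sqrt((1.0−0.6)·1.25) = 1.4 nm. The parabolic result is
  within 15 % of the exact root-found two-sphere solution.
* **Electric fields**: direct minimum-image Coulomb sums on grids (not
  Ewald) — the field maps are a local visualisation, and direct sums keep
  the computation trivially verifiable. Points within 0.25 sigma of a
  charge are masked. Exported as CSV and legacy-VTK structured points.
* **Morphology**: aggregate planarity is the smallest/largest eigenvalue
  ratio of the gyration tensor of macroion centres (< 0.2 ≈ flat,
  monolayer-like). Growth-curve shape is quantified by logistic-vs-linear
  fit R².

## Scaled-down scenarios and what they can show

Production-scale studies of this system use dozens of macroions, millions
of solvent beads and >100 ns of dynamics. The packaged scenarios are desk
scale by design and probe mechanism and direction, not converged
morphology:

* `nvt_temperature_check` — 1000 solvent beads at density 0.8, 5e4
  sampling steps: the thermostat holds the reduced temperature at the set
  point within sampling error.
* `dimer_attraction` — two 2.5-sigma macroions with 20 random surface
  charges each, released from a mediation-range surface gap (2.5 sigma) in
  a liquid-density (0.7) CG solvent bath, counterions initially condensed
  on the charged sites, after a pinned-body equilibration of the bath.
  With charges on, counterion mediation pulls the pair into contact and
  the mean potential energy of the bound tail of the trajectory lies well
  below the separated early window. With every charge switched off
  (identical construction) the liquid solvent screens the bare
  surface-surface van der Waals attraction, the pair does not durably
  bind, and the energy difference collapses to residual noise. The design
  follows from two desk-scale constraints established while building the
  scenario: (i) at this coupling, counterions cannot hop between surface
  sites on desk timescales, so *fixed*-gap energy comparisons between
  independently initialised conditions inherit quenched-disorder offsets
  of the same size as the signal — a free, continuously evolving
  trajectory self-anneals the ion distribution the way real assembly
  does; and (ii) the van der Waals control is only small in a
  liquid-density bath (in dilute or absent solvent, bare CG surfaces
  attract strongly at contact, and the charge-off control no longer
  collapses).
* `scenario_monolayer_demo` — 8 macroions (2.5 sigma, 10 charges,
  equatorial or control layout), counterions and reduced solvent (0.12)
  in a 16-sigma box, 2.5e4 NVT steps at reduced translational friction
  0.2 and rotational friction 0.05 (both lowered to speed diffusive
  annealing). Reports cluster kinetics, RDF, gaps, the aggregate
  planarity ratio (tail-averaged, graph-unwrapped across the periodic
  boundary) and the bond-equator alignment: the mean |cos| between each
  linked centre-centre bond and the partners' equatorial normals.
  A caveat established during development bounds what these runs can
  show: once macroions bind, the deeply condensed counterions lock the
  relative orientation, so orientations anneal only during the diffusive
  approach. Aggregate shape at this scale therefore retains large
  seed-to-seed scatter — across the seeds examined, the planarity ratio
  of a same-seed run pair orders in the monolayer direction (equatorial
  flatter) in most but not all seeds, and the bond-equator alignment of
  equatorial layouts (0.42-0.43) sits below the isotropic expectation
  (0.5) but inside the scatter of small-sample controls (0.41-0.50).
  Resolving the direction reliably needs larger aggregates and longer
  annealing than desk-scale runs afford. Full monolayer formation is
  beyond this scale.

The synthetic systems emulate composition, interaction strengths and state
points of the real CG model; they do not emulate production system sizes,
assembly timescales, or hydrodynamics (Langevin dynamics has no momentum
conservation for the solvent). Passing tests therefore demonstrate the
correctness of the machinery and the direction of the physical effects,
not converged self-assembly morphology.

## Known limitations

* PPPM-style mesh Ewald is not implemented; conventional Ewald is exact
  but scales worse, which is irrelevant at desk scale.
* Pressure for rigid-body systems uses the bead-based virial
  (approximate); NPT is for density equilibration only.
* Non-spherical macroions, mobile surface charges, bonded interactions and
  anisotropic boxes are out of scope.
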