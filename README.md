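# macroioncg

Coarse-grained modelling of **macroion solutions**: why do highly
symmetric, like-charged nanometre-scale ions — Keplerate polyoxometalates
such as {Mo72Fe30}, functionalized fullerenes, dendrimers — self-assemble
into flat 2-D monolayers (the precursor of hollow "blackberry" shells)
instead of 3-D aggregates?

The package is a self-contained toolkit for the CG model behind that
question, aimed at researchers in soft-matter / structural molecular
modelling:

* **builder** — rigid hollow-sphere macroion templates (Fibonacci-lattice
  bead coverings, 2.5–10 nm) with configurable surface-charge layouts
  (random, equatorial, equator + tropics, icosidodecahedron vertices, cube
  vertices, fully charged), assembled into electroneutral periodic boxes
  with counterions and CG solvent;
* **engine** — reduced-unit MD: truncated 12-6 Lennard-Jones plus Coulomb
  electrostatics by conventional Ewald summation, quaternion rigid-body
  dynamics for macroions, velocity-Verlet / Langevin (BAOAB) / Berendsen
  NVE-NVT-NPT ensembles, seeded and restartable;
* **analysis** — radial distribution functions and nearest-neighbour
  counts, single-linkage cluster kinetics, surface-gap statistics,
  equatorial **belt** charge-density anisotropy, belt-width geometry,
  electric-field grids, aggregate planarity;
* **io / cli** — LAMMPS data/dump and XYZ formats, TOML scenario configs,
  CSV/VTK exports, and a `macroioncg` command line.

## The physics in one paragraph

In reduced LJ units (sigma = 5 Å, eps = 4.5 kJ/mol, bead = 4 waters,
k_B = 1) the vacuum Coulomb prefactor is k_q = e²/(4 pi eps_0 eps sigma) ≈
61.7, so counterions condense onto charged surface beads and mediate
attraction between like-charged macroions. Counterions can only bridge two
macroions where their surface gap is below ~1.0 nm; around the contact
point of two spheres of radius R at equilibrium gap g0 ≈ 0.6 nm the gap
grows as g0 + y²/R, so mediation is confined to a **belt** of width
2·sqrt((1.0−0.6)·R) ≈ 1.4 nm for R = 1.25 nm. For 30 charges on the
vertices of an icosidodecahedron (the {Mo72Fe30} charge-site geometry),
that belt holds 20/30 charges when a pentagonal face faces out of the
assembly plane — a charge density ~57 % **higher** than the rest of the
surface — but only 12/30 (~48 % lower) for a triangular face. The apparent
charge anisotropy of a perfectly symmetric solid breaks the symmetry,
selects the pentagon orientation, and confines growth to a plane.

## Worked example

```python
from macroioncg.builder import ChargeLayout, icosidodecahedron_axes, make_template
from macroioncg.analysis import belt_charge_density, belt_width_from_gaps

# 2.5-nm macroion (R = 2.5 sigma) with 30 icosidodecahedron-vertex charges
t = make_template(2.5, ChargeLayout("icosidodecahedron"))
axes = icosidodecahedron_axes()

w = 2.8                          # 1.4 nm belt width in reduced units
pent = belt_charge_density(t, axes["five_fold"], w)
tri = belt_charge_density(t, axes["three_fold"], w)
print(f"pentagon: {pent.charges_in_belt}/30 in belt, "
      f"{pent.percent_difference:+.1f}%")
print(f"triangle: {tri.charges_in_belt}/30 in belt, "
      f"{tri.percent_difference:+.1f}%")
print(f"belt width: {belt_width_from_gaps(0.6, 1.0, 1.25):.2f} nm")
```

prints

```
pentagon: 20/30 in belt, +57.1%
triangle: 12/30 in belt, -47.6%
belt width: 1.41 nm
```

i.e. sitting on a pentagon concentrates charge in the mediation belt
(+57 %), sitting on a triangle depletes it (−48 %), and the belt geometry
itself follows from the two measured gaps.

Run a scaled-down assembly demo and the unit conversions from the shell:

```
macroioncg scenario monolayer --seed 0 --out out/demo
macroioncg convert-units 0.005 time       # -> 10 fs
```

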