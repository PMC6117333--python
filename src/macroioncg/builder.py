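"""Macroion templates and periodic solution systems.

A macroion is modelled as a rigid hollow sphere: a quasi-uniform covering of
CG beads on a spherical surface, a subset of which carry one negative
elementary charge each (the rest interact only through van der Waals
forces).  This module builds such templates for a menu of charge layouts
(random, equatorial, equator plus tropics, icosidodecahedron vertices, cube
vertices, fully charged) and assembles electroneutral periodic boxes of
macroions, monovalent counterions and CG solvent beads.

All lengths are in reduced units (bead diameter sigma = 1 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .units import DEFAULT_UNITS, UnitSystem

_GOLDEN = (1.0 + np.sqrt(5.0)) / 2.0

LAYOUT_NAMES = ("random", "equatorial", "equator_plus_tropics",
                "icosidodecahedron", "cube_vertices", "all_charged")


# ---------------------------------------------------------------------------
# surface geometry
# ---------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors from the golden-angle spiral lattice."""
    if n < 1:
        raise ValueError("need at least one point")
    i = np.arange(n)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = 2.0 * np.pi * i / _GOLDEN
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack((rho * np.cos(theta), rho * np.sin(theta), z))


def place_surface_beads(radius: float, bead_diameter: float = 1.0) -> np.ndarray:
    """Deterministic quasi-uniform covering of a sphere of given radius.

    Bead count is chosen so the mean nearest-neighbour spacing of the
    Fibonacci lattice equals ``bead_diameter`` under hexagonal packing:
    N = (8*pi/sqrt(3)) * (radius/bead_diameter)**2.

    Returns an (N, 3) array of body-frame positions, all of norm ``radius``.
    """
    if radius < bead_diameter:
        raise ValueError(
            f"radius {radius} smaller than bead diameter {bead_diameter}")
    n = int(round(8.0 * np.pi / np.sqrt(3.0) * (radius / bead_diameter) ** 2))
    return radius * fibonacci_sphere(max(n, 4))


def _icosahedron_vertices() -> np.ndarray:
    """12 unit vertices of an icosahedron with a 5-fold axis along +z."""
    top = np.array([[0.0, 0.0, 1.0]])
    bot = -top
    k = np.arange(5)
    upper = np.column_stack((
        2.0 / np.sqrt(5.0) * np.cos(2 * np.pi * k / 5),
        2.0 / np.sqrt(5.0) * np.sin(2 * np.pi * k / 5),
        np.full(5, 1.0 / np.sqrt(5.0)),
    ))
    lower = np.column_stack((
        2.0 / np.sqrt(5.0) * np.cos(2 * np.pi * (k + 0.5) / 5),
        2.0 / np.sqrt(5.0) * np.sin(2 * np.pi * (k + 0.5) / 5),
        np.full(5, -1.0 / np.sqrt(5.0)),
    ))
    return np.vstack((top, upper, lower, bot))


def icosidodecahedron_vertices(radius: float) -> np.ndarray:
    """30 vertices of an icosidodecahedron at distance ``radius`` from origin.

    Constructed as the rectified icosahedron (edge midpoints rescaled to the
    sphere), in a canonical orientation with a 5-fold symmetry axis along +z
    (i.e. a pentagonal face perpendicular to z).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    v = _icosahedron_vertices()
    # edges = vertex pairs at the icosahedron edge length (min nonzero dist)
    d = np.linalg.norm(v[:, None, :] - v[None, :, :], axis=-1)
    iu, ju = np.triu_indices(len(v), k=1)
    edge_len = d[iu, ju].min()
    mask = np.isclose(d[iu, ju], edge_len, rtol=1e-9)
    mids = 0.5 * (v[iu[mask]] + v[ju[mask]])
    mids /= np.linalg.norm(mids, axis=1)[:, None]
    order = np.lexsort((mids[:, 1], mids[:, 0], -np.round(mids[:, 2], 12)))
    return radius * mids[order]


def icosidodecahedron_axes() -> dict[str, np.ndarray]:
    """Canonical symmetry axes of :func:`icosidodecahedron_vertices` output.

    ``five_fold`` passes through a pentagonal face (the +z axis of the
    canonical orientation); ``three_fold`` passes through a triangular face
    (an icosahedron face centre); ``two_fold`` passes through a vertex.
    """
    v = _icosahedron_vertices()
    five = np.array([0.0, 0.0, 1.0])
    # a face of the icosahedron: top vertex and two adjacent upper-ring ones
    face_center = (v[0] + v[1] + v[2]) / 3.0
    three = face_center / np.linalg.norm(face_center)
    verts = icosidodecahedron_vertices(1.0)
    two = verts[np.argmax(verts[:, 2])]
    return {"five_fold": five, "three_fold": three, "two_fold": two}


def cube_vertices(radius: float) -> np.ndarray:
    """8 vertices of a cube inscribed in a sphere of given radius."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    signs = np.array([[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                      for sz in (-1, 1)], dtype=float)
    return radius * signs / np.sqrt(3.0)


# ---------------------------------------------------------------------------
# templates and layouts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChargeLayout:
    """Recipe for distributing charges over a macroion surface.

    ``name`` is one of LAYOUT_NAMES.  ``n_charges`` is the number of unit
    charges; forced to 30 for the icosidodecahedron layout and 8 for cube
    vertices.  ``parameters`` may hold ``tropic_latitude_deg`` (default 30)
    for equator_plus_tropics and ``mode`` ("insert" or "snap") for the
    polyhedral layouts.
    """

    name: str
    n_charges: int = 0
    parameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in LAYOUT_NAMES:
            raise ValueError(f"unknown layout {self.name!r}")
        forced = {"icosidodecahedron": 30, "cube_vertices": 8}
        if self.name in forced and self.n_charges not in (0, forced[self.name]):
            raise ValueError(
                f"{self.name} layout forces n_charges = {forced[self.name]}")
        if self.name in forced:
            object.__setattr__(self, "n_charges", forced[self.name])


@dataclass(frozen=True)
class MacroionTemplate:
    """Rigid hollow-sphere macroion in its body frame.

    positions: (N, 3) bead positions, all on the sphere of ``radius``;
    charges: (N,) integer charges, each 0 or -1.
    """

    radius: float
    bead_diameter: float
    positions: np.ndarray
    charges: np.ndarray
    layout: ChargeLayout | None = None

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        chg = np.asarray(self.charges, dtype=int)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "charges", chg)
        if pos.ndim != 2 or pos.shape[1] != 3 or len(pos) != len(chg):
            raise ValueError("positions must be (N,3) matching charges (N,)")
        r = np.linalg.norm(pos, axis=1)
        if not np.allclose(r, self.radius, atol=1e-9 * max(1.0, self.radius)):
            raise ValueError("all beads must lie on the spherical surface")
        if not np.all(np.isin(chg, (0, -1))):
            raise ValueError("bead charges must be 0 or -1")

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def n_charged(self) -> int:
        return int(np.count_nonzero(self.charges))

    @property
    def total_charge(self) -> int:
        return int(self.charges.sum())

    def surface_charge_density(self, units: UnitSystem = DEFAULT_UNITS) -> float:
        """|Q| e / (4 pi R^2) in C/m^2, using the unit system's sigma."""
        from scipy.constants import e as _e
        r_m = units.to_real(self.radius, "length") * 1e-10
        return abs(self.total_charge) * _e / (4.0 * np.pi * r_m**2)

    @property
    def mass(self) -> float:
        """total reduced mass (each bead has unit reduced mass)."""
        return float(self.n_beads)

    def inertia_tensor(self) -> np.ndarray:
        """Body-frame inertia tensor of the equal-mass bead shell."""
        p = self.positions
        r2 = np.einsum("ij,ij->i", p, p)
        return np.einsum("i,jk->jk", r2, np.eye(3)) - p.T @ p


def uncharged_template(radius: float, bead_diameter: float = 1.0) -> MacroionTemplate:
    pos = place_surface_beads(radius, bead_diameter)
    return MacroionTemplate(radius, bead_diameter, pos,
                            np.zeros(len(pos), dtype=int))


def _snap_to_beads(targets: np.ndarray, beads: np.ndarray) -> np.ndarray:
    """Greedy assignment of each target point to a distinct nearest bead."""
    tree = cKDTree(beads)
    k = min(len(beads), len(targets) + 8)
    _, idx = tree.query(targets, k=k)
    idx = np.atleast_2d(idx)
    chosen: list[int] = []
    used: set[int] = set()
    for row in idx:
        for j in row:
            if j not in used:
                chosen.append(int(j))
                used.add(int(j))
                break
        else:
            raise ValueError("could not snap all charge sites to distinct beads")
    return np.array(chosen, dtype=int)


def _ring_indices(template: MacroionTemplate, latitudes, counts) -> np.ndarray:
    """Beads approximating evenly-azimuthal rings at given latitudes.

    For each ring, candidate beads are restricted to the latitude band
    |z - z_ring| <= bead_diameter/2 (widened if the band holds too few
    beads), then assigned greedily to the evenly spaced target azimuths.
    """
    pos = template.positions
    z = pos[:, 2]
    phi_beads = np.arctan2(pos[:, 1], pos[:, 0])
    used: set[int] = set()
    chosen: list[int] = []
    for lat, m in zip(latitudes, counts):
        z_ring = template.radius * np.sin(lat)
        half_band = template.bead_diameter / 2
        while True:
            cand = [i for i in np.flatnonzero(np.abs(z - z_ring) <= half_band)
                    if i not in used]
            if len(cand) >= m:
                break
            half_band *= 1.5
        cand = np.array(cand)
        for phi_t in 2.0 * np.pi * np.arange(m) / max(m, 1):
            dphi = np.angle(np.exp(1j * (phi_beads[cand] - phi_t)))
            order = np.argsort(np.abs(dphi))
            for j in cand[order]:
                if j not in used:
                    used.add(int(j))
                    chosen.append(int(j))
                    break
    return np.array(chosen, dtype=int)


def assign_charges(template: MacroionTemplate, layout: ChargeLayout,
                   seed: int = 0) -> MacroionTemplate:
    """Return a template with the layout's charges assigned.

    Polyhedral layouts (icosidodecahedron, cube_vertices) default to
    inserting charged beads exactly at the polyhedron vertices, added to the
    uncharged covering ("insert" mode); "snap" mode instead charges the
    nearest existing covering beads.
    """
    pos = template.positions
    n = layout.n_charges
    if layout.name == "all_charged":
        n = template.n_beads
    if layout.name not in ("icosidodecahedron", "cube_vertices") \
            and n > template.n_beads:
        raise ValueError(
            f"{n} charges requested but template has {template.n_beads} beads")

    mode = layout.parameters.get("mode", "insert")
    if layout.name in ("icosidodecahedron", "cube_vertices"):
        verts = (icosidodecahedron_vertices(template.radius)
                 if layout.name == "icosidodecahedron"
                 else cube_vertices(template.radius))
        if mode == "insert":
            new_pos = np.vstack((pos, verts))
            charges = np.zeros(len(new_pos), dtype=int)
            charges[len(pos):] = -1
            return replace(template, positions=new_pos, charges=charges,
                           layout=layout)
        idx = _snap_to_beads(verts, pos)
    elif layout.name == "all_charged":
        idx = np.arange(template.n_beads)
    elif layout.name == "random":
        rng = np.random.default_rng(seed)
        idx = rng.choice(template.n_beads, size=n, replace=False)
    elif layout.name == "equatorial":
        idx = _ring_indices(template, np.array([0.0]), np.array([n]))
    elif layout.name == "equator_plus_tropics":
        lat = np.deg2rad(layout.parameters.get("tropic_latitude_deg", 30.0))
        n_trop = n // 3
        n_eq = n - 2 * n_trop
        idx = _ring_indices(template, np.array([0.0, lat, -lat]),
                            np.array([n_eq, n_trop, n_trop]))
    else:  # pragma: no cover - guarded by ChargeLayout
        raise ValueError(layout.name)

    charges = np.zeros(template.n_beads, dtype=int)
    charges[idx] = -1
    return replace(template, charges=charges, layout=layout)


def make_template(radius: float, layout: ChargeLayout,
                  bead_diameter: float = 1.0, seed: int = 0) -> MacroionTemplate:
    """Covering plus charge layout in one call."""
    return assign_charges(uncharged_template(radius, bead_diameter), layout,
                          seed=seed)


# ---------------------------------------------------------------------------
# solution systems
# ---------------------------------------------------------------------------

def _random_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)


def quaternion_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix (body -> lab) of a unit quaternion (w, x, y, z)."""
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def minimum_image(dr: np.ndarray, box: np.ndarray) -> np.ndarray:
    return dr - box * np.round(dr / box)


@dataclass
class Macroion:
    """One placed rigid macroion: template index + pose."""
    template_index: int
    com: np.ndarray
    quaternion: np.ndarray

    def lab_positions(self, template: MacroionTemplate) -> np.ndarray:
        return self.com + template.positions @ quaternion_matrix(self.quaternion).T


@dataclass
class SimulationSystem:
    """Periodic box of rigid macroions, counterions and solvent beads.

    Coordinates live in the box-centred cell [-L/2, L/2); the minimum-image
    convention applies throughout.  Counterions carry +1, solvent 0.
    """

    box: np.ndarray
    templates: list[MacroionTemplate]
    macroions: list[Macroion]
    counterions: np.ndarray          # (Nc, 3)
    solvent: np.ndarray              # (Ns, 3)
    bead_diameter: float = 1.0

    @property
    def n_counterions(self) -> int:
        return len(self.counterions)

    @property
    def n_solvent(self) -> int:
        return len(self.solvent)

    @property
    def net_charge(self) -> int:
        macro = sum(self.templates[m.template_index].total_charge
                    for m in self.macroions)
        return macro + self.n_counterions

    def macroion_bead_positions(self) -> np.ndarray:
        if not self.macroions:
            return np.empty((0, 3))
        return np.vstack([m.lab_positions(self.templates[m.template_index])
                          for m in self.macroions])

    def macroion_centers(self) -> np.ndarray:
        if not self.macroions:
            return np.empty((0, 3))
        return np.vstack([m.com for m in self.macroions])

    def validate(self) -> None:
        """Raise if any structural invariant is violated."""
        if self.net_charge != 0:
            raise ValueError(f"system not electroneutral: net {self.net_charge}")
        mobile = np.vstack([p for p in (self.counterions, self.solvent)
                            if len(p)]) if (len(self.counterions) or
                                            len(self.solvent)) else None
        if mobile is not None:
            for m in self.macroions:
                t = self.templates[m.template_index]
                d = np.linalg.norm(minimum_image(mobile - m.com, self.box),
                                   axis=1)
                if np.any(d < t.radius - self.bead_diameter / 2):
                    raise ValueError("mobile particle inside a macroion cavity")


def _rejection_fill(rng, n_wanted, box, existing, centers, radii,
                    min_dist, bead_diameter, max_batches=2000):
    """Uniform insertion with cavity and overlap rejection."""
    accepted = np.empty((0, 3))
    batch = max(4 * n_wanted, 128)
    for _ in range(max_batches):
        if len(accepted) >= n_wanted:
            break
        cand = rng.uniform(-box / 2, box / 2, size=(batch, 3))
        ok = np.ones(len(cand), dtype=bool)
        for c, r in zip(centers, radii):
            d = np.linalg.norm(minimum_image(cand - c, box), axis=1)
            ok &= d >= r + bead_diameter / 2
        cand = cand[ok]
        if len(cand) == 0:
            continue
        pool = np.vstack([existing, accepted]) if len(existing) or \
            len(accepted) else np.empty((0, 3))
        if len(pool):
            tree = cKDTree(np.mod(pool + box / 2, box), boxsize=box)
            d, _ = tree.query(np.mod(cand + box / 2, box), k=1)
            cand = cand[d >= min_dist]
        if len(cand) > 1:
            keep = np.ones(len(cand), dtype=bool)
            ctree = cKDTree(np.mod(cand + box / 2, box), boxsize=box)
            for i, j in sorted(ctree.query_pairs(min_dist)):
                if keep[i]:
                    keep[j] = False
            cand = cand[keep]
        room = n_wanted - len(accepted)
        accepted = np.vstack([accepted, cand[:room]]) if len(accepted) else \
            cand[:room]
    if len(accepted) < n_wanted:
        raise RuntimeError(
            f"could only place {len(accepted)}/{n_wanted} particles; "
            "box too small or density too high")
    return accepted


def build_system(templates: list[MacroionTemplate], counts: list[int],
                 box, solvent_density: float = 0.7, seed: int = 0,
                 overlap_factor: float = 0.8,
                 max_tries: int = 500) -> SimulationSystem:
    """Assemble a random electroneutral solution system.

    counterion count = total macroion charge magnitude; solvent count =
    solvent_density * (box volume - macroion excluded volume).  Insertion is
    rejection-sampled: no particle inside a macroion cavity, no bead pair
    from different bodies closer than overlap_factor * bead_diameter.
    """
    box = np.asarray(box, dtype=float) * np.ones(3)
    rng = np.random.default_rng(seed)
    bead_d = templates[0].bead_diameter if templates else 1.0
    min_dist = overlap_factor * bead_d

    macroions: list[Macroion] = []
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for t_idx, count in enumerate(counts):
        t = templates[t_idx]
        if 2 * t.radius + bead_d > box.min():
            raise ValueError("box too small for macroion diameter")
        for _ in range(count):
            for _try in range(max_tries):
                com = rng.uniform(-box / 2, box / 2, size=3)
                ok = all(np.linalg.norm(minimum_image(com - c, box)) >=
                         t.radius + r + bead_d
                         for c, r in zip(centers, radii))
                if ok:
                    macroions.append(Macroion(t_idx, com,
                                              _random_quaternion(rng)))
                    centers.append(com)
                    radii.append(t.radius)
                    break
            else:
                raise RuntimeError("could not place macroions without overlap; "
                                   "box too crowded")

    sys_ = SimulationSystem(box=box, templates=templates, macroions=macroions,
                            counterions=np.empty((0, 3)),
                            solvent=np.empty((0, 3)), bead_diameter=bead_d)
    surface = sys_.macroion_bead_positions()
    surface = minimum_image(surface, box) if len(surface) else surface

    n_ci = -sum(templates[m.template_index].total_charge for m in macroions)
    assert n_ci >= 0
    ci = _rejection_fill(rng, n_ci, box, surface, centers, radii, min_dist,
                         bead_d) if n_ci else np.empty((0, 3))

    v_excl = sum(4.0 / 3.0 * np.pi * (r + bead_d / 2) ** 3 for r in radii)
    n_solv = max(int(round(solvent_density * (np.prod(box) - v_excl))), 0)
    pool = np.vstack([surface, ci]) if n_ci else surface
    solv = _rejection_fill(rng, n_solv, box, pool, centers, radii, min_dist,
                           bead_d) if n_solv else np.empty((0, 3))

    sys_.counterions = ci
    sys_.solvent = solv
    sys_.validate()
    return sys_
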