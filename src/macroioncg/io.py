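"""File formats: LAMMPS data / dump, XYZ, TOML configs, CSV/VTK exports.

The data and dump dialects written here are the plain-text subsets widely
used for bead-spring CG simulations:

* data  — atom_style ``full``-compatible lines ``id mol type q x y z``;
* dump  — ``ITEM:`` records with ``id type q x y z`` per atom;
* XYZ   — element-per-type letters, positions only.

Particle types: 1 uncharged surface bead, 2 charged surface bead,
3 counterion, 4 solvent.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

TYPE_SURFACE = 1
TYPE_SURFACE_CHARGED = 2
TYPE_COUNTERION = 3
TYPE_SOLVENT = 4

_TYPE_ELEMENTS = {1: "C", 2: "Y", 3: "N", 4: "O"}


def _atom_table(psys):
    """(id, mol, type, q, xyz) arrays for a ParticleSystem."""
    n = psys.n_particles
    mol = psys.body_id + 1           # 0 = free
    types = np.full(n, TYPE_SOLVENT)
    surface = psys.body_id >= 0
    types[surface & (psys.charges == 0)] = TYPE_SURFACE
    types[surface & (psys.charges != 0)] = TYPE_SURFACE_CHARGED
    types[~surface & (psys.charges > 0)] = TYPE_COUNTERION
    return np.arange(1, n + 1), mol, types, psys.charges, psys.positions


def write_lammps_data(psys, path) -> None:
    ids, mol, types, q, xyz = _atom_table(psys)
    box = psys.box
    lines = ["CG macroion solution data file", "",
             f"{len(ids)} atoms", f"{types.max()} atom types", ""]
    for ax, name in enumerate(("x", "y", "z")):
        lines.append(f"{-box[ax] / 2:.10g} {box[ax] / 2:.10g} "
                     f"{name}lo {name}hi")
    lines += ["", "Atoms # full", ""]
    for i in range(len(ids)):
        lines.append(f"{ids[i]} {mol[i]} {types[i]} {q[i]:.6g} "
                     f"{xyz[i, 0]:.10g} {xyz[i, 1]:.10g} {xyz[i, 2]:.10g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_lammps_data(path):
    """Parse a data file back to plain arrays.

    Returns dict with box (3,), positions, charges, types, molecule.
    """
    text = Path(path).read_text().splitlines()
    n_atoms = None
    box = np.zeros(3)
    atoms_at = None
    for i, line in enumerate(text):
        s = line.split("#")[0].strip()
        if s.endswith("atoms"):
            n_atoms = int(s.split()[0])
        for ax, name in enumerate(("x", "y", "z")):
            if s.endswith(f"{name}lo {name}hi"):
                lo, hi = map(float, s.split()[:2])
                box[ax] = hi - lo
        if line.strip().startswith("Atoms"):
            atoms_at = i
            break
    if n_atoms is None or atoms_at is None:
        raise ValueError(f"{path}: not a recognisable LAMMPS data file")
    rows = []
    for line in text[atoms_at + 1:]:
        s = line.split("#")[0].strip()
        if not s:
            continue
        rows.append(s.split())
        if len(rows) == n_atoms:
            break
    rows.sort(key=lambda r: int(r[0]))
    arr = np.array(rows, dtype=float)
    return {"box": box, "positions": arr[:, 4:7],
            "charges": arr[:, 3], "types": arr[:, 2].astype(int),
            "molecule": arr[:, 1].astype(int)}


def write_xyz(psys, path, comment: str = "CG macroion frame") -> None:
    _, _, types, _, xyz = _atom_table(psys)
    lines = [str(len(types)), comment]
    for t, p in zip(types, xyz):
        lines.append(f"{_TYPE_ELEMENTS[int(t)]} "
                     f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_lammps_dump(frames, psys, path) -> None:
    """LAMMPS-style dump of trajectory frames (id type q x y z)."""
    _, _, types, _, _ = _atom_table(psys)
    out = []
    for f in frames:
        box = f.box
        out += ["ITEM: TIMESTEP", str(f.step),
                "ITEM: NUMBER OF ATOMS", str(len(f.positions)),
                "ITEM: BOX BOUNDS pp pp pp"]
        for ax in range(3):
            out.append(f"{-box[ax] / 2:.10g} {box[ax] / 2:.10g}")
        out.append("ITEM: ATOMS id type q x y z")
        for i, p in enumerate(f.positions):
            out.append(f"{i + 1} {types[i]} {psys.charges[i]:.6g} "
                       f"{p[0]:.8g} {p[1]:.8g} {p[2]:.8g}")
    Path(path).write_text("\n".join(out) + "\n")


def read_lammps_dump(path):
    """Yields dicts with step, box, positions, types, charges per frame."""
    lines = Path(path).read_text().splitlines()
    i = 0
    frames = []
    while i < len(lines):
        if not lines[i].startswith("ITEM: TIMESTEP"):
            i += 1
            continue
        step = int(lines[i + 1])
        n = int(lines[i + 3])
        box = np.zeros(3)
        for ax in range(3):
            lo, hi = map(float, lines[i + 5 + ax].split()[:2])
            box[ax] = hi - lo
        header = lines[i + 8].split()[2:]
        rows = [lines[i + 9 + k].split() for k in range(n)]
        rows.sort(key=lambda r: int(r[0]))
        arr = np.array(rows, dtype=float)
        cols = {name: arr[:, k] for k, name in enumerate(header)}
        frames.append({"step": step, "box": box,
                       "positions": np.column_stack(
                           (cols["x"], cols["y"], cols["z"])),
                       "types": cols["type"].astype(int),
                       "charges": cols.get("q")})
        i += 9 + n
    return frames


# ---------------------------------------------------------------------------
# scenario configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioConfig:
    """Fully-resolved description of one build + run + analysis scenario."""

    # template
    radius: float = 2.5
    bead_diameter: float = 1.0
    layout: str = "equatorial"
    n_charges: int = 10
    layout_parameters: dict = field(default_factory=dict)
    # composition
    n_macroions: int = 6
    box: float = 14.0
    solvent_density: float = 0.15
    # force field
    epsilon: float = 1.0
    sigma: float = 1.0
    r_c: float = 2.5
    ewald_accuracy: float = 1e-4
    # run protocol
    ensemble: str = "NVT"
    temperature: float = 1.0
    pressure: float = 0.1
    timestep: float = 0.005
    n_steps: int = 20000
    output_stride: int = 200
    friction: float = 0.2
    # bookkeeping
    seed: int = 0
    cluster_cutoff: float = 2.0


_SECTIONS = {
    "template": ("radius", "bead_diameter", "layout", "n_charges",
                 "layout_parameters"),
    "composition": ("n_macroions", "box", "solvent_density"),
    "forcefield": ("epsilon", "sigma", "r_c", "ewald_accuracy"),
    "run": ("ensemble", "temperature", "pressure", "timestep", "n_steps",
            "output_stride", "friction"),
    "analysis": ("cluster_cutoff",),
    "global": ("seed",),
}


def read_config(path) -> ScenarioConfig:
    """Load and validate a TOML scenario config.

    Unknown sections/keys and physically inconsistent values are rejected
    with messages naming the offending key.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    known = {f.name for f in fields(ScenarioConfig)}
    values = {}
    for section, content in raw.items():
        if section in known and not isinstance(content, dict):
            values[section] = content
            continue
        if section not in _SECTIONS:
            raise ValueError(f"{path}: unknown section [{section}]")
        for key, val in content.items():
            if key not in _SECTIONS[section]:
                raise ValueError(
                    f"{path}: unknown key {key!r} in section [{section}]")
            values[key] = val
    cfg = ScenarioConfig(**values)
    if cfg.r_c > cfg.box / 2.0:
        raise ValueError(
            f"{path}: r_c = {cfg.r_c} exceeds half the box ({cfg.box / 2}); "
            "minimum-image convention violated")
    if cfg.timestep <= 0:
        raise ValueError(f"{path}: timestep must be positive")
    if cfg.n_charges < 0:
        raise ValueError(f"{path}: n_charges must be >= 0")
    return cfg


def _toml_value(v):
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, dict):
        inner = ", ".join(f"{k} = {_toml_value(x)}" for k, x in v.items())
        return "{" + inner + "}"
    return repr(v)


def write_config(cfg: ScenarioConfig, path) -> None:
    d = asdict(cfg)
    lines = [f"seed = {d['seed']}", ""]    # top-level keys must lead
    for section, keys in _SECTIONS.items():
        if section == "global":
            continue
        lines.append(f"[{section}]")
        lines += [f"{k} = {_toml_value(d[k])}" for k in keys]
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# analysis exports
# ---------------------------------------------------------------------------

def write_table_csv(df, path, parameters: dict | None = None) -> None:
    """CSV with a YAML-style '#' header recording analysis parameters."""
    header = ""
    if parameters:
        header = "".join(f"# {k}: {v}\n" for k, v in parameters.items())
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False)


def write_field_vtk(grid, dims, spacing, origin, path) -> None:
    """Legacy-VTK structured points export of a FieldGrid."""
    n = int(np.prod(dims))
    if len(grid.points) != n:
        raise ValueError("grid size does not match dims")
    mag = np.where(np.isfinite(grid.magnitude), grid.magnitude, 0.0)
    vec = np.where(np.isfinite(grid.field), grid.field, 0.0)
    lines = ["# vtk DataFile Version 3.0", "electric field", "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {dims[0]} {dims[1]} {dims[2]}",
             f"ORIGIN {origin[0]} {origin[1]} {origin[2]}",
             f"SPACING {spacing[0]} {spacing[1]} {spacing[2]}",
             f"POINT_DATA {n}",
             "SCALARS magnitude float 1", "LOOKUP_TABLE default"]
    lines += [f"{v:.6g}" for v in mag]
    lines.append("VECTORS field float")
    lines += [f"{v[0]:.6g} {v[1]:.6g} {v[2]:.6g}" for v in vec]
    Path(path).write_text("\n".join(lines) + "\n")


def write_field_csv(grid, path) -> None:
    import pandas as pd
    df = pd.DataFrame(
        np.column_stack((grid.points, grid.field, grid.magnitude)),
        columns=["x", "y", "z", "ex", "ey", "ez", "magnitude"])
    df.to_csv(path, index=False)
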