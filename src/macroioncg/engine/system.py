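"""Flattened particle representation used by the MD engine.

A ``ParticleSystem`` holds every bead (macroion surface beads, counterions,
solvent) in flat arrays plus the rigid-body state of each macroion: centre
of mass, velocity, orientation quaternion, lab-frame angular momentum and
principal moments of inertia.  Surface bead positions are always derived
from the body pose; beads of a body never move relative to each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..builder import SimulationSystem, quaternion_matrix


def quat_multiply(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    w1, x1, y1, z1 = a
    w2, x2, y2, z2 = b
    return np.array([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ])


def quat_exp(rotvec: np.ndarray) -> np.ndarray:
    """Unit quaternion of the rotation by |rotvec| about rotvec."""
    angle = np.linalg.norm(rotvec)
    if angle < 1e-300:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = rotvec / angle
    return np.concatenate(([np.cos(angle / 2)], np.sin(angle / 2) * axis))


@dataclass
class ParticleSystem:
    """All particles plus rigid-body states (reduced units).

    ``body_id`` is -1 for free particles (counterions, solvent).  Body
    coordinates are stored in each body's principal frame; ``body_quat``
    rotates principal frame to lab frame.
    """

    box: np.ndarray
    positions: np.ndarray            # (N, 3)
    velocities: np.ndarray           # (N, 3), meaningful for free particles
    charges: np.ndarray              # (N,)
    masses: np.ndarray               # (N,)
    body_id: np.ndarray              # (N,) int, -1 = free
    body_coords: list = field(default_factory=list)    # [(nb,3)] principal
    body_index: list = field(default_factory=list)     # [(nb,) global idx]
    body_com: np.ndarray = None      # (B, 3)
    body_vel: np.ndarray = None      # (B, 3)
    body_quat: np.ndarray = None     # (B, 4) (w, x, y, z)
    body_angmom: np.ndarray = None   # (B, 3) lab frame
    body_mass: np.ndarray = None     # (B,)
    body_inertia: np.ndarray = None  # (B, 3) principal moments

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    @property
    def n_bodies(self) -> int:
        return len(self.body_coords)

    @property
    def free_index(self) -> np.ndarray:
        return np.flatnonzero(self.body_id < 0)

    @property
    def n_dof(self) -> int:
        return 3 * len(self.free_index) + 6 * self.n_bodies

    # -- construction ------------------------------------------------------

    @classmethod
    def from_simulation_system(cls, sys_: SimulationSystem,
                               bead_mass: float = 1.0) -> "ParticleSystem":
        parts_pos, parts_q, parts_body = [], [], []
        body_coords, body_index, coms, quats, bmass, binertia = \
            [], [], [], [], [], []
        offset = 0
        for b, m in enumerate(sys_.macroions):
            t = sys_.templates[m.template_index]
            inertia = bead_mass * t.inertia_tensor()
            evals, evecs = np.linalg.eigh(inertia)
            if np.linalg.det(evecs) < 0:
                evecs[:, 0] = -evecs[:, 0]
            coords_p = t.positions @ evecs        # principal frame
            r_body = quaternion_matrix(m.quaternion) @ evecs
            # quaternion for principal->lab rotation
            quats.append(_matrix_to_quat(r_body))
            body_coords.append(coords_p)
            body_index.append(np.arange(offset, offset + t.n_beads))
            coms.append(m.com)
            bmass.append(bead_mass * t.n_beads)
            binertia.append(evals)
            parts_pos.append(m.lab_positions(t))
            parts_q.append(t.charges.astype(float))
            parts_body.append(np.full(t.n_beads, b))
            offset += t.n_beads
        for arr, q in ((sys_.counterions, 1.0), (sys_.solvent, 0.0)):
            if len(arr):
                parts_pos.append(arr)
                parts_q.append(np.full(len(arr), q))
                parts_body.append(np.full(len(arr), -1))
                offset += len(arr)
        pos = np.vstack(parts_pos) if parts_pos else np.empty((0, 3))
        n = len(pos)
        ps = cls(
            box=np.asarray(sys_.box, dtype=float).copy(),
            positions=pos.astype(float),
            velocities=np.zeros((n, 3)),
            charges=np.concatenate(parts_q) if parts_q else np.empty(0),
            masses=np.full(n, bead_mass),
            body_id=np.concatenate(parts_body).astype(int)
            if parts_body else np.empty(0, dtype=int),
            body_coords=body_coords,
            body_index=body_index,
            body_com=np.array(coms) if coms else np.empty((0, 3)),
            body_vel=np.zeros((len(coms), 3)),
            body_quat=np.array(quats) if quats else np.empty((0, 4)),
            body_angmom=np.zeros((len(coms), 3)),
            body_mass=np.array(bmass),
            body_inertia=np.array(binertia) if binertia
            else np.empty((0, 3)),
        )
        ps.sync_bodies()
        return ps

    # -- body kinematics ---------------------------------------------------

    def sync_bodies(self) -> None:
        """Recompute surface bead positions from current body poses."""
        for b in range(self.n_bodies):
            r = quaternion_matrix(self.body_quat[b])
            self.positions[self.body_index[b]] = \
                self.body_com[b] + self.body_coords[b] @ r.T

    def body_omega_body(self, b: int) -> np.ndarray:
        """Angular velocity in the principal (body) frame."""
        r = quaternion_matrix(self.body_quat[b])
        pi = r.T @ self.body_angmom[b]
        return pi / self.body_inertia[b]

    def bead_velocities(self) -> np.ndarray:
        """Per-bead velocities (free particles + rigid-motion beads)."""
        v = self.velocities.copy()
        for b in range(self.n_bodies):
            r = quaternion_matrix(self.body_quat[b])
            omega_lab = r @ self.body_omega_body(b)
            rel = self.positions[self.body_index[b]] - self.body_com[b]
            v[self.body_index[b]] = self.body_vel[b] + np.cross(omega_lab, rel)
        return v

    # -- thermodynamics ----------------------------------------------------

    def kinetic_energy(self) -> dict:
        free = self.free_index
        k_free = 0.5 * float(np.sum(self.masses[free, None] *
                                    self.velocities[free] ** 2))
        k_trans = 0.5 * float(np.sum(self.body_mass[:, None] *
                                     self.body_vel ** 2)) \
            if self.n_bodies else 0.0
        k_rot = 0.0
        for b in range(self.n_bodies):
            r = quaternion_matrix(self.body_quat[b])
            pi = r.T @ self.body_angmom[b]
            k_rot += 0.5 * float(np.sum(pi**2 / self.body_inertia[b]))
        return {"free": k_free, "body_trans": k_trans, "body_rot": k_rot,
                "total": k_free + k_trans + k_rot}

    def temperature(self) -> float:
        dof = self.n_dof
        return 2.0 * self.kinetic_energy()["total"] / dof if dof else 0.0

    def wrap(self) -> None:
        """Wrap free particles and body COMs into the primary cell."""
        free = self.free_index
        self.positions[free] -= self.box * np.round(
            self.positions[free] / self.box)
        if self.n_bodies:
            self.body_com -= self.box * np.round(self.body_com / self.box)
            self.sync_bodies()

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Restart file: full state, bit-exact round trip."""
        np.savez(path,
                 box=self.box, positions=self.positions,
                 velocities=self.velocities, charges=self.charges,
                 masses=self.masses, body_id=self.body_id,
                 n_bodies=np.array(self.n_bodies),
                 body_com=self.body_com, body_vel=self.body_vel,
                 body_quat=self.body_quat, body_angmom=self.body_angmom,
                 body_mass=self.body_mass, body_inertia=self.body_inertia,
                 **{f"body_coords_{b}": self.body_coords[b]
                    for b in range(self.n_bodies)},
                 **{f"body_index_{b}": self.body_index[b]
                    for b in range(self.n_bodies)})

    @classmethod
    def load(cls, path) -> "ParticleSystem":
        d = np.load(path)
        nb = int(d["n_bodies"])
        return cls(
            box=d["box"], positions=d["positions"],
            velocities=d["velocities"], charges=d["charges"],
            masses=d["masses"], body_id=d["body_id"],
            body_coords=[d[f"body_coords_{b}"] for b in range(nb)],
            body_index=[d[f"body_index_{b}"] for b in range(nb)],
            body_com=d["body_com"], body_vel=d["body_vel"],
            body_quat=d["body_quat"], body_angmom=d["body_angmom"],
            body_mass=d["body_mass"], body_inertia=d["body_inertia"],
        )


def _matrix_to_quat(r: np.ndarray) -> np.ndarray:
    """Quaternion (w, x, y, z) of a proper rotation matrix."""
    from scipy.spatial.transform import Rotation
    x, y, z, w = Rotation.from_matrix(r).as_quat()
    q = np.array([w, x, y, z])
    return q / np.linalg.norm(q)
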