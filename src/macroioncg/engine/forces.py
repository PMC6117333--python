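"""Force evaluation: LJ + Ewald Coulomb with Verlet neighbour lists.

Pairs belonging to the same rigid body are excluded from both the LJ and
Coulomb sums (their contribution is constant under rigid motion and exerts
no net force or torque on the body).  Neighbour lists are built with a
periodic k-d tree and refreshed when any particle has moved more than half
the skin since the last build.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .ewald import EwaldSummation
from .forcefield import ForceField

try:
    from numba import njit
except ImportError:          # pragma: no cover - numba is a hard dep
    def njit(*a, **k):
        def deco(f):
            return f
        return deco

_HARD_FLOOR = 0.1  # fraction of sigma below which overlap is fatal


@njit(cache=True)
def _lj_kernel(pos, box, pi, pj, eps, sigma2, rc2, floor2, forces):
    """Truncated LJ energy/force accumulation over a pair list.

    Returns (energy, virial, min_r2); forces is accumulated in place.
    """
    energy = 0.0
    virial = 0.0
    min_r2 = 1e30
    for k in range(len(pi)):
        i = pi[k]
        j = pj[k]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        dx -= box[0] * np.round(dx / box[0])
        dy -= box[1] * np.round(dy / box[1])
        dz -= box[2] * np.round(dz / box[2])
        r2 = dx * dx + dy * dy + dz * dz
        if r2 > rc2:
            continue
        if r2 < min_r2:
            min_r2 = r2
        sr6 = (sigma2 / r2) ** 3
        energy += 4.0 * eps * (sr6 * sr6 - sr6)
        fr = 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r2
        virial += fr * r2
        fx = fr * dx
        fy = fr * dy
        fz = fr * dz
        forces[i, 0] += fx
        forces[i, 1] += fy
        forces[i, 2] += fz
        forces[j, 0] -= fx
        forces[j, 1] -= fy
        forces[j, 2] -= fz
    return energy, virial, min_r2


def _periodic_pairs(positions, box, cutoff):
    wrapped = np.mod(positions, box)
    # float rounding can land exactly on the upper box edge
    wrapped = np.where(wrapped < box, wrapped, 0.0)
    tree = cKDTree(wrapped, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return (np.empty(0, dtype=int), np.empty(0, dtype=int))
    return pairs[:, 0], pairs[:, 1]


class ForceCalculator:
    """Caches neighbour lists and the Ewald solver for one system."""

    def __init__(self, psys, ff: ForceField, skin: float = 0.3):
        self.ff = ff
        self.skin = skin * ff.sigma
        self.charged = np.flatnonzero(psys.charges != 0.0)
        self._subset_of = {int(g): i for i, g in enumerate(self.charged)}
        excl = []
        for b in range(psys.n_bodies):
            idx = [self._subset_of[int(g)] for g in psys.body_index[b]
                   if int(g) in self._subset_of]
            excl.extend((idx[i], idx[j]) for i in range(len(idx))
                        for j in range(i + 1, len(idx)))
        self._exclusions = np.array(excl, dtype=int) if excl else None
        self._ewald = None
        self._ewald_box = None
        self._ref_positions = None
        self._lj_pairs = None
        self._coul_pairs = None

    # -- neighbour lists ---------------------------------------------------

    def _coulomb_cutoff(self, box) -> float:
        want = self.ff.coulomb_r_c or 2.0 * self.ff.r_c
        return min(want, 0.45 * float(np.min(box)))

    def _rebuild(self, psys):
        box = psys.box
        pos = psys.positions
        i, j = _periodic_pairs(pos, box, self.ff.r_c + self.skin)
        same_body = (psys.body_id[i] >= 0) & (psys.body_id[i] == psys.body_id[j])
        self._lj_pairs = (i[~same_body], j[~same_body])
        if len(self.charged):
            rc = self._coulomb_cutoff(box)
            ci, cj = _periodic_pairs(pos[self.charged], box, rc + self.skin)
            gi, gj = self.charged[ci], self.charged[cj]
            same = (psys.body_id[gi] >= 0) & (psys.body_id[gi] ==
                                              psys.body_id[gj])
            self._coul_pairs = (ci[~same], cj[~same])
            if self._ewald is None or self._ewald_box is None or \
                    not np.array_equal(self._ewald_box, box):
                self._ewald = EwaldSummation(
                    box, psys.charges[self.charged], self.ff.k_q,
                    r_cut=rc, accuracy=self.ff.ewald_accuracy,
                    exclusions=self._exclusions)
                self._ewald_box = box.copy()
        self._ref_positions = pos.copy()
        self._ref_box = box.copy()

    def _needs_rebuild(self, psys) -> bool:
        if self._ref_positions is None or \
                len(self._ref_positions) != len(psys.positions):
            return True
        if not np.array_equal(self._ref_box, psys.box):
            return True
        disp = psys.positions - self._ref_positions
        disp -= psys.box * np.round(disp / psys.box)
        return bool(np.max(np.abs(disp)) > self.skin / 2.0)

    # -- evaluation --------------------------------------------------------

    def compute(self, psys):
        """Forces, energy decomposition and virial trace for the system.

        Returns (forces (N,3), energies dict, virial_scalar).
        Raises on particle overlap below the hard floor.
        """
        if self._needs_rebuild(psys):
            self._rebuild(psys)
        ff = self.ff
        pos, box = psys.positions, psys.box
        n = psys.n_particles
        forces = np.zeros((n, 3))
        virial = 0.0

        i, j = self._lj_pairs
        energies = {"lj": 0.0, "coulomb": 0.0}
        if len(i):
            u, w, min_r2 = _lj_kernel(pos, box, i, j, ff.epsilon,
                                      ff.sigma**2, ff.r_c**2,
                                      (_HARD_FLOOR * ff.sigma) ** 2, forces)
            if min_r2 < (_HARD_FLOOR * ff.sigma) ** 2:
                raise RuntimeError(
                    "particle overlap below 0.1 sigma; system is unstable")
            energies["lj"] = float(u)
            virial += float(w)

        if len(self.charged):
            ci, cj = self._coul_pairs
            e_c, f_c, w_c, parts = self._ewald.energy_forces(
                pos[self.charged], pairs_i=ci, pairs_j=cj)
            forces[self.charged] += f_c
            energies["coulomb"] = e_c
            energies.update({f"coulomb_{k}": v for k, v in parts.items()})
            virial += w_c

        energies["potential"] = energies["lj"] + energies["coulomb"]
        if not np.isfinite(energies["potential"]):
            raise RuntimeError("non-finite potential energy")
        return forces, energies, virial


def body_forces_torques(psys, forces):
    """Net force and torque on each rigid body from per-bead forces."""
    nb = psys.n_bodies
    f_body = np.zeros((nb, 3))
    tau_body = np.zeros((nb, 3))
    for b in range(nb):
        idx = psys.body_index[b]
        fb = forces[idx]
        f_body[b] = fb.sum(axis=0)
        rel = psys.positions[idx] - psys.body_com[b]
        tau_body[b] = np.cross(rel, fb).sum(axis=0)
    return f_body, tau_body


def compute_forces(psys, ff: ForceField):
    """One-shot convenience wrapper (no cached neighbour state).

    Returns (forces, energies, virial, body_forces, body_torques).
    """
    calc = ForceCalculator(psys, ff)
    forces, energies, virial = calc.compute(psys)
    f_b, tau_b = body_forces_torques(psys, forces)
    return forces, energies, virial, f_b, tau_b
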