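"""Conventional Ewald summation for periodic point charges.

The conditionally convergent Coulomb sum over all periodic images is split
into a short-range real-space part (complementary error function screened,
summed over minimum-image pairs within a cutoff), a reciprocal-space part
(Gaussian-damped structure-factor sum over k-vectors), the self-energy, and
corrections removing excluded (same rigid body) pairs.  Conducting
("tinfoil") boundary conditions; the system must be charge neutral.

The splitting parameter alpha and the k-space cutoff are chosen from the
requested accuracy: alpha = s/r_cut and k_cut = 2*alpha*s with
s = sqrt(-ln(accuracy)), so both truncated tails are O(accuracy).
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf, erfc


class EwaldSummation:
    """Ewald energy/forces for a fixed box, charge set and exclusion list.

    Parameters
    ----------
    box : (3,) array
        Orthorhombic box lengths.
    charges : (Nq,) array
        Charges of the charged particles (must sum to ~0).
    k_q : float
        Coulomb prefactor (energy*length per charge^2).
    r_cut : float
        Real-space cutoff; must not exceed half the shortest box length.
    accuracy : float
        Target relative truncation error.
    exclusions : (M, 2) int array, optional
        Index pairs (into the charge set) whose direct interaction must be
        removed (rigid-body internal pairs).
    """

    def __init__(self, box, charges, k_q, r_cut=None, accuracy=1e-5,
                 exclusions=None):
        self.box = np.asarray(box, dtype=float)
        self.charges = np.asarray(charges, dtype=float)
        if abs(self.charges.sum()) > 1e-9:
            raise ValueError(
                f"Ewald requires a neutral system (net {self.charges.sum()})")
        self.k_q = float(k_q)
        lmin = self.box.min()
        self.r_cut = min(r_cut if r_cut is not None else 0.45 * lmin,
                         0.499 * lmin)
        s = np.sqrt(-np.log(accuracy))
        self.alpha = s / self.r_cut
        self.k_cut = 2.0 * self.alpha * s
        self.exclusions = (np.asarray(exclusions, dtype=int).reshape(-1, 2)
                           if exclusions is not None and len(exclusions)
                           else np.empty((0, 2), dtype=int))
        self._build_kvectors()

    def _build_kvectors(self):
        nmax = np.ceil(self.k_cut * self.box / (2.0 * np.pi)).astype(int)
        ax = [np.arange(-n, n + 1) for n in nmax]
        grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1).reshape(-1, 3)
        k = 2.0 * np.pi * grid / self.box
        k2 = np.einsum("ij,ij->i", k, k)
        mask = (k2 > 0) & (k2 <= self.k_cut**2)
        # half space: keep one of each +/-k pair, weight 2
        order = grid[mask]
        keep = ((order[:, 0] > 0) |
                ((order[:, 0] == 0) & (order[:, 1] > 0)) |
                ((order[:, 0] == 0) & (order[:, 1] == 0) & (order[:, 2] > 0)))
        self.kvecs = k[mask][keep]
        self.k2 = k2[mask][keep]
        vol = float(np.prod(self.box))
        self.ak = (4.0 * np.pi * self.k_q / vol *
                   np.exp(-self.k2 / (4.0 * self.alpha**2)) / self.k2)

    # -- pieces ------------------------------------------------------------

    def real_space(self, positions, pairs_i, pairs_j):
        """Screened real-space sum over the given minimum-image pairs.

        Returns (energy, forces, virial); pairs beyond r_cut contribute 0.
        """
        n = len(positions)
        forces = np.zeros((n, 3))
        if len(pairs_i) == 0:
            return 0.0, forces, 0.0
        dr = positions[pairs_i] - positions[pairs_j]
        dr -= self.box * np.round(dr / self.box)
        r = np.linalg.norm(dr, axis=1)
        inside = r <= self.r_cut
        dr, r = dr[inside], r[inside]
        pi, pj = pairs_i[inside], pairs_j[inside]
        qq = self.k_q * self.charges[pi] * self.charges[pj]
        u = qq * erfc(self.alpha * r) / r
        fmag = qq * (erfc(self.alpha * r) / r +
                     2.0 * self.alpha / np.sqrt(np.pi) *
                     np.exp(-(self.alpha * r) ** 2)) / r**2
        fvec = fmag[:, None] * dr
        for ax in range(3):
            forces[:, ax] += np.bincount(pi, weights=fvec[:, ax], minlength=n)
            forces[:, ax] -= np.bincount(pj, weights=fvec[:, ax], minlength=n)
        virial = float(np.sum(fmag * r * r))
        return float(u.sum()), forces, virial

    def reciprocal(self, positions):
        """k-space sum: (energy, forces, virial trace)."""
        phase = self.kvecs @ positions.T                    # (Nk, Nq)
        eikr = np.exp(1j * phase)
        s_k = eikr @ self.charges                           # (Nk,)
        u = float(np.sum(self.ak * np.abs(s_k) ** 2))       # half-space*2/2
        # F_j = -q_j sum_k 2 A_k k Im[ S(k) e^{-i k r_j} ]
        im = np.imag(s_k[:, None] * np.conj(eikr))          # (Nk, Nq)
        fk = -2.0 * (self.ak[:, None] * im)
        forces = (self.kvecs.T @ fk).T * self.charges[:, None]
        virial = float(np.sum(self.ak * np.abs(s_k) ** 2 *
                              (1.0 - self.k2 / (2.0 * self.alpha**2))))
        return u, forces, virial

    def self_energy(self):
        return float(-self.k_q * self.alpha / np.sqrt(np.pi) *
                     np.sum(self.charges**2))

    def exclusion_correction(self, positions):
        """Remove the erf-screened part of excluded (intra-body) pairs."""
        n = len(positions)
        forces = np.zeros((n, 3))
        if len(self.exclusions) == 0:
            return 0.0, forces
        pi, pj = self.exclusions[:, 0], self.exclusions[:, 1]
        dr = positions[pi] - positions[pj]
        dr -= self.box * np.round(dr / self.box)
        r = np.linalg.norm(dr, axis=1)
        qq = self.k_q * self.charges[pi] * self.charges[pj]
        u = -qq * erf(self.alpha * r) / r
        fmag = -qq * (erf(self.alpha * r) / r -
                      2.0 * self.alpha / np.sqrt(np.pi) *
                      np.exp(-(self.alpha * r) ** 2)) / r**2
        fvec = fmag[:, None] * dr
        for ax in range(3):
            forces[:, ax] += np.bincount(pi, weights=fvec[:, ax], minlength=n)
            forces[:, ax] -= np.bincount(pj, weights=fvec[:, ax], minlength=n)
        return float(u.sum()), forces

    # -- public ------------------------------------------------------------

    def energy_forces(self, positions, pairs_i=None, pairs_j=None):
        """Total Coulomb energy, per-charge forces and virial trace.

        If real-space pair lists are not supplied they are built by brute
        force over all charge pairs not in the exclusion list.
        """
        positions = np.asarray(positions, dtype=float)
        nq = len(positions)
        if pairs_i is None:
            iu, ju = np.triu_indices(nq, k=1)
            if len(self.exclusions):
                excl = set(map(tuple, np.sort(self.exclusions, axis=1)))
                keep = np.array([(a, b) not in excl for a, b in zip(iu, ju)])
                iu, ju = iu[keep], ju[keep]
            pairs_i, pairs_j = iu, ju
        u_r, f_r, w_r = self.real_space(positions, pairs_i, pairs_j)
        u_k, f_k, w_k = self.reciprocal(positions)
        u_x, f_x = self.exclusion_correction(positions)
        u_s = self.self_energy()
        energy = u_r + u_k + u_s + u_x
        parts = {"real": u_r, "reciprocal": u_k, "self": u_s,
                 "exclusion": u_x}
        return energy, f_r + f_k + f_x, w_r + w_k, parts
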