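"""Pair interactions: truncated LJ 12-6 and Coulomb.

The LJ potential is truncated without shift at r_c (zero beyond), matching
the piecewise form used for CG macroion solutions:

    U_LJ(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ]   for r <= r_c, else 0.

The Coulomb pair energy is U = k_q q_a q_b / r with k_q = 1/(4 pi eps_0)
expressed in reduced units (see units.UnitSystem.coulomb_constant_reduced);
long-range periodic sums are handled by the Ewald module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..units import DEFAULT_UNITS


@dataclass(frozen=True)
class ForceField:
    """Global pair-interaction parameters (reduced units).

    A single epsilon/sigma applies to all species.  ``coulomb_r_c`` is the
    real-space Ewald cutoff (defaults to twice the LJ cutoff, capped at
    just under half the box at run time); ``ewald_accuracy`` is the target
    relative truncation error of both Ewald sums.
    """

    epsilon: float = 1.0
    sigma: float = 1.0
    r_c: float = 2.5
    k_q: float = DEFAULT_UNITS.coulomb_constant_reduced
    coulomb_r_c: float | None = None
    ewald_accuracy: float = 1e-5

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.r_c <= self.sigma:
            raise ValueError("r_c must exceed sigma")


def lj_pair(r, ff: ForceField):
    """Truncated LJ energy and radial force magnitude (-dU/dr) at r.

    Accepts scalars or arrays; r must be positive.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("LJ pair distance must be positive (overlap)")
    sr6 = (ff.sigma / r) ** 6
    inside = r <= ff.r_c
    u = np.where(inside, 4.0 * ff.epsilon * (sr6 * sr6 - sr6), 0.0)
    f = np.where(inside, 24.0 * ff.epsilon * (2.0 * sr6 * sr6 - sr6) / r, 0.0)
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def coulomb_pair(r, q_a: float, q_b: float, ff: ForceField):
    """Bare Coulomb pair energy k_q q_a q_b / r (no cutoff)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("Coulomb pair distance must be positive")
    u = ff.k_q * q_a * q_b / r
    return float(u) if u.ndim == 0 else u
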