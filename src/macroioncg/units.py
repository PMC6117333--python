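"""Reduced (LJ-style) <-> physical unit conversion.

All simulation quantities are dimensionless multiples of four reference
scales: a length ``sigma`` (the CG bead diameter), an energy ``epsilon``
(the global LJ well depth), a bead mass (one CG solvent bead standing for
four water molecules), and the elementary charge.  Every other reference is
derived from these:

* time:        tau   = sigma * sqrt(mass / epsilon)
* temperature: T_ref = epsilon / k_B
* pressure:    P_ref = epsilon / sigma**3
* the Boltzmann constant is 1 in reduced units.

Defaults reproduce the MARTINI-style CG water parameterisation used for
hydrophilic macroion solutions: sigma = 5 Angstrom, epsilon = 4.5 kJ/mol,
bead mass = 72 g/mol, for which the reduced timestep 0.005 corresponds to
10 fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy import constants as _const

# SI reference constants
_KJ_PER_MOL = 1e3 / _const.Avogadro          # J per (kJ/mol)
_G_PER_MOL = 1e-3 / _const.Avogadro          # kg per (g/mol)
_ANGSTROM = 1e-10                            # m

#: dimensions supported by :meth:`UnitSystem.to_real` / ``to_reduced``
DIMENSIONS = ("length", "energy", "mass", "time", "temperature", "pressure",
              "charge")

#: human-readable unit of each dimension's real-side value
REAL_UNITS = {
    "length": "Angstrom",
    "energy": "kJ/mol",
    "mass": "g/mol",
    "time": "fs",
    "temperature": "K",
    "pressure": "bar",
    "charge": "e",
}


@dataclass(frozen=True)
class UnitSystem:
    """Bidirectional map between reduced LJ units and real units.

    Parameters
    ----------
    length_ref : float
        sigma in Angstrom (default 5.0).
    energy_ref : float
        epsilon in kJ/mol (default 4.5).
    mass_ref : float
        bead mass in g/mol (default 72.0, i.e. four water molecules).
    charge_ref : float
        charge unit in elementary charges (default 1.0).
    """

    length_ref: float = 5.0
    energy_ref: float = 4.5
    mass_ref: float = 72.0
    charge_ref: float = 1.0

    @property
    def time_ref(self) -> float:
        """tau = sigma*sqrt(m/epsilon), expressed in femtoseconds."""
        sigma_m = self.length_ref * _ANGSTROM
        eps_j = self.energy_ref * _KJ_PER_MOL
        mass_kg = self.mass_ref * _G_PER_MOL
        tau_s = sigma_m * (mass_kg / eps_j) ** 0.5
        return tau_s / 1e-15

    @property
    def temperature_ref(self) -> float:
        """epsilon/k_B in Kelvin."""
        return self.energy_ref * _KJ_PER_MOL / _const.Boltzmann

    @property
    def pressure_ref(self) -> float:
        """epsilon/sigma^3 in bar."""
        eps_j = self.energy_ref * _KJ_PER_MOL
        sigma_m = self.length_ref * _ANGSTROM
        return eps_j / sigma_m**3 / 1e5

    @property
    def coulomb_constant_reduced(self) -> float:
        """k_q = e^2/(4 pi eps_0) expressed in reduced energy*length.

        This is the prefactor of q_a*q_b/r (charges in units of e,
        r in units of sigma) that reproduces the vacuum Coulomb energy.
        """
        e2_over_4pieps0 = _const.e**2 / (4.0 * _const.pi * _const.epsilon_0)  # J*m
        eps_j = self.energy_ref * _KJ_PER_MOL
        sigma_m = self.length_ref * _ANGSTROM
        return e2_over_4pieps0 / (eps_j * sigma_m) * self.charge_ref**2

    def _factor(self, dimension: str) -> float:
        if dimension == "length":
            return self.length_ref
        if dimension == "energy":
            return self.energy_ref
        if dimension == "mass":
            return self.mass_ref
        if dimension == "time":
            return self.time_ref
        if dimension == "temperature":
            return self.temperature_ref
        if dimension == "pressure":
            return self.pressure_ref
        if dimension == "charge":
            return self.charge_ref
        raise ValueError(
            f"unknown dimension {dimension!r}; supported: {', '.join(DIMENSIONS)}"
        )

    def to_real(self, quantity: float, dimension: str) -> float:
        """Convert a reduced quantity to real units (see REAL_UNITS)."""
        return quantity * self._factor(dimension)

    def to_reduced(self, quantity: float, dimension: str) -> float:
        """Convert a real-unit quantity to reduced units (inverse of to_real)."""
        return quantity / self._factor(dimension)

    def describe(self) -> str:
        lines = [f"sigma      = {self.length_ref} Angstrom",
                 f"epsilon    = {self.energy_ref} kJ/mol",
                 f"bead mass  = {self.mass_ref} g/mol",
                 f"tau        = {self.time_ref:.6g} fs",
                 f"T_ref      = {self.temperature_ref:.6g} K",
                 f"P_ref      = {self.pressure_ref:.6g} bar",
                 f"k_q (red.) = {self.coulomb_constant_reduced:.6g}"]
        return "\n".join(lines)


#: default unit system of the CG macroion model
DEFAULT_UNITS = UnitSystem()
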