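"""Reduced-unit system for the bead-spring model.

All internal computation uses reduced units: the bead diameter ``sigma`` is
the unit of length, the thermal energy ``k_B T`` at the simulation
temperature is the unit of energy, and the bead mass is the unit of mass.
The physical mapping identifies one reduced length unit with
``sigma = 1.535 angstrom = 0.1535 nm`` (the effective diameter of a
coarse-grained carbon bead) and the energy unit with ``k_B T`` at
``T = 300 K``.  Configuration files and all reported observables use nm and
``k_B T``; conversion is a single multiplication and therefore exactly
invertible to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Physical length of one reduced length unit, in nanometres.
SIGMA_NM = 0.1535

#: Simulation temperature in kelvin (the energy unit is k_B * T at this T).
TEMPERATURE_K = 300.0


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between reduced simulation units and physical units.

    Parameters
    ----------
    sigma_nm:
        Physical size of one reduced length unit in nm.
    temperature_K:
        Temperature defining the energy unit (``1`` energy unit =
        ``k_B * temperature_K``).
    """

    sigma_nm: float = SIGMA_NM
    temperature_K: float = TEMPERATURE_K

    def to_nm(self, x_reduced: float) -> float:
        """Convert a length from reduced units to nm."""
        return x_reduced * self.sigma_nm

    def from_nm(self, x_nm: float) -> float:
        """Convert a length from nm to reduced units."""
        return x_nm / self.sigma_nm

    def volume_to_nm3(self, v_reduced: float) -> float:
        return v_reduced * self.sigma_nm**3

    def volume_from_nm3(self, v_nm3: float) -> float:
        return v_nm3 / self.sigma_nm**3

    def density_to_per_nm3(self, rho_reduced: float) -> float:
        """Convert a number density from sigma^-3 to nm^-3."""
        return rho_reduced / self.sigma_nm**3

    def density_from_per_nm3(self, rho_nm3: float) -> float:
        return rho_nm3 * self.sigma_nm**3


#: Module-level default unit system.
UNITS = UnitSystem()
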