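"""Physical constants and ion species shared by all transport computations.

Membrane permeabilities are handled in um/s, concentrations in mM, potentials
in mV and currents in uA/cm^2 at the public surface; conversions to coherent
per-cm^2 SI units happen inside the flux routines.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["PhysicalConstants", "IonSpecies", "NA", "K", "CL", "DEFAULT_CONSTANTS"]


@dataclass(frozen=True)
class PhysicalConstants:
    """Faraday constant, gas constant, temperature and membrane capacitance.

    Attributes
    ----------
    F : float
        Faraday constant, C mol^-1.
    R : float
        Gas constant, J mol^-1 K^-1.
    T : float
        Absolute temperature, K. Physiological range enforced.
    C_m : float
        Membrane capacitance per unit area, uF cm^-2.
    """

    F: float = 96485.0
    R: float = 8.314
    T: float = 310.0
    C_m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("F", "R", "T", "C_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not (273.0 <= self.T <= 320.0):
            raise ValueError(f"T={self.T} K outside the physiological range [273, 320]")

    @property
    def RT_F_mV(self) -> float:
        """Thermal voltage R*T/F in mV (~26.7 mV at 310 K)."""
        return 1e3 * self.R * self.T / self.F


@dataclass(frozen=True)
class IonSpecies:
    """A permeant ion with its valence."""

    name: str
    z: int

    _VALENCES = {"Na": 1, "K": 1, "Cl": -1}

    def __post_init__(self) -> None:
        expected = self._VALENCES.get(self.name)
        if expected is None:
            raise ValueError(f"unknown ion species {self.name!r}; expected one of Na, K, Cl")
        if self.z != expected:
            raise ValueError(f"valence {self.z} does not match ion {self.name} (expected {expected})")


NA = IonSpecies("Na", 1)
K = IonSpecies("K", 1)
CL = IonSpecies("Cl", -1)

DEFAULT_CONSTANTS = PhysicalConstants()
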