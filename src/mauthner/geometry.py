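"""Cylindrical single-compartment geometry and unit conversions.

The oocyte and M-cell models are bare cylinders (no end caps, matching the
lateral-area convention of cable simulators).  All conversions between
absolute conductance (nS) and surface density (mS/cm^2) go through the
lateral area so the two representations round-trip exactly.

Internal units throughout the package: mV, ms, nS, pA, pF, um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["CylindricalCompartment", "OOCYTE", "MCELL"]

_UM2_PER_CM2 = 1e8


@dataclass(frozen=True)
class CylindricalCompartment:
    """Cylinder of given length/diameter (um) with specific capacitance (uF/cm^2)."""

    length_um: float
    diameter_um: float
    c_m_uF_cm2: float = 1.0

    def __post_init__(self) -> None:
        if self.length_um <= 0 or self.diameter_um <= 0:
            raise ValueError("compartment dimensions must be positive")
        if self.c_m_uF_cm2 <= 0:
            raise ValueError("specific capacitance must be positive")

    @property
    def area_um2(self) -> float:
        """Lateral surface area pi * d * L (um^2), no end caps."""
        return math.pi * self.diameter_um * self.length_um

    @property
    def area_cm2(self) -> float:
        return self.area_um2 / _UM2_PER_CM2

    @property
    def capacitance_pF(self) -> float:
        # uF/cm^2 * cm^2 = uF; 1 uF = 1e6 pF
        return self.c_m_uF_cm2 * self.area_cm2 * 1e6

    def density_mS_cm2(self, gbar_nS: float) -> float:
        """Convert absolute conductance (nS) to surface density (mS/cm^2)."""
        return gbar_nS * 1e-6 / self.area_cm2

    def gbar_nS(self, density_mS_cm2: float) -> float:
        """Convert surface density (mS/cm^2) back to absolute conductance (nS)."""
        return density_mS_cm2 * self.area_cm2 * 1e6


#: Xenopus oocyte model compartment (geometry-derived capacitance 12.57 pF).
OOCYTE = CylindricalCompartment(length_um=20.0, diameter_um=20.0)

#: Mauthner-cell model compartment (geometry-derived capacitance 50.27 pF).
MCELL = CylindricalCompartment(length_um=40.0, diameter_um=40.0)
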