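"""Stirred-tank geometry.

The reference vessel is a 54 m3 production-scale stirred fermentor: a
flat-bottomed cylinder holding a single Newtonian liquid phase, agitated by
two Rushton turbines on a common shaft.  All downstream modules treat the
liquid as incompressible with constant density, so geometry fixes the total
broth mass once and for all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


class GeometryError(ValueError):
    """Raised when a tank specification is not physically meaningful."""


@dataclass(frozen=True)
class TankGeometry:
    """Cylindrical stirred-tank dimensions and operating point.

    Parameters
    ----------
    diameter:
        Inner tank diameter ``T`` (m).
    liquid_height:
        Ungassed liquid fill height ``Hl`` (m).
    impeller_diameter:
        Rushton impeller diameter ``D`` (m); both impellers share it.
    bottom_clearance:
        Off-bottom clearance ``C`` of the lower impeller (m).
    impeller_spacing:
        Distance between the two impeller planes (m).
    stirrer_rpm:
        Shaft speed ``N`` (revolutions per minute).
    rho_liquid:
        Broth density (kg/m3).  The broth is treated as one Newtonian
        liquid, so this converts every volume flow to a mass flow.
    """

    diameter: float = 3.0
    liquid_height: float = 7.7
    impeller_diameter: float = 1.3
    bottom_clearance: float = 1.3
    impeller_spacing: float = 3.0
    stirrer_rpm: float = 98.0
    rho_liquid: float = 1000.0

    def __post_init__(self) -> None:
        for name in (
            "diameter",
            "liquid_height",
            "impeller_diameter",
            "bottom_clearance",
            "stirrer_rpm",
            "rho_liquid",
        ):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive, got {getattr(self, name)}")
        if self.impeller_spacing < 0:
            raise GeometryError("impeller_spacing must be non-negative")
        if self.bottom_clearance + self.impeller_spacing > self.liquid_height:
            raise GeometryError("impellers do not fit inside the liquid column")

    @property
    def radius(self) -> float:
        return 0.5 * self.diameter

    @property
    def liquid_volume(self) -> float:
        """Liquid volume ``VT = pi (T/2)^2 Hl`` (m3)."""
        return math.pi * self.radius**2 * self.liquid_height

    @property
    def liquid_mass(self) -> float:
        """Total broth mass (kg)."""
        return self.rho_liquid * self.liquid_volume

    @property
    def tip_speed(self) -> float:
        """Impeller tip speed ``pi D N`` (m/s)."""
        return math.pi * self.impeller_diameter * self.stirrer_rpm / 60.0

    @property
    def impeller_heights(self) -> tuple[float, float]:
        """Axial positions of the lower and upper impeller planes (m)."""
        return (
            self.bottom_clearance,
            self.bottom_clearance + self.impeller_spacing,
        )


#: Default geometry of the 54 m3 two-Rushton penicillin fermentor.
DEFAULT_TANK = TankGeometry()
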