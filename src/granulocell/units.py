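"""Unit system and force calibration.

The simulation runs in a dimensionless system built on three anchors:

* length unit  = mean microparticle diameter ``d`` (in metres),
* acceleration = gravity, rescaled so the dimensionless gravity is 1,
* mass unit    = *effective* (buoyancy-reduced) mass of a mean-diameter
  baseline particle.

With these choices the dimensionless weight of a mean baseline particle is
exactly 1, so elastic constants written as multiples of ``d`` and the kinetic
energy relaxation threshold can be used verbatim.

The force scale of the cell is calibrated from experiment: the maximum
traction force of a human adipose-derived stem cell (~200 pN) equals the
buoyant weight of an 82 um polystyrene sphere in water, and 82 um is 82/32
times the 32 um cell diameter.  The same 82/32 rule defines the maximum cell
force for any cell size.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "QuantityKind",
    "UnitSystem",
    "buoyant_weight",
    "max_cell_force",
    "MAX_FORCE_DIAMETER_RATIO",
    "POLYSTYRENE_DENSITY",
    "WATER_DENSITY",
    "STANDARD_GRAVITY",
]

#: density of polystyrene microparticles, kg m^-3
POLYSTYRENE_DENSITY = 1070.0
#: density of the aqueous medium, kg m^-3
WATER_DENSITY = 1000.0
#: standard gravity, m s^-2
STANDARD_GRAVITY = 9.81
#: the maximum cell force equals the buoyant weight of a sphere this many
#: times the cell diameter (82 um particle / 32 um cell)
MAX_FORCE_DIAMETER_RATIO = 82.0 / 32.0


class QuantityKind(enum.Enum):
    """Physical dimension tags understood by :class:`UnitSystem`."""

    LENGTH = "length"
    TIME = "time"
    MASS = "mass"
    FORCE = "force"
    VELOCITY = "velocity"
    ENERGY = "energy"


def buoyant_weight(
    diameter: float,
    particle_density: float,
    fluid_density: float,
    g: float = STANDARD_GRAVITY,
) -> float:
    """Buoyant weight of a sphere immersed in a fluid.

    Parameters are in coherent units (SI recommended): ``diameter`` in m,
    densities in kg m^-3, ``g`` in m s^-2; the result is in N.  The value is
    ``(pi/6) d^3 (rho_p - rho_f) g`` and is negative for a particle lighter
    than the fluid.
    """
    if diameter < 0:
        raise ValueError(f"diameter must be non-negative, got {diameter}")
    if particle_density < 0 or fluid_density < 0:
        raise ValueError("densities must be non-negative")
    if g < 0:
        raise ValueError("g must be non-negative")
    return math.pi / 6.0 * diameter**3 * (particle_density - fluid_density) * g


def max_cell_force(
    cell_diameter: float,
    particle_density: float = POLYSTYRENE_DENSITY,
    fluid_density: float = WATER_DENSITY,
    g: float = STANDARD_GRAVITY,
) -> float:
    """Maximum traction force of a cell of diameter ``cell_diameter``.

    Defined as the buoyant weight of a baseline-density sphere whose diameter
    is 82/32 times the cell diameter; for a 32 um cell on polystyrene in
    water this is ~200 pN.
    """
    if cell_diameter <= 0:
        raise ValueError(f"cell diameter must be positive, got {cell_diameter}")
    return buoyant_weight(
        MAX_FORCE_DIAMETER_RATIO * cell_diameter, particle_density, fluid_density, g
    )


def max_cell_force_dimless(cell_diameter: float) -> float:
    """Maximum cell force in the dimensionless system.

    In dimensionless units a baseline sphere of diameter ``D`` has effective
    mass ``D**3`` and weight ``D**3 * g`` with ``g = 1``, so the maximum cell
    force for a cell of dimensionless diameter ``L_i`` is
    ``(82/32 * L_i)**3``.
    """
    if cell_diameter <= 0:
        raise ValueError(f"cell diameter must be positive, got {cell_diameter}")
    return (MAX_FORCE_DIAMETER_RATIO * cell_diameter) ** 3


@dataclass(frozen=True)
class UnitSystem:
    """Mapping between dimensionless simulation units and physical units.

    Attributes
    ----------
    length_unit:
        Metres per dimensionless length; by convention the mean microparticle
        diameter.
    effective_density_unit:
        Particle-fluid density contrast of the baseline material, kg m^-3
        (polystyrene in water: 70).
    gravity_phys:
        Physical gravity, m s^-2.
    gravity_dimless:
        Dimensionless gravity (1 by convention).
    """

    length_unit: float = 32e-6
    effective_density_unit: float = POLYSTYRENE_DENSITY - WATER_DENSITY
    gravity_phys: float = STANDARD_GRAVITY
    gravity_dimless: float = 1.0

    def __post_init__(self) -> None:
        if self.length_unit <= 0:
            raise ValueError("length_unit must be positive")
        if self.effective_density_unit <= 0:
            raise ValueError("effective_density_unit must be positive")
        if self.gravity_phys <= 0 or self.gravity_dimless <= 0:
            raise ValueError("gravity values must be positive")

    @property
    def time_unit(self) -> float:
        """Seconds per dimensionless time, chosen so g_dimless holds."""
        return math.sqrt(self.gravity_dimless * self.length_unit / self.gravity_phys)

    @property
    def mass_unit(self) -> float:
        """Effective mass (kg) of a mean-diameter baseline particle."""
        return self.effective_density_unit * math.pi / 6.0 * self.length_unit**3

    @property
    def force_unit(self) -> float:
        return self.mass_unit * self.length_unit / self.time_unit**2

    @property
    def velocity_unit(self) -> float:
        return self.length_unit / self.time_unit

    @property
    def energy_unit(self) -> float:
        return self.force_unit * self.length_unit

    def _scale(self, kind: QuantityKind | str) -> float:
        kind = QuantityKind(kind)
        return {
            QuantityKind.LENGTH: self.length_unit,
            QuantityKind.TIME: self.time_unit,
            QuantityKind.MASS: self.mass_unit,
            QuantityKind.FORCE: self.force_unit,
            QuantityKind.VELOCITY: self.velocity_unit,
            QuantityKind.ENERGY: self.energy_unit,
        }[kind]

    def to_dimensionless(self, value: float, kind: QuantityKind | str) -> float:
        """Convert a physical value (SI) to dimensionless units."""
        return value / self._scale(kind)

    def to_physical(self, value: float, kind: QuantityKind | str) -> float:
        """Convert a dimensionless value to physical units (SI)."""
        return value * self._scale(kind)
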