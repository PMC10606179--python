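"""Specific drying-energy calculation for a convective hot-air dryer.

The heating duty carried by the air stream over the sample tray is
``P = A * w * rho * Cp * dT`` (kW when Cp is in kJ/kg/°C), where A is the
tray area, w the air velocity, rho the air density and dT the difference
between the drying-air and ambient temperatures.  Multiplying by the
drying time t (h) and dividing by the sample mass m (kg) gives the
specific energy in kWh per kg of material:

    E = A * w * rho * Cp * dT * t / m        ("dimensional", default)

A literal variant that divides by the drying time instead of multiplying
(``E = A w rho Cp dT / (m t)``) appears in parts of the drying literature;
it is retained behind ``formula_variant="as_printed"`` but is
dimensionally inconsistent with kWh/kg and inverts the time trend, so the
dimensional form is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

__all__ = ["EnergyConfig", "specific_energy"]


@dataclass(frozen=True)
class EnergyConfig:
    """Air, tray, and sample parameters for the specific-energy calculation.

    Units: area m^2, velocity m/s, density kg/m^3, specific heat kJ/(kg °C),
    temperatures °C, mass kg, time h.
    """

    plate_area: float
    air_velocity: float
    air_density: float
    air_specific_heat: float
    air_temperature: float
    ambient_temperature: float
    sample_mass: float
    drying_time: float
    formula_variant: Literal["dimensional", "as_printed"] = "dimensional"

    def __post_init__(self) -> None:
        for name in (
            "plate_area",
            "air_velocity",
            "air_density",
            "air_specific_heat",
            "sample_mass",
            "drying_time",
        ):
            value = getattr(self, name)
            if value <= 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.air_temperature <= self.ambient_temperature:
            raise ValueError(
                f"air temperature ({self.air_temperature} °C) must exceed ambient "
                f"({self.ambient_temperature} °C)"
            )


def specific_energy(config: EnergyConfig) -> float:
    """Specific drying energy (kWh per kg of sample) for one drying run."""
    dt = config.air_temperature - config.ambient_temperature
    power_kw = (
        config.plate_area
        * config.air_velocity
        * config.air_density
        * config.air_specific_heat
        * dt
    )
    if config.formula_variant == "dimensional":
        return power_kw * config.drying_time / config.sample_mass
    if config.formula_variant == "as_printed":
        return power_kw / (config.sample_mass * config.drying_time)
    raise ValueError(f"unknown formula_variant {config.formula_variant!r}")
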