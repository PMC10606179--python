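"""Data model for thin-layer drying experiments and moisture conversions.

A drying experiment weighs a thin slab of wet material at fixed intervals
while hot air removes moisture.  Three moisture scales are used:

* wet basis ``M_WB`` — water mass as a percentage of total sample mass;
* dry basis ``M`` — kg water per kg dry solid, ``M = m_w / m_s``;
* moisture ratio ``MR = (M - M_e) / (M_0 - M_e)`` — dimensionless,
  decaying from 1 toward 0, the quantity every kinetic model predicts.

The equilibrium moisture ``M_e`` is small compared to ``M`` and ``M_0``
for hot-air drying and defaults to 0, so ``MR = M / M_0``.

Times are stored internally in seconds; CSV I/O accepts hours (samples
are weighed hourly) and thin-layer rate constants are reported per hour.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MoistureObservation",
    "DryingCurve",
    "MoistureRatioSeries",
    "DryingDataError",
    "wet_to_dry_basis",
    "dry_to_wet_basis",
    "resolve_dry_basis",
    "moisture_ratio_series",
]

#: Relative slack (fraction of dry-solid mass) within which a measured mass
#: below the dry-solid mass is attributed to balance noise and clipped.
MASS_NOISE_TOLERANCE = 0.02

#: Upper slack on moisture ratios of noisy data (MR may slightly exceed 1).
MR_NOISE_TOLERANCE = 0.02


class DryingDataError(ValueError):
    """Invalid or unresolvable drying data."""


def wet_to_dry_basis(m_wb: float) -> float:
    """Convert wet-basis moisture (% wt.) to dry basis (kg water / kg solid).

    ``M = M_WB / (100 - M_WB)``.  Inverse of :func:`dry_to_wet_basis`.

    Raises
    ------
    DryingDataError
        If ``m_wb`` is negative or >= 100 (no dry solid left).
    """
    m_wb = float(m_wb)
    if m_wb < 0.0 or m_wb >= 100.0:
        raise DryingDataError(
            f"wet-basis moisture must lie in [0, 100) % wt., got {m_wb!r}"
        )
    return m_wb / (100.0 - m_wb)


def dry_to_wet_basis(m_db: float) -> float:
    """Convert dry-basis moisture (kg/kg) to wet basis (% wt.)."""
    m_db = float(m_db)
    if m_db < 0.0:
        raise DryingDataError(f"dry-basis moisture must be >= 0, got {m_db!r}")
    return 100.0 * m_db / (1.0 + m_db)


@dataclass(frozen=True)
class MoistureObservation:
    """One weighing: time since drying start (s) with mass and/or moisture.

    Exactly one of ``mass`` (g) and ``moisture_dry_basis`` (kg/kg) may be
    absent; a curve is unusable only if both are missing at some time.
    """

    time: float
    mass: float | None = None
    moisture_dry_basis: float | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise DryingDataError(f"observation time must be >= 0, got {self.time}")
        if self.mass is None and self.moisture_dry_basis is None:
            raise DryingDataError(
                f"observation at t={self.time} s has neither mass nor dry-basis moisture"
            )
        if self.mass is not None and self.mass <= 0:
            raise DryingDataError(f"mass must be > 0 g, got {self.mass}")
        if self.moisture_dry_basis is not None and self.moisture_dry_basis < 0:
            raise DryingDataError(
                f"dry-basis moisture must be >= 0, got {self.moisture_dry_basis}"
            )


@dataclass
class DryingCurve:
    """One temperature's drying time series with slab geometry.

    Parameters
    ----------
    temperature : float
        Drying air temperature (°C).
    slab_thickness : float
        Full slab thickness L (m); diffusion acts over the half thickness L/2.
    observations : sequence of MoistureObservation
        Strictly increasing in time, first observation at t = 0.
    initial_wet_basis_moisture : float, optional
        Wet-basis moisture at t = 0 (% wt.); with the initial mass this
        determines the dry-solid mass.
    dry_solid_mass : float, optional
        Mass of the bone-dry solid (g); alternative to the wet-basis route.
    equilibrium_moisture : float
        M_e (kg/kg), 0 by default (negligible for hot-air drying).
    replicate_id : str
        Label for the replicate the series belongs to.
    """

    temperature: float
    slab_thickness: float
    observations: Sequence[MoistureObservation]
    initial_wet_basis_moisture: float | None = None
    dry_solid_mass: float | None = None
    equilibrium_moisture: float = 0.0
    replicate_id: str = "mean"

    def __post_init__(self) -> None:
        if self.slab_thickness <= 0:
            raise DryingDataError(f"slab thickness must be > 0 m, got {self.slab_thickness}")
        if self.temperature <= 0:
            raise DryingDataError(f"temperature must be > 0 °C, got {self.temperature}")
        if len(self.observations) == 0:
            raise DryingDataError("drying curve has no observations")
        times = np.array([o.time for o in self.observations], dtype=float)
        if times[0] != 0.0:
            raise DryingDataError(f"first observation must be at t=0, got t={times[0]} s")
        if np.any(np.diff(times) <= 0):
            raise DryingDataError("observation times must be strictly increasing")
        if self.initial_wet_basis_moisture is None and self.dry_solid_mass is None:
            # still resolvable when moisture_dry_basis is given everywhere
            if any(o.moisture_dry_basis is None for o in self.observations):
                raise DryingDataError(
                    "need initial_wet_basis_moisture or dry_solid_mass to resolve "
                    "dry-basis moisture from masses"
                )
        if self.equilibrium_moisture < 0:
            raise DryingDataError(
                f"equilibrium moisture must be >= 0, got {self.equilibrium_moisture}"
            )

    @property
    def times(self) -> np.ndarray:
        """Observation times (s)."""
        return np.array([o.time for o in self.observations], dtype=float)


@dataclass
class MoistureRatioSeries:
    """Dimensionless moisture-ratio curve MR(t) for one temperature."""

    times: np.ndarray
    mr_values: np.ndarray
    temperature: float
    slab_thickness: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mr_values = np.asarray(self.mr_values, dtype=float)
        if self.times.shape != self.mr_values.shape:
            raise DryingDataError("times and mr_values must have equal length")
        if abs(self.mr_values[0] - 1.0) > 1e-12:
            raise DryingDataError(
                f"moisture ratio at t=0 must equal 1, got {self.mr_values[0]}"
            )
        # round-off from the (M - M_e)/(M_0 - M_e) arithmetic may leave
        # values a few ulp below zero
        tiny = (self.mr_values < 0) & (self.mr_values >= -1e-12)
        self.mr_values[tiny] = 0.0
        if np.any(self.mr_values < 0) or np.any(self.mr_values > 1.0 + MR_NOISE_TOLERANCE):
            bad = self.mr_values[(self.mr_values < 0) | (self.mr_values > 1.0 + MR_NOISE_TOLERANCE)]
            raise DryingDataError(f"moisture ratios out of [0, 1+tol]: {bad}")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def times_h(self) -> np.ndarray:
        """Observation times in hours (rate constants are reported per hour)."""
        return self.times / 3600.0


def resolve_dry_basis(curve: DryingCurve) -> np.ndarray:
    """Dry-basis moisture M(t) (kg/kg) at every observation time.

    Uses ``moisture_dry_basis`` where given; otherwise converts masses with
    ``M(t) = (m(t) - m_s) / m_s`` where the dry-solid mass ``m_s`` comes from
    ``dry_solid_mass`` or from ``m(0) * (1 - M_WB/100)``.

    Masses slightly below ``m_s`` (within 2 % of ``m_s``, balance noise) are
    clipped to M = 0 with a warning; larger violations raise.
    """
    m_s: float | None = curve.dry_solid_mass
    if m_s is None and curve.initial_wet_basis_moisture is not None:
        m0 = curve.observations[0].mass
        if m0 is None:
            raise DryingDataError(
                "cannot derive dry-solid mass: no mass at t=0"
            )
        m_s = m0 * (1.0 - curve.initial_wet_basis_moisture / 100.0)

    out = np.empty(len(curve.observations), dtype=float)
    for i, obs in enumerate(curve.observations):
        if obs.moisture_dry_basis is not None:
            out[i] = obs.moisture_dry_basis
            continue
        if obs.mass is None or m_s is None:
            raise DryingDataError(
                f"moisture unresolvable at t={obs.time} s: no mass or dry-solid mass"
            )
        m_db = (obs.mass - m_s) / m_s
        if m_db < 0:
            if obs.mass >= m_s * (1.0 - MASS_NOISE_TOLERANCE):
                warnings.warn(
                    f"mass {obs.mass} g at t={obs.time} s slightly below dry-solid "
                    f"mass {m_s:.4g} g; clipping moisture to 0",
                    stacklevel=2,
                )
                m_db = 0.0
            else:
                raise DryingDataError(
                    f"mass {obs.mass} g at t={obs.time} s is below the dry-solid mass "
                    f"{m_s:.4g} g by more than {MASS_NOISE_TOLERANCE:.0%}"
                )
        out[i] = m_db
    return out


def moisture_ratio_series(curve: DryingCurve) -> MoistureRatioSeries:
    """Normalize a drying curve to the moisture ratio MR(t).

    ``MR(t) = (M(t) - M_e) / (M_0 - M_e)``; with the default ``M_e = 0``
    this is ``M(t) / M_0``.  MR(0) = 1 exactly by construction.
    """
    m = resolve_dry_basis(curve)
    m0 = m[0]
    me = curve.equilibrium_moisture
    if me >= m0:
        raise DryingDataError(
            f"equilibrium moisture {me} must be below initial moisture {m0}"
        )
    mr = (m - me) / (m0 - me)
    mr[0] = 1.0
    return MoistureRatioSeries(
        times=curve.times,
        mr_values=mr,
        temperature=curve.temperature,
        slab_thickness=curve.slab_thickness,
    )
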