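"""Published reference measurements for hot-air drying of tomato peel.

A small collection of reported values from a six-temperature (50–75 °C)
hot-air drying study of Rila tomato peel: per-temperature effective
diffusivities, fitted Page and Modified Page constants, Two-term
constants, drying durations, and carotenoid concentrations of extracts
from the dried peels.  These serve as real-world inputs for consistency
checks (Arrhenius activation energy, model-parameterization equivalences,
degradation percentages) where the raw weighing series are not available.
"""

from __future__ import annotations

import numpy as np

from .degradation import CarotenoidSeries

__all__ = [
    "DRYING_TEMPERATURES_C",
    "DRYING_DURATIONS_H",
    "SLAB_THICKNESS_M",
    "SAMPLE_MASS_G",
    "INITIAL_WET_BASIS_PCT",
    "FINAL_WET_BASIS_PCT",
    "TOMATO_PEEL_DEFF_M2S",
    "PAGE_CONSTANTS",
    "MODIFIED_PAGE_CONSTANTS",
    "TWO_TERM_CONSTANTS",
    "NEWTON_K",
    "lycopene_series",
    "beta_carotene_series",
]

DRYING_TEMPERATURES_C = (50.0, 55.0, 60.0, 65.0, 70.0, 75.0)

#: Drying duration (h) needed to reach ~6.42 % wt. final moisture.
DRYING_DURATIONS_H = {50.0: 11.0, 55.0: 10.0, 60.0: 9.0, 65.0: 8.0, 70.0: 7.0, 75.0: 6.0}

SLAB_THICKNESS_M = 0.01
SAMPLE_MASS_G = 30.0
INITIAL_WET_BASIS_PCT = 82.63
FINAL_WET_BASIS_PCT = 6.42

#: Effective moisture diffusivity (m^2/s) per drying temperature (°C).
TOMATO_PEEL_DEFF_M2S = {
    50.0: 1.0074e-9,
    55.0: 1.0226e-9,
    60.0: 1.1642e-9,
    65.0: 1.2441e-9,
    70.0: 1.3712e-9,
    75.0: 1.5350e-9,
}

#: Page model constants (k in h^-1, n dimensionless) per temperature.
PAGE_CONSTANTS = {
    50.0: (0.5854, 0.8494),
    55.0: (0.6901, 0.8143),
    60.0: (0.6904, 0.8661),
    65.0: (0.8978, 0.7331),
    70.0: (1.1523, 0.6865),
    75.0: (1.3681, 0.7399),
}

#: Modified Page constants (k in h^-1, n) per temperature.
MODIFIED_PAGE_CONSTANTS = {
    50.0: (0.5324, 0.8494),
    55.0: (0.6341, 0.8143),
    60.0: (0.6519, 0.8661),
    65.0: (0.8633, 0.7331),
    70.0: (1.2294, 0.6865),
    75.0: (1.5274, 0.7399),
}

#: Two-term constants (a, k1, b, k2; rates h^-1) per temperature.
TWO_TERM_CONSTANTS = {
    50.0: (0.3204, 0.2673, 0.6800, 0.7452),
    55.0: (0.1957, 0.2180, 0.8062, 0.8145),
    60.0: (0.1455, 0.2194, 0.8568, 0.7801),
    65.0: (0.3408, 0.3562, 0.6593, 1.3215),
    70.0: (0.2667, 0.4049, 0.7333, 1.6353),
    75.0: (0.0769, 0.2581, 0.9232, 1.5304),
}

#: Newton drying constant k (h^-1) per temperature.
NEWTON_K = {
    50.0: 0.5096,
    55.0: 0.5989,
    60.0: 0.6271,
    65.0: 0.7691,
    70.0: 1.0250,
    75.0: 1.2920,
}

_LYCOPENE = (95.56, 88.94, 73.39, 60.87, 40.42, 31.16)
_LYCOPENE_SD = (3.92, 2.30, 2.57, 1.99, 0.84, 1.11)
_BETA_CAROTENE = (96.22, 90.70, 80.89, 71.59, 54.32, 47.33)
_BETA_CAROTENE_SD = (1.56, 0.86, 2.39, 1.39, 1.01, 1.54)


def lycopene_series() -> CarotenoidSeries:
    """Lycopene concentration (mg/100 g dried peel) vs drying temperature."""
    return CarotenoidSeries(
        compound="lycopene",
        temperatures=np.array(DRYING_TEMPERATURES_C),
        concentrations=np.array(_LYCOPENE),
        uncertainties=np.array(_LYCOPENE_SD),
    )


def beta_carotene_series() -> CarotenoidSeries:
    """β-carotene concentration (mg/100 g dried peel) vs drying temperature."""
    return CarotenoidSeries(
        compound="beta_carotene",
        temperatures=np.array(DRYING_TEMPERATURES_C),
        concentrations=np.array(_BETA_CAROTENE),
        uncertainties=np.array(_BETA_CAROTENE_SD),
    )
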