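"""Synthetic drying and degradation data with known ground truth.

The generators emulate the structure of a hot-air drying study of thin
slabs of plant material: 30 g samples weighed hourly at six temperatures
between 50 and 75 °C, with run durations shrinking from 11 h to 6 h as the
temperature rises, an initial wet-basis moisture of 82.63 % wt., and a
10 mm slab.  Moisture-ratio curves are produced by a chosen truth model
(any registered thin-layer form, or the Fickian slab series), converted to
masses, and perturbed by additive Gaussian noise on the MR scale —
approximating a constant balance error divided by the dry mass.  A
multiplicative noise option exists for sensitivity checks.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .degradation import CarotenoidSeries, _retention
from .diffusion import GAS_CONSTANT, FickParams, fick_mr, fick_mr_first_term
from .drying_data import DryingCurve, MoistureObservation, wet_to_dry_basis
from .thin_layer_models import lookup

__all__ = [
    "GeneratorConfig",
    "StudySet",
    "DEFAULT_DURATIONS_H",
    "gen_drying_curve",
    "gen_multi_temperature_study",
    "gen_carotenoid_series",
]

#: Default run durations (h) per drying temperature (°C): hourly weighing,
#: 11 h at 50 °C shrinking to 6 h at 75 °C.
DEFAULT_DURATIONS_H: dict[float, float] = {50: 11, 55: 10, 60: 9, 65: 8, 70: 7, 75: 6}

#: Default sample and geometry: 30 g on the tray, 82.63 % wt. initial
#: moisture, 10 mm slab.
DEFAULT_INITIAL_MASS_G = 30.0
DEFAULT_INITIAL_WET_BASIS_PCT = 82.63
DEFAULT_SLAB_THICKNESS_M = 0.01


@dataclass(frozen=True)
class GeneratorConfig:
    """Ground truth and sampling layout for one synthetic drying curve."""

    truth_model: str = "newton"  # registered model name, or "fick"
    truth_params: tuple[float, ...] = (0.6,)  # model theta (h^-1), or (d_eff,)
    duration_h: float = 11.0
    time_step_h: float = 1.0
    noise_sd: float = 0.0
    noise_kind: Literal["additive", "multiplicative"] = "additive"
    replicates: int = 1
    seed: int = 0
    temperature: float = 50.0
    slab_thickness: float = DEFAULT_SLAB_THICKNESS_M
    initial_mass_g: float = DEFAULT_INITIAL_MASS_G
    initial_wet_basis_pct: float = DEFAULT_INITIAL_WET_BASIS_PCT

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.duration_h <= 0 or self.time_step_h <= 0:
            raise ValueError("duration and time step must be > 0")


@dataclass(frozen=True)
class StudySet:
    """A multi-temperature synthetic study with its Arrhenius ground truth."""

    curves: tuple[DryingCurve, ...]
    d0: float
    e_a: float
    d_eff_by_temperature: dict[float, float]


def _truth_mr(config: GeneratorConfig, t_h: np.ndarray) -> np.ndarray:
    if config.truth_model == "fick":
        params = FickParams(
            d_eff=config.truth_params[0],
            half_thickness=config.slab_thickness / 2.0,
            n_terms=int(config.truth_params[1]) if len(config.truth_params) > 1 else 50,
        )
        return fick_mr(t_h * 3600.0, params)
    spec = lookup(config.truth_model)
    return spec.evaluator(t_h, np.asarray(config.truth_params, dtype=float))


def gen_drying_curve(config: GeneratorConfig) -> DryingCurve | list[DryingCurve]:
    """Generate drying curve(s) with mass series from a known truth model.

    The truth MR(t) is evaluated on the hourly grid, perturbed with
    Gaussian noise (t = 0 kept exact so MR(0) = 1 survives normalization),
    truncated at 0 below and at 1.05 above (a warning notes truncation at
    the top), and converted to masses via the configured initial mass and
    wet-basis moisture.  Deterministic under the seed.

    The sample starts fully wet, so the t = 0 point is pinned at MR = 1
    regardless of the truth model's analytic intercept (the one-term slab
    form starts at 8/pi^2 and describes only the t > 0 decay).

    Returns a single curve when ``replicates == 1``, else a list.
    """
    t_h = np.arange(0.0, config.duration_h + 0.5 * config.time_step_h, config.time_step_h)
    mr_true = _truth_mr(config, t_h)
    mr_true[0] = 1.0
    rng = np.random.default_rng(config.seed)

    m0 = wet_to_dry_basis(config.initial_wet_basis_pct)  # initial dry-basis moisture
    m_s = config.initial_mass_g * (1.0 - config.initial_wet_basis_pct / 100.0)

    curves = []
    for rep in range(config.replicates):
        mr = mr_true.copy()
        if config.noise_sd > 0:
            noise = rng.normal(0.0, config.noise_sd, size=len(t_h))
            if config.noise_kind == "additive":
                mr = mr + noise
            else:
                mr = mr * (1.0 + noise)
            mr[0] = mr_true[0]  # keep the anchor point exact
            if np.any(mr > 1.05):
                warnings.warn("noise pushed MR above 1.05; truncating", stacklevel=2)
                mr = np.minimum(mr, 1.05)
            mr = np.maximum(mr, 0.0)
        masses = m_s * (1.0 + mr * m0)
        obs = tuple(
            MoistureObservation(time=float(t * 3600.0), mass=float(m))
            for t, m in zip(t_h, masses)
        )
        curves.append(
            DryingCurve(
                temperature=config.temperature,
                slab_thickness=config.slab_thickness,
                observations=obs,
                initial_wet_basis_moisture=config.initial_wet_basis_pct,
                replicate_id=f"rep{rep + 1}",
            )
        )
    return curves[0] if config.replicates == 1 else curves


def gen_multi_temperature_study(
    d0: float,
    e_a: float,
    half_thickness: float = DEFAULT_SLAB_THICKNESS_M / 2.0,
    temperatures: Sequence[float] = tuple(DEFAULT_DURATIONS_H),
    noise_sd: float = 0.0,
    seed: int = 0,
    durations_h: dict[float, float] | None = None,
) -> StudySet:
    """Generate a multi-temperature drying study under an Arrhenius law.

    Per-temperature diffusivities follow ``D_eff = d0 * exp(-e_a / (R T))``
    (e_a in J/mol, T in kelvin); each curve follows the one-term Fickian
    slab solution for its D_eff, so estimating D_eff per temperature and
    regressing ln(D_eff) on 1/T recovers (d0, e_a) exactly on noise-free
    output.
    """
    if len(temperatures) < 2:
        raise ValueError("need at least two temperatures for a study")
    durations = dict(DEFAULT_DURATIONS_H if durations_h is None else durations_h)
    curves = []
    d_eff_map: dict[float, float] = {}
    for i, temp in enumerate(temperatures):
        d_eff = d0 * math.exp(-e_a / (GAS_CONSTANT * (temp + 273.15)))
        d_eff_map[float(temp)] = d_eff
        duration = durations.get(temp, 8.0)
        # one-term slab truth, expressed through the generic generator: the
        # hourly decay rate is pi^2 D_eff / (4 (L/2)^2) converted to h^-1
        config = GeneratorConfig(
            truth_model="fick_first_term",
            truth_params=(math.pi**2 * d_eff * 3600.0 / (4.0 * half_thickness**2),),
            duration_h=duration,
            noise_sd=noise_sd,
            seed=seed + i,
            temperature=float(temp),
            slab_thickness=2.0 * half_thickness,
        )
        curve = gen_drying_curve(config)
        curves.append(curve)
    return StudySet(curves=tuple(curves), d0=d0, e_a=e_a, d_eff_by_temperature=d_eff_map)


def gen_carotenoid_series(
    form: str,
    params: dict[str, float],
    c_ref: float,
    temperatures: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
    compound: str = "lycopene",
) -> CarotenoidSeries:
    """Generate a concentration-vs-temperature series from a retention form.

    ``C(T) = c_ref * y(T) + N(0, noise_sd)``, truncated to stay positive;
    deterministic under the seed.
    """
    t = np.asarray(temperatures, dtype=float)
    y = _retention(form, params, t)
    rng = np.random.default_rng(seed)
    c = c_ref * y
    if noise_sd > 0:
        c = c + rng.normal(0.0, noise_sd, size=len(t))
        c = np.maximum(c, 1e-6 * c_ref)
    return CarotenoidSeries(compound=compound, temperatures=t, concentrations=c)
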