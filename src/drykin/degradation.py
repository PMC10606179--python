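"""Carotenoid thermal-degradation modeling across drying temperatures.

Lycopene and β-carotene in dried plant material degrade increasingly with
drying temperature.  Given concentrations C(T) (mg per 100 g dried
material) measured at several drying temperatures, this module computes
degradation percentages relative to a reference concentration and fits a
retention model

    y(T) = C(T) / C_ref,   0 < y <= 1, non-increasing in T,

with C_ref a fitted baseline.  Two forms are registered:

* ``logistic``:     y(T) = 1 / (1 + exp(s * (T - T_m))),  s > 0 —
  slow initial loss followed by a fast drop around a midpoint temperature
  T_m, the pattern seen in hot-air-dried tomato peel;
* ``exponential``:  y(T) = exp(-b * max(T - T_0, 0)^p),  b > 0, p >= 1 —
  no loss below an onset temperature T_0, power-law-accelerated above it.

Goodness of fit is reported on the retention scale with the same R^2,
reduced chi-square and RMSE statistics used for the drying models.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .model_fitting import gof_stats

__all__ = [
    "CarotenoidSeries",
    "DegradationFit",
    "DEGRADATION_FORMS",
    "degradation_percent",
    "fit_degradation",
    "predict_concentration",
]

DEGRADATION_FORMS = ("logistic", "exponential")


@dataclass(frozen=True)
class CarotenoidSeries:
    """Concentration vs drying temperature for one compound.

    ``concentrations`` in mg per 100 g dried material; ``temperatures`` in
    °C, strictly increasing; optional per-point standard deviations.
    """

    compound: str
    temperatures: np.ndarray
    concentrations: np.ndarray
    uncertainties: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "temperatures", np.asarray(self.temperatures, dtype=float))
        object.__setattr__(self, "concentrations", np.asarray(self.concentrations, dtype=float))
        if self.temperatures.shape != self.concentrations.shape:
            raise ValueError("temperatures and concentrations must have equal length")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be > 0")
        if self.uncertainties is not None:
            u = np.asarray(self.uncertainties, dtype=float)
            if u.shape != self.temperatures.shape:
                raise ValueError("uncertainties length mismatch")
            object.__setattr__(self, "uncertainties", u)


@dataclass(frozen=True)
class DegradationFit:
    """A fitted retention model y(T) with its baseline concentration."""

    compound: str
    form: Literal["logistic", "exponential"]
    params: dict[str, float]  # shape parameters, excluding the baseline
    reference_concentration: float  # fitted C_ref, mg/100 g
    r_squared: float
    chi_squared: float
    rmse: float
    converged: bool
    temperature_range: tuple[float, float]
    near_degenerate: bool = False

    def retention(self, temperature) -> np.ndarray:
        """Predicted retention y(T) in (0, 1]."""
        return _retention(self.form, self.params, temperature)


def _retention(form: str, params: dict[str, float], temperature) -> np.ndarray:
    t = np.asarray(temperature, dtype=float)
    if form == "logistic":
        return 1.0 / (1.0 + np.exp(params["s"] * (t - params["t_m"])))
    if form == "exponential":
        dt = np.maximum(t - params["t_0"], 0.0)
        return np.exp(-params["b"] * dt ** params["p"])
    raise ValueError(f"unknown degradation form {form!r}; valid: {DEGRADATION_FORMS}")


def degradation_percent(c_ref: float, c: float, round_to_int: bool = False) -> float:
    """Percent loss of a compound relative to a reference concentration.

    ``100 * (c_ref - c) / c_ref``.  A concentration above the reference
    yields a negative value (apparent gain) with a warning, never a silent
    clamp.  ``round_to_int`` rounds to whole percent for reporting.
    """
    if c_ref <= 0:
        raise ValueError(f"reference concentration must be > 0, got {c_ref}")
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    pct = 100.0 * (c_ref - c) / c_ref
    if pct < 0:
        warnings.warn(
            f"concentration {c} exceeds reference {c_ref}: apparent gain of "
            f"{-pct:.1f} %",
            stacklevel=2,
        )
    return float(round(pct)) if round_to_int else pct


# bounds per form: (shape parameter bounds, in order)
_FORM_PARAMS: dict[str, tuple[tuple[str, float, float], ...]] = {
    "logistic": (("s", 1e-4, 1.0), ("t_m", 0.0, 200.0)),
    "exponential": (("b", 1e-8, 1.0), ("t_0", 0.0, 100.0), ("p", 1.0, 5.0)),
}


def fit_degradation(
    series: CarotenoidSeries,
    form: Literal["logistic", "exponential"] = "logistic",
) -> DegradationFit:
    """Fit a retention model to a concentration-vs-temperature series.

    Concentrations are normalized to retention ``y_i = C_i / C_ref`` with
    the baseline ``C_ref`` fitted jointly with the shape parameters
    (initialized at the lowest-temperature concentration).  Residuals and
    the reported statistics are on the retention scale.
    """
    if form not in _FORM_PARAMS:
        raise ValueError(f"unknown degradation form {form!r}; valid: {DEGRADATION_FORMS}")
    t = series.temperatures
    c = series.concentrations
    if len(t) < 4:
        raise ValueError(f"need >= 4 points to fit a degradation model, got {len(t)}")

    names = [p[0] for p in _FORM_PARAMS[form]]
    lo = np.array([p[1] for p in _FORM_PARAMS[form]] + [0.2 * c.max()])
    hi = np.array([p[2] for p in _FORM_PARAMS[form]] + [5.0 * c.max()])

    c_ref0 = c[0]
    if form == "logistic":
        x0 = np.array([0.05, float(np.median(t)), c_ref0])
    else:
        x0 = np.array([1e-3, float(t[0]), 1.5, c_ref0])

    def resid(x):
        params = dict(zip(names, x[:-1]))
        return c / x[-1] - _retention(form, params, t)

    res = least_squares(resid, x0, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12)
    params = dict(zip(names, res.x[:-1]))
    c_ref = float(res.x[-1])
    y = c / c_ref
    pred = _retention(form, params, t)
    r2, chi2, rmse = gof_stats(y, pred, len(res.x))
    # shape parameter pinned at its lower bound means no temperature signal
    shape0 = res.x[0]
    near_degenerate = bool(shape0 <= lo[0] * (1 + 1e-6))
    if near_degenerate:
        warnings.warn(
            f"{form} degradation fit for {series.compound!r} is near-degenerate "
            "(no temperature dependence detected)",
            stacklevel=2,
        )
    return DegradationFit(
        compound=series.compound,
        form=form,
        params=params,
        reference_concentration=c_ref,
        r_squared=r2,
        chi_squared=chi2,
        rmse=rmse,
        converged=res.status > 0,
        temperature_range=(float(t[0]), float(t[-1])),
        near_degenerate=near_degenerate,
    )


def predict_concentration(fit: DegradationFit, temperature) -> np.ndarray:
    """Predicted concentration C_ref * y(T) (mg/100 g) at given temperatures.

    Extrapolation beyond the fitted temperature range is permitted — the
    retention forms are monotone so predictions stay in (0, C_ref] — but a
    warning flags it.
    """
    if not fit.converged:
        raise ValueError("cannot predict from a non-converged degradation fit")
    t = np.asarray(temperature, dtype=float)
    lo, hi = fit.temperature_range
    if np.any(t < lo) or np.any(t > hi):
        warnings.warn(
            f"extrapolating degradation fit beyond the fitted range [{lo}, {hi}] °C",
            stacklevel=2,
        )
    return fit.reference_concentration * fit.retention(t)
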