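"""Fickian slab diffusion: series solution, D_eff estimation, Arrhenius fit.

During the falling-rate period, moisture transport through a thin slab of
thickness L dried from both faces obeys Fick's second law in the moisture
ratio, ``dMR/dt = D_eff * d2MR/dz2`` on 0 <= z <= L/2, with uniform initial
moisture, zero flux at the mid-plane and the equilibrium value at the
surface.  Its solution, thickness-averaged, is the Fourier series

    MR(t) = (8/pi^2) * sum_j (2j+1)^-2 * exp(-(2j+1)^2 pi^2 D_eff t / (4 (L/2)^2))

For Fourier number Fo = D_eff t / (L/2)^2 above ~0.2 only the first term
matters, so ln(MR) is linear in t with slope -pi^2 D_eff / (4 (L/2)^2) and
intercept ln(8/pi^2): a linear regression of ln(MR) on t yields D_eff.
Across temperatures D_eff follows an Arrhenius law,
``D_eff = D_0 exp(-E_a / (R T))``, so ln(D_eff) regressed on 1/T gives the
activation energy E_a.

An implicit finite-difference solver of the same boundary-value problem is
provided as an independent numerical check on the series.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from scipy.linalg import solve_banded
from scipy.stats import linregress

from .drying_data import MoistureRatioSeries

__all__ = [
    "GAS_CONSTANT",
    "FIRST_TERM_INTERCEPT",
    "FickParams",
    "DeffEstimate",
    "ArrheniusFit",
    "fick_mr",
    "fick_mr_first_term",
    "estimate_deff",
    "fit_arrhenius",
    "fd_solve",
]

#: Universal gas constant, J/(mol K).
GAS_CONSTANT = 8.3145

#: Leading coefficient of the slab series, 8/pi^2.
FIRST_TERM_INTERCEPT = 8.0 / math.pi**2


class InsufficientDataError(ValueError):
    """Too few usable points for the requested regression."""


@dataclass(frozen=True)
class FickParams:
    """Slab-diffusion parameters: D_eff (m^2/s), half thickness L/2 (m), terms."""

    d_eff: float
    half_thickness: float
    n_terms: int = 50

    def __post_init__(self) -> None:
        if self.d_eff <= 0:
            raise ValueError(f"d_eff must be > 0, got {self.d_eff}")
        if self.half_thickness <= 0:
            raise ValueError(f"half_thickness must be > 0, got {self.half_thickness}")
        if self.n_terms < 1:
            raise ValueError(f"n_terms must be >= 1, got {self.n_terms}")


@dataclass(frozen=True)
class DeffEstimate:
    """Effective diffusivity from the linearized ln(MR) regression."""

    slope: float  # per second
    intercept: float  # on the ln(MR) scale
    d_eff: float  # m^2/s
    r_squared: float
    chi_squared: float
    rmse: float
    n_points: int
    intercept_mode: Literal["fixed", "free"]
    physical: bool = True  # False when the slope came out nonnegative


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius law ln(D_eff) = ln(D_0) - E_a / (R T) fitted across temperatures."""

    d0: float  # m^2/s
    e_a: float  # J/mol
    r_squared: float
    chi_squared: float
    rmse: float
    gas_constant: float = GAS_CONSTANT

    def predict(self, temperature_c: float | np.ndarray) -> np.ndarray:
        """D_eff (m^2/s) at the given temperature(s) in °C."""
        t_k = np.asarray(temperature_c, dtype=float) + 273.15
        return self.d0 * np.exp(-self.e_a / (self.gas_constant * t_k))


def fick_mr(t, params: FickParams):
    """Thickness-averaged moisture ratio from the slab Fourier series.

    Vectorized over ``t`` (seconds).  The series is truncated at
    ``params.n_terms`` terms; at t = 0 the partial sum approaches 1 from
    below as terms are added (sum of (2j+1)^-2 equals pi^2/8).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    rate = math.pi**2 * params.d_eff / (4.0 * params.half_thickness**2)
    j = np.arange(params.n_terms)
    odd = 2 * j + 1
    # terms: (n_terms, *t.shape)
    expo = np.exp(-np.multiply.outer(odd.astype(float) ** 2 * rate, t))
    series = np.tensordot(1.0 / odd.astype(float) ** 2, expo, axes=1)
    return FIRST_TERM_INTERCEPT * series


def fick_mr_first_term(t, d_eff: float, half_thickness: float):
    """One-term slab solution ``(8/pi^2) exp(-pi^2 D_eff t / (4 (L/2)^2))``.

    Accurate for Fo >= 0.2; identical to :func:`fick_mr` with ``n_terms=1``.
    """
    t = np.asarray(t, dtype=float)
    rate = math.pi**2 * d_eff / (4.0 * half_thickness**2)
    return FIRST_TERM_INTERCEPT * np.exp(-rate * t)


def estimate_deff(
    series: MoistureRatioSeries,
    intercept_mode: Literal["fixed", "free"] = "fixed",
) -> DeffEstimate:
    """Estimate D_eff from the slope of ln(MR) vs t.

    Usable points are those with t > 0 and MR > 0 (the log of a fully dry
    point is undefined; such points are dropped with a warning).  With
    ``intercept_mode="fixed"`` the intercept is pinned at ln(8/pi^2), the
    analytic value of the one-term solution; ``"free"`` estimates it.

    ``D_eff = -slope * 4 * (L/2)^2 / pi^2``.  Goodness-of-fit statistics are
    computed on the ln(MR) scale; the reduced chi-square divides by N minus
    the number of fitted coefficients (1 fixed, 2 free).
    """
    t = series.times
    mr = series.mr_values
    usable = (t > 0) & (mr > 0)
    n_dropped = int(np.sum((t > 0) & (mr <= 0)))
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} fully-dry point(s) with MR <= 0 from the "
            "ln(MR) regression",
            stacklevel=2,
        )
    t_u = t[usable]
    y = np.log(mr[usable])
    n = len(t_u)
    if n < 3:
        raise InsufficientDataError(
            f"need >= 3 usable points (t > 0, MR > 0) for the D_eff regression, got {n}"
        )

    if intercept_mode == "fixed":
        c = math.log(FIRST_TERM_INTERCEPT)
        slope = float(np.sum((y - c) * t_u) / np.sum(t_u**2))
        intercept = c
        n_coef = 1
    elif intercept_mode == "free":
        res = linregress(t_u, y)
        slope = float(res.slope)
        intercept = float(res.intercept)
        n_coef = 2
    else:
        raise ValueError(f"intercept_mode must be 'fixed' or 'free', got {intercept_mode!r}")

    pred = intercept + slope * t_u
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else (1.0 if sse == 0 else -math.inf)
    chi2 = sse / (n - n_coef) if n > n_coef else math.nan
    rmse = math.sqrt(sse / n)

    half = series.slab_thickness / 2.0
    d_eff = -slope * 4.0 * half**2 / math.pi**2
    physical = slope < 0
    if not physical:
        warnings.warn(
            f"nonnegative ln(MR) slope ({slope:.3g}/s): no drying signal; "
            "D_eff estimate flagged non-physical",
            stacklevel=2,
        )
    return DeffEstimate(
        slope=slope,
        intercept=intercept,
        d_eff=d_eff,
        r_squared=r2,
        chi_squared=chi2,
        rmse=rmse,
        n_points=n,
        intercept_mode=intercept_mode,
        physical=physical,
    )


def fit_arrhenius(d_eff_by_temperature: Mapping[float, float]) -> ArrheniusFit:
    """Fit ``ln(D_eff) = ln(D_0) - E_a/(R T)`` across drying temperatures.

    Parameters
    ----------
    d_eff_by_temperature : mapping or sequence of pairs
        Temperature (°C) -> D_eff (m^2/s); at least three distinct
        temperatures, all diffusivities positive.

    Returns
    -------
    ArrheniusFit
        ``e_a`` in J/mol, ``d0`` in m^2/s, statistics on the ln(D_eff) scale
        with the reduced chi-square divided by N - 2.
    """
    if hasattr(d_eff_by_temperature, "items"):
        pairs = list(d_eff_by_temperature.items())
    else:
        pairs = [(float(t), float(v)) for t, v in d_eff_by_temperature]
    temps = np.array([p[0] for p in pairs], dtype=float)
    if len(np.unique(temps)) != len(temps):
        raise ValueError("duplicate temperatures in the Arrhenius input")
    if len(temps) < 3:
        raise InsufficientDataError(
            f"need >= 3 temperatures for the Arrhenius fit, got {len(temps)}"
        )
    d = np.array([p[1] for p in pairs], dtype=float)
    if np.any(d <= 0):
        raise ValueError("all diffusivities must be > 0")

    x = 1.0 / (temps + 273.15)
    y = np.log(d)
    res = linregress(x, y)
    e_a = -float(res.slope) * GAS_CONSTANT
    d0 = math.exp(float(res.intercept))

    pred = res.intercept + res.slope * x
    sse = float(np.sum((y - pred) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    n = len(temps)
    return ArrheniusFit(
        d0=d0,
        e_a=e_a,
        r_squared=1.0 - sse / sst if sst > 0 else 1.0,
        chi_squared=sse / (n - 2),
        rmse=math.sqrt(sse / n),
    )


def fd_solve(
    d_eff: float,
    half_thickness: float,
    times,
    n_nodes: int = 201,
    scheme: Literal["crank-nicolson", "backward-euler"] = "crank-nicolson",
    temperature: float = 25.0,
) -> MoistureRatioSeries:
    """Finite-difference solution of the slab diffusion problem.

    Solves ``dMR/dt = D_eff d2MR/dz2`` on 0 <= z <= L/2 with MR(z, 0) = 1,
    zero flux at the mid-plane z = 0 and MR = 0 at the surface z = L/2,
    by an unconditionally stable implicit scheme, and returns the
    thickness-averaged MR at the requested times.  Serves as an independent
    numerical check on :func:`fick_mr`.

    The first steps use backward Euler regardless of ``scheme`` to damp the
    initial surface discontinuity (Rannacher start-up); time steps ramp up
    geometrically, capped so the diffusion number D_eff dt / dz^2 <= 10.
    """
    if d_eff <= 0 or half_thickness <= 0:
        raise ValueError("d_eff and half_thickness must be > 0")
    if n_nodes < 11:
        raise ValueError(f"n_nodes must be >= 11, got {n_nodes}")
    times = np.asarray(times, dtype=float)
    if np.any(times < 0) or np.any(np.diff(times) < 0):
        raise ValueError("times must be sorted and nonnegative")
    if scheme not in ("crank-nicolson", "backward-euler"):
        raise ValueError(f"unknown scheme {scheme!r}")

    dz = half_thickness / (n_nodes - 1)
    dt_max = 10.0 * dz**2 / d_eff  # diffusion-number cap
    # start small relative to the fastest decaying resolved mode
    dt0 = 0.01 * dz**2 / d_eff

    u = np.ones(n_nodes)
    u[-1] = 0.0  # surface at equilibrium from t=0+

    def step(u: np.ndarray, dt: float, theta: float) -> np.ndarray:
        """One theta-scheme step (theta=1 backward Euler, 0.5 Crank-Nicolson)."""
        r = d_eff * dt / dz**2
        n = n_nodes
        # banded matrix for implicit part: (I - theta*r*Lap)
        ab = np.zeros((3, n))
        ab[0, 1:] = -theta * r  # superdiag
        ab[1, :] = 1.0 + 2.0 * theta * r
        ab[2, :-1] = -theta * r  # subdiag
        # zero-flux at node 0: ghost u[-1] = u[1] -> coefficient doubling
        ab[0, 1] = -2.0 * theta * r
        # Dirichlet at the last node
        ab[1, -1] = 1.0
        ab[0, -1] = 0.0
        ab[2, -2] = 0.0
        # explicit part
        rhs = u.copy()
        lam = (1.0 - theta) * r
        if lam != 0.0:
            lap = np.empty(n)
            lap[1:-1] = u[:-2] - 2.0 * u[1:-1] + u[2:]
            lap[0] = 2.0 * (u[1] - u[0])
            lap[-1] = 0.0
            rhs += lam * lap
        rhs[-1] = 0.0
        return solve_banded((1, 1), ab, rhs)

    theta_main = 1.0 if scheme == "backward-euler" else 0.5

    # integrate, recording the average at each requested time
    out = np.empty(len(times))
    t_now = 0.0
    dt = dt0
    n_startup = 4  # backward-Euler start-up steps
    n_done = 0
    for i, t_req in enumerate(times):
        if t_req == 0.0:
            out[i] = 1.0  # initial condition (uniform moisture)
            continue
        while t_now < t_req - 1e-12 * max(t_req, 1.0):
            dt_use = min(dt, dt_max, t_req - t_now)
            theta = 1.0 if n_done < n_startup else theta_main
            u = step(u, dt_use, theta)
            t_now += dt_use
            n_done += 1
            dt = min(dt * 1.05, dt_max)
        out[i] = np.trapezoid(u, dx=dz) / half_thickness

    # series has mr[0]=1 requirement only when times start at 0
    return MoistureRatioSeries(
        times=times,
        mr_values=out,
        temperature=temperature,
        slab_thickness=2.0 * half_thickness,
    ) if times[0] == 0.0 else MoistureRatioSeries(
        times=np.concatenate([[0.0], times]),
        mr_values=np.concatenate([[1.0], out]),
        temperature=temperature,
        slab_thickness=2.0 * half_thickness,
    )
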