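"""Nonlinear least-squares fitting, goodness of fit, ranking, Hartley Fmax.

Each thin-layer model is fitted to a moisture-ratio series by bounded
least squares (trust-region reflective) minimizing the sum of squared MR
residuals, started from the model's initializer plus a deterministic
multi-start grid.  Fits are compared with three statistics:

    RMSE  = sqrt(SSE / N)
    chi2  = SSE / (N - n)            (reduced chi-square; n = parameter count)
    R^2   = 1 - SSE / SST

where SST centers the experimental values on their own mean by default.
An "as_printed" R^2 variant centering on the mean of the *predicted*
values is kept for comparability with reports that use that convention.

Ranking is a deterministic total order: RMSE ascending, then reduced
chi-square ascending, then R^2 descending, then fewer parameters, then
model name.  RMSE and chi-square are quantized at 1e-8 for ranking, so
fits that are indistinguishable at numerical precision (e.g. nested
models reproducing noise-free data exactly) count as ties and the
parameter-count tie-break decides.

Hartley's Fmax test checks homogeneity of replicate variances; its
critical value is obtained by Monte-Carlo simulation of normal groups
under the homogeneous null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import least_squares

from .drying_data import MoistureRatioSeries
from .thin_layer_models import ModelSpec, lookup

__all__ = [
    "FitResult",
    "RankTable",
    "FitOptions",
    "fit_model",
    "gof_stats",
    "fit_all",
    "hartley_fmax",
    "InsufficientDataError",
]


class InsufficientDataError(ValueError):
    """Fewer observations than the model has parameters."""


@dataclass(frozen=True)
class FitOptions:
    """Optimizer settings: multi-start count, tolerances, R^2 variant."""

    n_starts: int = 8
    tol: float = 1e-10
    r2_variant: Literal["conventional", "as_printed"] = "conventional"


@dataclass(frozen=True)
class FitResult:
    """One model's best fit to one curve, with statistics."""

    model: str
    theta_hat: np.ndarray
    sse: float
    r_squared: float
    chi_squared: float
    rmse: float
    n_obs: int
    n_params: int
    converged: bool
    n_starts_used: int
    error: str | None = None

    @property
    def params(self) -> dict[str, float]:
        return dict(zip(lookup(self.model).parameter_names, self.theta_hat))


@dataclass
class RankTable:
    """FitResults for one curve, ordered by the ranking criterion."""

    results: list[FitResult]
    criterion: str = "rmse, chi_squared, -r_squared, n_params, name"

    def __iter__(self):
        return iter(self.results)

    def __len__(self):
        return len(self.results)

    def best(self) -> FitResult:
        return self.results[0]


def gof_stats(
    mr_exp,
    mr_pred,
    n_params: int,
    r2_variant: Literal["conventional", "as_printed"] = "conventional",
) -> tuple[float, float, float]:
    """(R^2, reduced chi-square, RMSE) of predictions against observations.

    ``r2_variant="as_printed"`` centers the total sum of squares on the mean
    of the predicted values instead of the experimental ones.
    """
    e = np.asarray(mr_exp, dtype=float)
    p = np.asarray(mr_pred, dtype=float)
    if e.shape != p.shape:
        raise ValueError(f"length mismatch: {e.shape} vs {p.shape}")
    n = len(e)
    if n < 1:
        raise ValueError("need at least one observation")
    sse = float(np.sum((e - p) ** 2))
    rmse = math.sqrt(sse / n)
    if n <= n_params:
        raise InsufficientDataError(
            f"reduced chi-square undefined: N={n} <= n_params={n_params}"
        )
    chi2 = sse / (n - n_params)
    center = p.mean() if r2_variant == "as_printed" else e.mean()
    sst = float(np.sum((e - center) ** 2))
    if sst == 0.0:
        r2 = 1.0 if sse == 0.0 else -math.inf
    else:
        r2 = 1.0 - sse / sst
    return r2, chi2, rmse


def _start_grid(model: ModelSpec, x0: np.ndarray, n_starts: int) -> list[np.ndarray]:
    """Deterministic multi-start grid around the initializer.

    Rates are scaled by fixed factors, exponents and coefficients nudged by
    fixed offsets; every start is clipped strictly inside the bounds.
    """
    lo = np.array([b[0] for b in model.bounds])
    hi = np.array([b[1] for b in model.bounds])
    is_rate = np.array([name.rstrip("12") in ("k", "g", "h") for name in model.parameter_names])
    scales = [1.0, 0.5, 2.0, 0.25, 4.0, 0.1, 8.0, 1.5]
    offsets = [0.0, 0.1, -0.1, 0.2, -0.2, 0.3, -0.3, 0.05]
    starts = []
    for i in range(n_starts):
        x = x0.copy()
        x[is_rate] = x[is_rate] * scales[i % len(scales)]
        x[~is_rate] = x[~is_rate] + offsets[i % len(offsets)]
        eps = 1e-8 * (hi - lo)
        starts.append(np.clip(x, lo + eps, hi - eps))
    return starts


def fit_model(
    series: MoistureRatioSeries | tuple,
    model: ModelSpec | str,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Fit one thin-layer model to a moisture-ratio curve.

    ``series`` is normally a :class:`MoistureRatioSeries`; a raw
    ``(times_h, mr)`` pair is also accepted for fitting data that need not
    satisfy the MR(0) = 1 curve invariant (e.g. checking that a model
    refits its own synthetic output, whose intercept may differ from 1).

    Minimizes the sum of squared MR residuals over bounded parameters by a
    derivative-based trust-region method from the model's initializer plus
    a deterministic multi-start grid, and returns the best start.  The
    result is flagged ``converged=False`` when no start met the optimizer
    tolerances; it is never silently dropped.
    """
    if isinstance(model, str):
        model = lookup(model)
    if isinstance(series, MoistureRatioSeries):
        t = series.times_h
        mr = series.mr_values
    else:  # raw (times_h, mr) arrays, e.g. for model-manifold checks
        t, mr = (np.asarray(a, dtype=float) for a in series)
    n = len(mr)
    if n <= model.arity:
        raise InsufficientDataError(
            f"model {model.name!r} has {model.arity} parameters but only "
            f"{n} observations are available"
        )

    lo = np.array([b[0] for b in model.bounds])
    hi = np.array([b[1] for b in model.bounds])

    def resid(theta):
        return model.evaluator(t, theta) - mr

    best = None
    any_converged = False
    starts = _start_grid(model, model.initializer(t, mr), options.n_starts)
    for x0 in starts:
        try:
            res = least_squares(
                resid,
                x0,
                bounds=(lo, hi),
                method="trf",
                xtol=options.tol,
                ftol=options.tol,
                gtol=options.tol,
            )
        except Exception:  # a bad start must not abort the sweep
            continue
        sse = 2.0 * res.cost
        if res.status > 0:
            any_converged = True
        if best is None or sse < best[1]:
            best = (res.x, sse)

    if best is None:
        return FitResult(
            model=model.name,
            theta_hat=np.full(model.arity, np.nan),
            sse=math.nan,
            r_squared=math.nan,
            chi_squared=math.nan,
            rmse=math.nan,
            n_obs=n,
            n_params=model.arity,
            converged=False,
            n_starts_used=len(starts),
            error="all starts diverged",
        )

    theta, sse = best
    pred = model.evaluator(t, theta)
    r2, chi2, rmse = gof_stats(mr, pred, model.arity, options.r2_variant)
    return FitResult(
        model=model.name,
        theta_hat=theta,
        sse=sse,
        r_squared=r2,
        chi_squared=chi2,
        rmse=rmse,
        n_obs=n,
        n_params=model.arity,
        converged=any_converged,
        n_starts_used=len(starts),
    )


def fit_all(
    series: MoistureRatioSeries,
    model_names: Sequence[str],
    options: FitOptions = FitOptions(),
) -> RankTable:
    """Fit several models to one curve and rank them.

    Per-model failures become flagged rows (``error`` set) rather than
    aborting the sweep; failed rows sort last.
    """
    if len(model_names) == 0:
        raise ValueError("at least one model name is required")
    results = []
    for name in model_names:
        try:
            results.append(fit_model(series, name, options))
        except InsufficientDataError as exc:
            spec = lookup(name)
            results.append(
                FitResult(
                    model=name,
                    theta_hat=np.full(spec.arity, np.nan),
                    sse=math.nan,
                    r_squared=math.nan,
                    chi_squared=math.nan,
                    rmse=math.nan,
                    n_obs=len(series),
                    n_params=spec.arity,
                    converged=False,
                    n_starts_used=0,
                    error=str(exc),
                )
            )

    quantum = 1e-8  # fits equal to within numerical precision tie

    def key(r: FitResult):
        failed = r.error is not None or math.isnan(r.rmse)
        return (
            failed,
            round(r.rmse / quantum) if not failed else math.inf,
            round(r.chi_squared / quantum) if not failed else math.inf,
            -r.r_squared if not failed else math.inf,
            r.n_params,
            r.model,
        )

    return RankTable(results=sorted(results, key=key))


def hartley_fmax(
    groups: Sequence[Sequence[float]],
    n_sim: int = 20_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float, bool]:
    """Hartley's Fmax variance-homogeneity test.

    ``fmax`` is the ratio of the largest to smallest sample variance across
    groups.  The critical value at level ``alpha`` is simulated: ``n_sim``
    draws of ``k`` normal groups of the common size under the homogeneous
    null, taking the (1 - alpha) quantile of their fmax statistics.

    Returns ``(fmax, critical_value, homogeneous)``.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least two groups")
    sizes = {len(a) for a in arrs}
    if any(s < 2 for s in sizes):
        raise ValueError("every group needs at least two values")
    if len(sizes) != 1:
        raise ValueError("classical Fmax requires equal group sizes")
    n = sizes.pop()
    variances = np.array([a.var(ddof=1) for a in arrs])
    if np.any(variances == 0):
        raise ValueError("a group has zero variance; Fmax is degenerate")
    fmax = float(variances.max() / variances.min())

    rng = np.random.default_rng(seed)
    sim = rng.standard_normal((n_sim, k, n)).var(axis=2, ddof=1)
    stats = sim.max(axis=1) / sim.min(axis=1)
    critical = float(np.quantile(stats, 1.0 - alpha))
    return fmax, critical, fmax <= critical
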