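"""Registry of the ten thin-layer drying model forms.

Thin-layer models are closed-form expressions MR(t) for the moisture ratio
of a thin bed of material under constant drying conditions.  One is the
first term of the Fickian slab series; the rest are semi-theoretical forms
derived either from Newton's law of cooling (Newton, Page, Modified Page)
or from Fick's law (Henderson–Pabis and its modification, Midili,
Logarithmic, Two-term, Two-term exponential).

Rate constants (k, k1, k2, g, h) are per hour at this interface, matching
the magnitudes fitted to hourly-weighed drying runs of 6–11 h; empirical
constants (a, b, c, n) are dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .diffusion import FIRST_TERM_INTERCEPT

__all__ = [
    "ModelSpec",
    "MODEL_NAMES",
    "registry",
    "lookup",
    "evaluate",
    "page_to_modified_page",
    "rate_per_hour_to_per_second",
]

# default bounds, bracketing published tomato-peel constants with wide margin
RATE_BOUNDS = (1e-4, 50.0)  # h^-1
COEF_BOUNDS = (-2.0, 2.0)  # a, b, c
EXPONENT_BOUNDS = (0.1, 5.0)  # n


@dataclass(frozen=True)
class ModelSpec:
    """A thin-layer model: name, parameters, bounds, evaluator, initializer."""

    name: str
    parameter_names: tuple[str, ...]
    bounds: tuple[tuple[float, float], ...]
    evaluator: Callable[[np.ndarray, Sequence[float]], np.ndarray]
    initializer: Callable[[np.ndarray, np.ndarray], np.ndarray]

    @property
    def arity(self) -> int:
        return len(self.parameter_names)

    def __call__(self, t, theta):
        return evaluate(self, theta, t)


def evaluate(model: ModelSpec, theta: Sequence[float], t) -> np.ndarray:
    """Evaluate a model at times ``t`` (hours) with parameter vector ``theta``."""
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (model.arity,):
        raise ValueError(
            f"model {model.name!r} takes {model.arity} parameters "
            f"{model.parameter_names}, got {theta.shape[0] if theta.ndim else 'scalar'}"
        )
    t = np.asarray(t, dtype=float)
    return model.evaluator(t, theta)


def page_to_modified_page(k_page: float, n: float) -> float:
    """Rate constant of the Modified Page form equivalent to a Page fit.

    ``exp(-k t^n) == exp(-(k' t)^n)`` exactly when ``k' = k**(1/n)``; the
    two parameterizations describe the same curve and reach the same SSE.
    """
    if k_page <= 0 or n <= 0:
        raise ValueError(f"k_page and n must be > 0, got k={k_page}, n={n}")
    return k_page ** (1.0 / n)


def rate_per_hour_to_per_second(k: float) -> float:
    """Convert a drying rate constant from h^-1 to s^-1."""
    return k / 3600.0


def _k_init(t: np.ndarray, mr: np.ndarray) -> float:
    """Single-exponential rate guess from the mid-time point, -ln(MR)/t."""
    pos = (t > 0) & (mr > 0)
    if not np.any(pos):
        return 1.0
    tp, mp = t[pos], mr[pos]
    i = len(tp) // 2
    k = -math.log(mp[i]) / tp[i]
    return float(min(max(k, RATE_BOUNDS[0] * 1.01), RATE_BOUNDS[1] * 0.99))


def _build_registry() -> dict[str, ModelSpec]:
    r, c, e = RATE_BOUNDS, COEF_BOUNDS, EXPONENT_BOUNDS
    specs = [
        ModelSpec(
            "fick_first_term",
            ("k",),
            (r,),
            lambda t, th: FIRST_TERM_INTERCEPT * np.exp(-th[0] * t),
            lambda t, mr: np.array([_k_init(t, mr)]),
        ),
        ModelSpec(
            "newton",
            ("k",),
            (r,),
            lambda t, th: np.exp(-th[0] * t),
            lambda t, mr: np.array([_k_init(t, mr)]),
        ),
        ModelSpec(
            "page",
            ("k", "n"),
            (r, e),
            lambda t, th: np.exp(-th[0] * t ** th[1]),
            lambda t, mr: np.array([_k_init(t, mr), 1.0]),
        ),
        ModelSpec(
            "modified_page",
            ("k", "n"),
            (r, e),
            lambda t, th: np.exp(-((th[0] * t) ** th[1])),
            lambda t, mr: np.array([_k_init(t, mr), 1.0]),
        ),
        ModelSpec(
            "henderson_pabis",
            ("a", "k"),
            (c, r),
            lambda t, th: th[0] * np.exp(-th[1] * t),
            lambda t, mr: np.array([1.0, _k_init(t, mr)]),
        ),
        ModelSpec(
            "modified_henderson_pabis",
            ("a", "k", "b", "g", "c", "h"),
            (c, r, c, r, c, r),
            lambda t, th: (
                th[0] * np.exp(-th[1] * t)
                + th[2] * np.exp(-th[3] * t)
                + th[4] * np.exp(-th[5] * t)
            ),
            lambda t, mr: (lambda k: np.array([0.34, k, 0.33, k / 2, 0.33, 2 * k]))(
                _k_init(t, mr)
            ),
        ),
        ModelSpec(
            "midili",
            ("a", "k", "n", "b"),
            (c, r, e, c),
            lambda t, th: th[0] * np.exp(-th[1] * t ** th[2]) + th[3] * t,
            lambda t, mr: np.array([1.0, _k_init(t, mr), 1.0, 0.0]),
        ),
        ModelSpec(
            "logarithmic",
            ("a", "k", "b"),
            (c, r, c),
            lambda t, th: th[0] * np.exp(-th[1] * t) + th[2],
            lambda t, mr: np.array([1.0, _k_init(t, mr), 0.0]),
        ),
        ModelSpec(
            "two_term",
            ("a", "k1", "b", "k2"),
            (c, r, c, r),
            lambda t, th: th[0] * np.exp(-th[1] * t) + th[2] * np.exp(-th[3] * t),
            lambda t, mr: (lambda k: np.array([0.5, k / 2, 0.5, 2 * k]))(_k_init(t, mr)),
        ),
        ModelSpec(
            "two_term_exponential",
            ("a", "k"),
            ((0.01, 2.0), r),
            lambda t, th: th[0] * np.exp(-th[1] * t)
            + (1.0 - th[0]) * np.exp(-th[1] * th[0] * t),
            lambda t, mr: np.array([0.5, _k_init(t, mr)]),
        ),
    ]
    return {s.name: s for s in specs}


_REGISTRY = _build_registry()

MODEL_NAMES: tuple[str, ...] = tuple(_REGISTRY)


def registry() -> dict[str, ModelSpec]:
    """All ten model specs, keyed by stable name."""
    return dict(_REGISTRY)


def lookup(name: str) -> ModelSpec:
    """Fetch one model spec by name; unknown names list the valid ones."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown thin-layer model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        ) from None
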