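"""Least-squares fitting, goodness of fit, ranking, and the Fmax test."""

import math
import warnings

import numpy as np
import pytest

from drykin import (
    GeneratorConfig,
    fit_all,
    fit_model,
    gen_drying_curve,
    gof_stats,
    hartley_fmax,
    lookup,
    moisture_ratio_series,
)
from drykin.model_fitting import InsufficientDataError

T_HOURS = np.arange(0.0, 12.0)

# intercept-1 truth parameters for every registered model (the synthetic
# sample starts fully wet, so truths are chosen with MR(0) = 1)
SELF_REFIT_TRUTHS = {
    "fick_first_term": (0.55,),
    "newton": (0.6,),
    "page": (0.6, 0.85),
    "modified_page": (0.65, 0.85),
    "henderson_pabis": (1.0, 0.6),
    "modified_henderson_pabis": (0.2, 0.3, 0.5, 0.9, 0.3, 2.2),
    "midili": (1.0, 0.6, 0.9, 0.002),
    "logarithmic": (0.96, 0.6, 0.04),
    "two_term": (0.32, 0.27, 0.68, 0.75),
    "two_term_exponential": (0.35, 1.1),
}


def _normalize(name: str, theta: np.ndarray) -> np.ndarray:
    """Resolve exact label-swap non-identifiabilities before comparison."""
    if name == "two_term":
        (a, k1, b, k2) = theta
        return np.array(sorted([(k1, a), (k2, b)])).ravel()
    if name == "modified_henderson_pabis":
        (a, k, b, g, c, h) = theta
        return np.array(sorted([(k, a), (g, b), (h, c)])).ravel()
    return np.asarray(theta)


class TestGofStats:
    def test_hand_arithmetic_oracle(self):
        # SSE = 0.05^2 + 0.05^2 = 0.005; mean(exp) = 7/12,
        # SST = (5/12)^2 + (1/12)^2 + (4/12)^2 = 42/144 = 7/24
        r2, chi2, rmse = gof_stats([1, 0.5, 0.25], [1, 0.45, 0.3], n_params=1)
        assert rmse == pytest.approx(math.sqrt(0.005 / 3))
        assert chi2 == pytest.approx(0.005 / 2)
        assert r2 == pytest.approx(1 - 0.005 / (7 / 24))

    def test_perfect_fit(self):
        assert gof_stats([1, 0.5], [1, 0.5], n_params=1) == (1.0, 0.0, 0.0)

    def test_constant_observations_not_clamped(self):
        r2, _, _ = gof_stats([0.5, 0.5, 0.5], [0.4, 0.5, 0.6], n_params=1)
        assert r2 == -math.inf  # zero total variance, nonzero error

    def test_as_printed_variant_centers_on_predictions(self):
        e = np.array([1.0, 0.6, 0.3, 0.1])
        p = np.array([0.95, 0.62, 0.33, 0.08])
        r2p, chi2p, rmsep = gof_stats(e, p, 1, r2_variant="as_printed")
        sse = np.sum((e - p) ** 2)
        assert r2p == pytest.approx(1 - sse / np.sum((e - p.mean()) ** 2))
        r2c, chi2c, rmsec = gof_stats(e, p, 1)
        assert (chi2p, rmsep) == (chi2c, rmsec)  # variant changes only R^2

    def test_matches_independent_arithmetic_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            n = int(rng.integers(5, 30))
            e, p = rng.random(n), rng.random(n)
            r2, chi2, rmse = gof_stats(e, p, n_params=2)
            # brute-force reimplementation, scalar loops
            sse = sum((float(a) - float(b)) ** 2 for a, b in zip(e, p))
            mean_e = sum(map(float, e)) / n
            sst = sum((float(a) - mean_e) ** 2 for a in e)
            assert rmse == pytest.approx(math.sqrt(sse / n), abs=1e-12)
            assert chi2 == pytest.approx(sse / (n - 2), abs=1e-12)
            assert r2 == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_length_mismatch_and_undefined_chi2(self):
        with pytest.raises(ValueError, match="mismatch"):
            gof_stats([1, 2], [1], 1)
        with pytest.raises(InsufficientDataError):
            gof_stats([1, 0.5], [1, 0.5], n_params=2)


class TestFitModel:
    def test_newton_round_trip(self):
        mr = np.exp(-0.6 * T_HOURS)
        r = fit_model((T_HOURS, mr), "newton")
        assert r.theta_hat[0] == pytest.approx(0.6, rel=1e-6)
        assert r.converged

    def test_two_term_noise_free_sse(self):
        spec = lookup("two_term")
        theta = np.array([0.32, 0.27, 0.68, 0.75])
        mr = spec.evaluator(T_HOURS, theta)
        r = fit_model((T_HOURS, mr), spec)
        assert r.sse < 1e-12

    @pytest.mark.parametrize("name", sorted(SELF_REFIT_TRUTHS))
    def test_every_model_refits_its_own_data(self, name):
        spec = lookup(name)
        theta = np.array(SELF_REFIT_TRUTHS[name])
        mr = spec.evaluator(T_HOURS, theta)
        r = fit_model((T_HOURS, mr), spec)
        assert r.sse < 1e-10
        got, want = _normalize(name, r.theta_hat), _normalize(name, theta)
        assert np.allclose(got, want, rtol=1e-4, atol=1e-6)

    def test_noisy_newton_recovery_median_error(self):
        errs = []
        for seed in range(200):
            cfg = GeneratorConfig(
                truth_model="newton", truth_params=(0.6,), duration_h=11,
                noise_sd=0.01, seed=seed,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # occasional clipped points
                series = moisture_ratio_series(gen_drying_curve(cfg))
            r = fit_model(series, "newton")
            errs.append(abs(r.theta_hat[0] / 0.6 - 1))
        assert np.median(errs) < 0.05

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            fit_model((np.array([0.0, 1.0]), np.array([1.0, 0.5])), "two_term")

    def test_statistics_consistency(self, mr_series):
        series = mr_series(np.exp(-0.5 * np.arange(10.0)) + 0.01 * np.cos(np.arange(10.0)) * [0, *([1] * 9)])
        r = fit_model(series, "page")
        assert r.rmse == pytest.approx(math.sqrt(r.sse / r.n_obs))
        assert r.chi_squared == pytest.approx(r.sse / (r.n_obs - r.n_params))
        assert r.r_squared <= 1


class TestRanking:
    def test_truth_model_ranks_first(self, mr_series):
        spec = lookup("two_term")
        mr = spec.evaluator(T_HOURS, np.array([0.32, 0.27, 0.68, 0.75]))
        table = fit_all(mr_series(mr), ["newton", "page", "two_term", "logarithmic"])
        assert table.best().model == "two_term"

    def test_single_model_table(self, mr_series):
        table = fit_all(mr_series(np.exp(-0.5 * np.arange(8.0))), ["newton"])
        assert len(table) == 1

    def test_nested_models_tie_broken_by_parameter_count(self, mr_series):
        # Newton data is exactly representable by Page, Modified Page, and
        # Two-term; all reach SSE ~ 0 and the tie-break prefers fewer params
        mr = np.exp(-0.7 * T_HOURS)
        table = fit_all(mr_series(mr), ["two_term", "page", "modified_page", "newton"])
        assert table.best().model == "newton"
        rmses = [r.rmse for r in table]
        assert all(v < 1e-8 for v in rmses)

    def test_empty_model_list_rejected(self, mr_series):
        with pytest.raises(ValueError, match="at least one"):
            fit_all(mr_series([1.0, 0.5]), [])

    def test_insufficient_data_becomes_flagged_row(self, mr_series):
        series = mr_series([1.0, 0.6, 0.35])
        table = fit_all(series, ["newton", "modified_henderson_pabis"])
        rows = {r.model: r for r in table}
        assert rows["modified_henderson_pabis"].error is not None
        assert rows["newton"].error is None
        assert table.results[-1].model == "modified_henderson_pabis"  # failures last

    def test_ranking_is_deterministic(self, mr_series):
        mr = np.exp(-0.55 * T_HOURS)
        order1 = [r.model for r in fit_all(mr_series(mr), ["page", "newton", "midili"])]
        order2 = [r.model for r in fit_all(mr_series(mr), ["page", "newton", "midili"])]
        assert order1 == order2


class TestHartleyFmax:
    def test_identical_groups_are_homogeneous(self):
        g = [1.0, 1.2, 0.9]
        fmax, crit, homogeneous = hartley_fmax([g, g, g], n_sim=5000, seed=0)
        assert fmax == pytest.approx(1.0)
        assert homogeneous

    def test_statistic_is_variance_ratio(self):
        # sample variances exactly 1 and 4
        fmax, _, _ = hartley_fmax([[0.0, 1.0, 2.0], [0.0, 2.0, 4.0]], n_sim=1000, seed=0)
        assert fmax == pytest.approx(4.0)

    def test_monte_carlo_critical_value_stability(self):
        groups = [[1.0, 1.2, 0.9], [1.1, 1.0, 1.3], [0.8, 1.0, 1.1]]
        _, c1, _ = hartley_fmax(groups, n_sim=100_000, seed=1)
        _, c2, _ = hartley_fmax(groups, n_sim=100_000, seed=2)
        assert abs(c1 / c2 - 1) < 0.02

    def test_degenerate_and_invalid_groups(self):
        with pytest.raises(ValueError, match="zero variance"):
            hartley_fmax([[1.0, 1.0], [1.0, 2.0]])
        with pytest.raises(ValueError, match="equal group sizes"):
            hartley_fmax([[1.0, 2.0], [1.0, 2.0, 3.0]])
        with pytest.raises(ValueError, match="two groups"):
            hartley_fmax([[1.0, 2.0]])
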