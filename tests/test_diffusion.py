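"""Slab-diffusion series, finite-difference oracle, D_eff and Arrhenius fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drykin import (
    FIRST_TERM_INTERCEPT,
    FickParams,
    MoistureRatioSeries,
    estimate_deff,
    fd_solve,
    fick_mr,
    fick_mr_first_term,
    fit_arrhenius,
)
from drykin.datasets import TOMATO_PEEL_DEFF_M2S
from drykin.diffusion import InsufficientDataError

HALF = 0.005  # m, half of a 10 mm slab


def fo_to_seconds(fo, d_eff, half=HALF):
    return fo * half**2 / d_eff


class TestSeries:
    def test_value_at_zero_converges_to_one(self):
        p = FickParams(d_eff=1e-9, half_thickness=HALF, n_terms=10_000)
        assert fick_mr(0.0, p) == pytest.approx(1.0, abs=1e-4)

    def test_one_term_value_at_zero_is_leading_coefficient(self):
        p = FickParams(d_eff=1e-9, half_thickness=HALF, n_terms=1)
        assert fick_mr(0.0, p) == pytest.approx(0.8106, abs=5e-5)

    def test_first_term_truncation_within_half_percent_at_fo_02(self):
        d = 1.2e-9
        t = fo_to_seconds(0.2, d)
        full = fick_mr(t, FickParams(d_eff=d, half_thickness=HALF, n_terms=50))
        one = fick_mr(t, FickParams(d_eff=d, half_thickness=HALF, n_terms=1))
        assert abs(one / full - 1) < 0.005

    def test_first_term_equals_series_with_one_term(self):
        d = 1.0074e-9
        t = np.linspace(0, 8 * 3600, 20)
        a = fick_mr_first_term(t, d, HALF)
        b = fick_mr(t, FickParams(d_eff=d, half_thickness=HALF, n_terms=1))
        assert np.allclose(a, b, rtol=0, atol=1e-15)

    def test_first_term_hand_evaluation(self):
        d, t = 1.0074e-9, 3600.0
        expected = (8 / math.pi**2) * math.exp(-(math.pi**2) * d * t / 1e-4)
        assert fick_mr_first_term(t, d, 0.005) == pytest.approx(expected, rel=1e-12)

    def test_doubling_thickness_quarters_exponent(self):
        d, t = 1e-9, 7200.0
        mr1 = fick_mr_first_term(t, d, HALF)
        mr2 = fick_mr_first_term(t, d, 2 * HALF)
        expo1 = math.log(mr1 / FIRST_TERM_INTERCEPT)
        expo2 = math.log(mr2 / FIRST_TERM_INTERCEPT)
        assert expo2 == pytest.approx(expo1 / 4, rel=1e-10)

    @given(
        fo=st.floats(min_value=1e-3, max_value=2.0),
        factor=st.floats(min_value=1.1, max_value=5.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_decreasing_in_time_and_diffusivity(self, fo, factor):
        d = 1e-9
        p = FickParams(d_eff=d, half_thickness=HALF, n_terms=50)
        t = fo_to_seconds(fo, d)
        assert fick_mr(t * factor, p) < fick_mr(t, p)
        p_hi = FickParams(d_eff=d * factor, half_thickness=HALF, n_terms=50)
        assert fick_mr(t, p_hi) < fick_mr(t, p)

    def test_partial_sums_increase_at_zero(self):
        values = [
            float(fick_mr(0.0, FickParams(d_eff=1e-9, half_thickness=HALF, n_terms=n)))
            for n in (1, 2, 5, 20, 100)
        ]
        assert values == sorted(values)
        assert values[-1] <= 1.0


class TestFiniteDifferenceOracle:
    def test_matches_series_within_1e3_over_fo_range(self):
        d = 1.2e-9
        fo = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 1.0, 1.5, 2.0])
        t = fo_to_seconds(fo, d)
        series = fick_mr(t, FickParams(d_eff=d, half_thickness=HALF, n_terms=50))
        fd = fd_solve(d, HALF, np.concatenate([[0.0], t]), n_nodes=201)
        assert np.max(np.abs(fd.mr_values[1:] - series)) < 1e-3

    def test_initial_condition(self):
        fd = fd_solve(1e-9, HALF, [0.0])
        assert fd.mr_values[0] == 1.0

    def test_monotone_in_diffusivity(self):
        t = [0.0, 3600.0]
        lo = fd_solve(1e-9, HALF, t).mr_values[-1]
        hi = fd_solve(2e-9, HALF, t).mr_values[-1]
        assert hi < lo

    def test_grid_halving_converges(self):
        d = 1.2e-9
        t = [0.0, fo_to_seconds(0.3, d)]
        exact = float(fick_mr(t[1], FickParams(d_eff=d, half_thickness=HALF, n_terms=50)))
        err_coarse = abs(fd_solve(d, HALF, t, n_nodes=51).mr_values[-1] - exact)
        err_fine = abs(fd_solve(d, HALF, t, n_nodes=101).mr_values[-1] - exact)
        assert err_fine <= err_coarse + 1e-12

    def test_rejects_degenerate_grid(self):
        with pytest.raises(ValueError, match="n_nodes"):
            fd_solve(1e-9, HALF, [0.0, 1.0], n_nodes=5)
        with pytest.raises(ValueError, match="scheme"):
            fd_solve(1e-9, HALF, [0.0, 1.0], scheme="explicit")


class TestEstimateDeff:
    def _series_from_first_term(self, d_eff, thickness=0.01, hours=12):
        t = np.arange(hours + 1, dtype=float) * 3600.0
        mr = fick_mr_first_term(t, d_eff, thickness / 2)
        mr[0] = 1.0  # wet sample at t=0; one-term form applies at t > 0
        return MoistureRatioSeries(times=t, mr_values=mr, temperature=50.0,
                                   slab_thickness=thickness)

    def test_round_trip_fixed_intercept(self):
        series = self._series_from_first_term(1.2e-9)
        est = estimate_deff(series, "fixed")
        assert est.d_eff == pytest.approx(1.2e-9, rel=1e-6)
        assert est.intercept == pytest.approx(math.log(8 / math.pi**2))
        assert est.physical

    def test_free_intercept_recovers_both(self):
        series = self._series_from_first_term(0.9e-9)
        est = estimate_deff(series, "free")
        assert est.d_eff == pytest.approx(0.9e-9, rel=1e-6)
        assert math.exp(est.intercept) == pytest.approx(8 / math.pi**2, rel=1e-6)

    def test_full_series_data_restricted_to_late_times(self):
        # data from the 50-term series; regression on Fo > 0.2 only
        d, thickness = 1.3e-9, 0.01
        half = thickness / 2
        t_all = np.arange(0.0, 13.0) * 3600.0
        mr = fick_mr(t_all, FickParams(d_eff=d, half_thickness=half, n_terms=50))
        fo = d * t_all / half**2
        keep = (t_all == 0) | (fo > 0.2)
        series = MoistureRatioSeries(
            times=t_all[keep], mr_values=np.where(t_all[keep] == 0, 1.0, mr[keep]),
            temperature=50.0, slab_thickness=thickness,
        )
        est = estimate_deff(series, "fixed")
        assert est.d_eff == pytest.approx(d, rel=0.02)

    def test_constant_series_flagged_non_physical(self, mr_series):
        series = mr_series([1.0, 0.8106, 0.8106, 0.8106])
        with pytest.warns(UserWarning, match="non-physical"):
            est = estimate_deff(series)
        assert not est.physical

    def test_insufficient_points(self, mr_series):
        with pytest.raises(InsufficientDataError):
            estimate_deff(mr_series([1.0, 0.5]))

    def test_fully_dry_points_dropped_with_warning(self, mr_series):
        series = mr_series([1.0, 0.5, 0.2, 0.05, 0.0])
        with pytest.warns(UserWarning, match="fully-dry"):
            est = estimate_deff(series)
        assert est.n_points == 3


class TestArrhenius:
    def test_reference_diffusivities_give_activation_energy(self):
        fit = fit_arrhenius(dict(TOMATO_PEEL_DEFF_M2S))
        assert fit.e_a / 1000 == pytest.approx(16.27, abs=0.05)
        assert fit.r_squared == pytest.approx(0.9706, abs=1e-3)

    def test_noise_free_round_trip(self):
        d0, e_a, R = 1e-7, 20_000.0, 8.3145
        temps = [50.0, 55.0, 60.0, 65.0, 70.0, 75.0]
        d = {t: d0 * math.exp(-e_a / (R * (t + 273.15))) for t in temps}
        fit = fit_arrhenius(d)
        assert fit.e_a == pytest.approx(e_a, rel=1e-9)
        assert fit.d0 == pytest.approx(d0, rel=1e-9)

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            fit_arrhenius([(50.0, 1e-9), (50.0, 1.1e-9), (60.0, 1.2e-9)])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_arrhenius({50.0: 1e-9, 60.0: 1.2e-9})
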