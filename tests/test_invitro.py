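"""Logistic birth-death fitting: simulation, grid search, dose-response."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from lapsched.invitro import (
    DoseResponseParams,
    GrowthParams,
    estimate_carrying_capacity,
    fit_dose_response,
    grid_search_fit,
    logistic_viable,
    simulate_logistic,
    stasis_concentration,
)
from lapsched.synthetic import SyntheticConfig, generate_counts


class TestSimulateLogistic:
    def test_pure_death_matches_exponential_decay(self):
        p = GrowthParams(b=0.0, d=0.3, c=0.0, K=1e6)
        t, y1, y2 = simulate_logistic(p, 1e5, 0.0, horizon=5.0)
        np.testing.assert_allclose(y1, 1e5 * np.exp(-0.3 * t), rtol=1e-6)
        np.testing.assert_allclose(y2, 1e5 * (1 - np.exp(-0.3 * t)), rtol=1e-5)

    def test_carrying_capacity_is_a_fixed_point_without_death(self):
        p = GrowthParams(b=1.0, d=0.0, K=5e5)
        _, y1, _ = simulate_logistic(p, 5e5, 0.0, horizon=10.0)
        np.testing.assert_allclose(y1, 5e5, rtol=1e-7)

    @given(b=st.floats(0.1, 2.0), y0=st.floats(1e4, 9e5))
    def test_death_free_growth_matches_closed_form(self, b, y0):
        K = 1e6
        p = GrowthParams(b=b, d=0.0, K=K)
        t, y1, _ = simulate_logistic(p, y0, 0.0, horizon=5.0)
        expected = K * y0 * np.exp(b * t) / (K + y0 * (np.exp(b * t) - 1.0))
        np.testing.assert_allclose(y1, expected, rtol=1e-6)

    def test_counts_stay_nonnegative(self):
        p = GrowthParams(b=0.5, d=1.5, c=0.4, K=1e6)
        _, y1, y2 = simulate_logistic(p, 1e5, 1e3, horizon=20.0)
        assert (y1 >= 0).all() and (y2 >= 0).all()

    def test_zero_capacity_with_positive_birth_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(b=1.0, d=0.0, K=0.0)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            GrowthParams(b=-0.1, d=0.0)


class TestCarryingCapacity:
    def test_max_of_untreated_day5_counts(self):
        data = pd.DataFrame({
            "concentration_nM": [0.0] * 3 + [100.0],
            "day": [5.0] * 4,
            "replicate": [1, 2, 3, 1],
            "viable": [9.1e5, 8.7e5, 9.3e5, 1e5],
            "dead": [0.0] * 4,
        })
        assert estimate_carrying_capacity(data) == 9.3e5

    def test_single_replicate_returns_that_value(self):
        data = pd.DataFrame({"concentration_nM": [0.0], "day": [5.0],
                             "replicate": [1], "viable": [8e5], "dead": [0.0]})
        assert estimate_carrying_capacity(data) == 8e5

    def test_missing_untreated_day5_rejected(self):
        data = pd.DataFrame({"concentration_nM": [100.0], "day": [5.0],
                             "replicate": [1], "viable": [8e5], "dead": [0.0]})
        with pytest.raises(ValueError):
            estimate_carrying_capacity(data)

    def test_underestimates_and_approaches_true_K_on_noiseless_data(self, noiseless_counts):
        K_hat = estimate_carrying_capacity(noiseless_counts)
        assert K_hat <= 1e6
        assert K_hat > 0.9e6  # b*5 >> 1: the untreated arm nearly saturates


class TestGridSearch:
    def test_noiseless_data_at_grid_point_recovered_exactly(self):
        truth = DoseResponseParams(b0=1.4, b1=-1e-3, d0=0.02, d1=8e-4)
        cfg = SyntheticConfig(concentrations=(0.0,), noise_cv=0.0, true_params=truth)
        data = generate_counts(cfg)
        fit = grid_search_fit(data, K=1e6)
        assert fit.loc[0, "b"] == pytest.approx(1.4, abs=1e-12)
        assert fit.loc[0, "d"] == pytest.approx(0.02, abs=1e-12)
        assert fit.loc[0, "c"] == 0.0

    def test_exhaustive_minimum_matches_bruteforce_oracle(self, noisy_counts):
        """On a deliberately tiny grid, compare against per-point simulation."""
        sub = noisy_counts[noisy_counts["concentration_nM"] == 500.0]
        b_grid = np.array([0.6, 0.8, 1.0])
        d_grid = np.array([0.01, 0.05])
        got = grid_search_fit(sub, K=1e6, b_grid=b_grid, d_grid=d_grid)
        days = np.sort(sub["day"].unique())
        y1_0 = sub[sub["day"] == 0]["viable"].mean()
        y2_0 = sub[sub["day"] == 0]["dead"].mean()
        best, best_obj = None, np.inf
        for b in b_grid:
            for d in d_grid:
                _, y1, y2 = simulate_logistic(GrowthParams(b=b, d=d, K=1e6),
                                              y1_0, y2_0, 5.0, t_eval=days,
                                              rtol=1e-10, atol=1e-8)
                obj = 0.0
                for k, day in enumerate(days):
                    o = sub[sub["day"] == day]
                    obj += ((o["viable"] - y1[k]) ** 2).sum()
                    obj += ((o["dead"] - y2[k]) ** 2).sum()
                if obj < best_obj:
                    best, best_obj = (b, d), obj
        assert (got.loc[0, "b"], got.loc[0, "d"]) == best
        assert got.loc[0, "objective"] == pytest.approx(best_obj, rel=1e-4)

    def test_singleton_grid_returns_it_with_near_zero_objective(self, noiseless_counts):
        sub = noiseless_counts[noiseless_counts["concentration_nM"] == 0.0]
        dr = DoseResponseParams(b0=1.4153, b1=-0.001043, d0=0.02159, d1=8.418e-4)
        fit = grid_search_fit(sub, K=1e6, b_grid=[dr.b0], d_grid=[dr.d0])
        # objective only reflects integer rounding of the generated counts
        assert fit.loc[0, "objective"] < 1e2

    def test_empty_grid_rejected(self, noisy_counts):
        with pytest.raises(ValueError):
            grid_search_fit(noisy_counts, K=1e6, b_grid=[])


class TestDoseResponse:
    def test_exact_exponential_inputs_recovered(self):
        L = np.array([0.0, 250.0, 500.0, 1000.0, 2000.0])
        rates = pd.DataFrame({
            "concentration_nM": L,
            "b": 1.4153 * np.exp(-0.001043 * L),
            "d": 0.02159 * np.exp(8.418e-4 * L),
        })
        fit = fit_dose_response(rates)
        assert fit.b0 == pytest.approx(1.4153, rel=1e-6)
        assert fit.b1 == pytest.approx(-0.001043, rel=1e-6)
        assert fit.d0 == pytest.approx(0.02159, rel=1e-6)
        assert fit.d1 == pytest.approx(8.418e-4, rel=1e-6)

    def test_constant_death_rates_give_zero_slope(self):
        L = np.array([0.0, 500.0, 1000.0, 2000.0])
        rates = pd.DataFrame({"concentration_nM": L,
                              "b": 1.4 * np.exp(-1e-3 * L), "d": 0.02})
        fit = fit_dose_response(rates)
        assert fit.d1 == pytest.approx(0.0, abs=1e-10)

    def test_noisy_rates_recovered_within_three_published_se(self, dose_response):
        """CV-5% multiplicative noise on the rates themselves (n=7).

        Recovery is judged on the scale of the published standard errors
        attached to the true coefficients; the fitted (unweighted) NLS SEs
        understate the sampling error of heteroscedastic rates and are not
        a calibrated yardstick here.
        """
        rng = np.random.default_rng(11)
        L = np.array([0.0, 125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0])
        hits = 0
        n = 100
        for _ in range(n):
            rates = pd.DataFrame({
                "concentration_nM": L,
                "b": 1.4153 * np.exp(-0.001043 * L) * rng.lognormal(0, 0.05, L.size),
                "d": 0.02159 * np.exp(8.418e-4 * L) * rng.lognormal(0, 0.05, L.size),
            })
            fit = fit_dose_response(rates)
            ok = all(abs(getattr(fit, k) - getattr(dose_response, k))
                     <= 3 * dose_response.se[k] for k in ("b0", "b1", "d0", "d1"))
            hits += ok
        assert hits / n >= 0.95

    def test_too_few_points_rejected(self):
        rates = pd.DataFrame({"concentration_nM": [0.0, 100.0], "b": [1, 1], "d": [1, 1]})
        with pytest.raises(ValueError):
            fit_dose_response(rates)


class TestStasisConcentration:
    def test_closed_form_value(self):
        p = DoseResponseParams(b0=2.0, b1=-0.001, d0=1.0, d1=0.001)
        assert stasis_concentration(p) == pytest.approx(np.log(2) / 0.002, rel=1e-12)

    def test_equal_intercepts_mean_stasis_at_zero_dose(self):
        p = DoseResponseParams(b0=1.0, b1=-0.001, d0=1.0, d1=0.001)
        with pytest.warns(UserWarning):
            assert stasis_concentration(p) == 0.0

    def test_non_crossing_rates_rejected(self):
        p = DoseResponseParams(b0=2.0, b1=0.001, d0=1.0, d1=-0.001)
        with pytest.raises(ValueError):
            stasis_concentration(p)


@given(L=st.floats(0.0, 5000.0))
def test_rates_are_monotone_in_concentration(dose_response, L):
    """b(L) strictly falls and d(L) strictly rises when b1 < 0 < d1."""
    eps = 1.0
    assert dose_response.birth_rate(L + eps) < dose_response.birth_rate(L)
    assert dose_response.death_rate(L + eps) > dose_response.death_rate(L)


def test_closed_form_handles_zero_net_rate():
    # b = d: logistic r -> 0 limit Y0 / (1 + b Y0 t / K)
    y = logistic_viable(0.5, 0.5, 1e6, 1e5, np.array([0.0, 2.0]))
    np.testing.assert_allclose(y, [1e5, 1e5 / (1 + 0.5 * 0.1 * 2.0)], rtol=1e-5)
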