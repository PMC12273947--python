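"""Joinpoint model: segment fits, BIC selection, APC/AAPC, labels."""

import numpy as np
import pytest
from itertools import combinations

from mortrend.joinpoint import (JoinpointRegression, admissible_placements,
                                fit_joinpoint, fit_loglinear, label_trend)
from mortrend.io import RateSeries


def brute_force_select(years, rates, max_k, min_obs):
    """Independent oracle: enumerate every admissible placement, fit the
    continuous piecewise model by explicit normal equations, score with
    n*ln(SSE/n) + (2k+2)*ln(n), and apply the documented tie-breaks."""
    t = np.asarray(years, float) - years[0]
    y = np.log(np.asarray(rates, float))
    n = len(y)
    results = []
    for k in range(max_k + 1):
        placements = [()] if k == 0 else [
            c for c in combinations(range(min_obs, n - min_obs), k)
            if all(b - a >= min_obs for a, b in zip(c, c[1:]))]
        for combo in placements:
            cols = [np.ones(n), t] + [np.clip(t - t[j], 0, None) for j in combo]
            X = np.stack(cols, axis=1)
            beta = np.linalg.solve(X.T @ X, X.T @ y)
            sse = float(((y - X @ beta) ** 2).sum())
            bic = n * np.log(sse / n) + (2 * k + 2) * np.log(n)
            results.append((bic, k, combo))
    best = min(results, key=lambda r: (round(r[0], 10), r[1], r[2]))
    return best[1], best[2]


class TestSegmentFit:
    def test_noiseless_exponential(self):
        t = np.arange(10)
        rates = 100 * 1.05 ** t
        b, a, se, p = fit_loglinear(t, rates)
        assert b == pytest.approx(np.log(1.05), abs=1e-12)
        assert se == pytest.approx(0.0, abs=1e-9)

    def test_constant_series_has_zero_slope(self):
        b, _, _, _ = fit_loglinear(np.arange(8), np.full(8, 3.3))
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_slope_matches_closed_form_ols(self):
        t = np.arange(5, dtype=float)
        y = np.array([0.0, 0.1, -0.05, 0.2, 0.4])  # log rates
        b, *_ = fit_loglinear(t, np.exp(y))
        expected = ((t - t.mean()) @ (y - y.mean())) / ((t - t.mean()) ** 2).sum()
        assert b == pytest.approx(expected, abs=1e-12)

    def test_zero_rate_raises_with_policy_hint(self):
        with pytest.raises(ValueError, match="zero"):
            fit_loglinear(np.arange(5), [1, 2, 0, 2, 1])


class TestSelection:
    def test_noiseless_single_exponential_selects_no_joinpoint(self):
        years = np.arange(2000, 2023)
        rates = 2.0 * 1.04 ** np.arange(23)
        fit = JoinpointRegression().fit(years, rates)
        assert fit.n_joinpoints_ == 0
        assert fit.segments_[0].apc == pytest.approx(4.0, abs=1e-9)

    def test_noiseless_two_phase_recovers_kink(self):
        years = np.arange(2000, 2023)
        apc = np.where(years[:-1] < 2011, 0.0, 8.0)
        rates = 3.0 * np.cumprod(np.concatenate([[1.0], 1 + apc / 100]))
        fit = JoinpointRegression().fit(years, rates)
        assert fit.joinpoint_years_ == [2011]
        assert fit.segments_[0].apc == pytest.approx(0.0, abs=1e-8)
        assert fit.segments_[1].apc == pytest.approx(8.0, abs=1e-8)

    def test_continuity_at_joinpoints(self):
        years = np.arange(2000, 2023)
        rng = np.random.default_rng(7)
        apc = np.where(years[:-1] < 2012, -1.0, 9.0)
        rates = 3.0 * np.cumprod(np.concatenate([[1.0], 1 + apc / 100]))
        rates *= np.exp(rng.normal(0, 0.03, 23))
        fit = JoinpointRegression().fit(years, rates)
        for tau in fit.joinpoint_years_:
            left = fit.predict_log([tau - 1e-9])[0]
            right = fit.predict_log([tau + 1e-9])[0]
            assert left == pytest.approx(right, abs=1e-10)

    def test_selection_matches_brute_force_on_random_series(self):
        """BIC selection equals exhaustive enumeration for 50 random series
        of up to 15 points with up to 2 joinpoints."""
        rng = np.random.default_rng(123)
        for _ in range(50):
            n = rng.integers(9, 16)
            years = np.arange(2000, 2000 + n)
            k_true = rng.integers(0, 3)
            slopes = rng.normal(0, 0.08, k_true + 1)
            taus = np.sort(rng.choice(np.arange(2, n - 2), size=k_true,
                                      replace=False)) if k_true else []
            logr = np.zeros(n)
            seg = 0
            for i in range(1, n):
                if seg < len(taus) and i - 1 >= taus[seg]:
                    seg += 1
                logr[i] = logr[i - 1] + slopes[seg]
            rates = 2.5 * np.exp(logr + rng.normal(0, 0.04, n))
            fit = JoinpointRegression(max_joinpoints=2).fit(years, rates)
            k_exp, combo_exp = brute_force_select(years, rates, 2, 4)
            assert fit.n_joinpoints_ == k_exp
            assert tuple(fit.joinpoint_indices_) == combo_exp

    def test_bic_never_worse_than_straight_line(self):
        rng = np.random.default_rng(5)
        years = np.arange(2000, 2020)
        rates = 2.0 * np.exp(rng.normal(0, 0.1, 20))
        fit = JoinpointRegression().fit(years, rates)
        line = JoinpointRegression(max_joinpoints=0).fit(years, rates)
        assert fit.bic_ <= line.bic_ + 1e-12

    def test_sse_nonincreasing_in_k(self):
        rng = np.random.default_rng(11)
        years = np.arange(2000, 2023)
        rates = 3.0 * np.exp(np.linspace(0, 0.5, 23) + rng.normal(0, 0.05, 23))
        sses = []
        for k in range(3):
            t = years - years[0]
            y = np.log(rates)
            best = np.inf
            for combo in admissible_placements(23, k, 4):
                cols = [np.ones(23), t.astype(float)] + [
                    np.clip(t - t[j], 0, None).astype(float) for j in combo]
                X = np.stack(cols, axis=1)
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                best = min(best, ((y - X @ beta) ** 2).sum())
            sses.append(best)
        assert sses[0] >= sses[1] >= sses[2]

    def test_short_series_returns_straight_line(self):
        years = np.arange(2000, 2006)
        rates = [2, 2.1, 2.2, 2.0, 2.3, 2.2]
        fit = JoinpointRegression().fit(years, rates)
        assert fit.n_joinpoints_ == 0


class TestAPCAndAAPC:
    def test_apc_analytic(self):
        years = np.arange(2000, 2010)
        rates = 2.0 * 1.05 ** np.arange(10)
        fit = JoinpointRegression().fit(years, rates)
        seg = fit.segments_[0]
        assert seg.apc == pytest.approx(5.0, abs=1e-9)
        assert seg.ci_low == pytest.approx(seg.ci_high)  # noiseless: point CI

    def test_single_segment_aapc_equals_apc(self):
        rng = np.random.default_rng(3)
        years = np.arange(2000, 2012)
        rates = 2.0 * np.exp(0.03 * np.arange(12) + rng.normal(0, 0.02, 12))
        fit = JoinpointRegression(max_joinpoints=0).fit(years, rates)
        assert fit.aapc_ == pytest.approx(fit.segments_[0].apc, abs=1e-12)

    def test_two_equal_segments_aapc_is_geometric_mean(self):
        years = np.arange(2000, 2023)  # joinpoint at 2011 splits 11 + 11 intervals
        apc = np.where(years[:-1] < 2011, 0.0, 8.0)
        rates = 3.0 * np.cumprod(np.concatenate([[1.0], 1 + apc / 100]))
        fit = JoinpointRegression().fit(years, rates)
        b1, b2 = (s.slope for s in fit.segments_)
        expected = 100 * (np.exp((b1 * 11 + b2 * 11) / 22) - 1)
        assert fit.aapc_ == pytest.approx(expected, abs=1e-9)

    def test_aapc_outside_window_rejected(self):
        years = np.arange(2000, 2010)
        fit = JoinpointRegression().fit(years, 2.0 * 1.02 ** np.arange(10))
        with pytest.raises(ValueError):
            fit.aapc(1999, 2009)


class TestLabels:
    @pytest.mark.parametrize("lo, hi, expected", [
        (-0.53, 1.40, "Stable"),
        (6.17, 9.29, "Increasing"),
        (-11.49, -8.14, "Decreasing"),
    ])
    def test_label_trend(self, lo, hi, expected):
        assert label_trend(lo, hi) == expected


class TestWeightingAndOptions:
    def test_rate_weighting_changes_fit_on_heteroscedastic_series(self, rate_fixture):
        s = rate_fixture[("total", "15-19")]
        unweighted = fit_joinpoint(s)
        weighted = fit_joinpoint(s, weighting="rate")
        assert weighted.joinpoint_years_ != unweighted.joinpoint_years_ or \
            not np.allclose([seg.apc for seg in weighted.segments_],
                            [seg.apc for seg in unweighted.segments_])

    def test_zero_rate_policy(self):
        years = np.arange(2000, 2010)
        rates = np.array([2, 2, 0, 2, 2, 2, 2, 2, 2, 2.0])
        with pytest.raises(ValueError, match="zero"):
            JoinpointRegression().fit(years, rates)
        fit = JoinpointRegression(zero_rate="substitute").fit(years, rates)
        assert np.isfinite(fit.bic_)

    def test_bootstrap_ci_contains_point_estimate(self):
        rng = np.random.default_rng(9)
        years = np.arange(2000, 2023)
        apc = np.where(years[:-1] < 2012, 0.0, 8.0)
        rates = 3.0 * np.cumprod(np.concatenate([[1.0], 1 + apc / 100]))
        rates *= np.exp(rng.normal(0, 0.05, 23))
        fit = JoinpointRegression(ci_method="bootstrap", n_boot=300,
                                  random_state=0).fit(years, rates)
        for seg in fit.segments_:
            assert seg.ci_low <= seg.apc <= seg.ci_high
        assert fit.aapc_ci_[0] <= fit.aapc_ <= fit.aapc_ci_[1]

    def test_sklearn_get_set_params_roundtrip(self):
        model = JoinpointRegression(max_joinpoints=2, weighting="rate")
        params = model.get_params()
        clone = JoinpointRegression().set_params(**params)
        assert clone.get_params() == params

    def test_predict_reproduces_observations_of_noiseless_fit(self):
        years = np.arange(2000, 2023)
        apc = np.where(years[:-1] < 2011, 2.0, -3.0)
        rates = 3.0 * np.cumprod(np.concatenate([[1.0], 1 + apc / 100]))
        fit = JoinpointRegression().fit(years, rates)
        assert np.allclose(fit.predict(years), rates, rtol=1e-10)


def test_fit_joinpoint_on_rate_series(rate_fixture):
    fit = fit_joinpoint(rate_fixture[("total", "10-19")], weighting="rate")
    assert fit.joinpoint_years_ == [2013]
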