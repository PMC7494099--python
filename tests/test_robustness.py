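"""ACF estimation, decay-rate fitting, classification, KL divergence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leakyclock.robustness import (ACFResult, DistributionSummary,
                                   autocorrelation, classify_sustained,
                                   find_acf_peaks, fit_damped_cosine,
                                   fit_normalized_decay, kl_divergence,
                                   score_series, shared_edges,
                                   summarize_cohort)


def _cosine(periods=30, period=24.0, dt=0.1, noise=0.0, seed=0):
    t = np.arange(0, periods * period, dt)
    x = np.cos(2 * np.pi * t / period)
    if noise:
        x = x + np.random.default_rng(seed).normal(0, noise, len(t))
    return t, x


class TestAutocorrelation:
    def test_lag_zero_is_one(self):
        x = np.random.default_rng(1).normal(0, 1, 5000)
        res = autocorrelation(x, max_lag_steps=100)
        assert res.acf[0] == pytest.approx(1.0)

    def test_matches_direct_sum_oracle(self):
        """FFT estimator equals the literal 1/(M-n) windowed sum."""
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 1500).cumsum()  # strongly correlated series
        res = autocorrelation(x, dt=0.1, max_lag_steps=300)
        mu, s2, m = x.mean(), np.mean((x - x.mean()) ** 2), len(x)
        direct = np.array([np.sum((x[:m - n] - mu) * (x[n:] - mu)) /
                           ((m - n) * s2) for n in range(301)])
        np.testing.assert_allclose(res.acf, direct, rtol=1e-10, atol=1e-12)

    def test_pure_cosine_peaks_at_period_multiples(self):
        _, x = _cosine(periods=40)
        res = find_acf_peaks(autocorrelation(x), period_hint=24.0)
        assert len(res.peak_lags) >= 8
        np.testing.assert_allclose(res.peak_lags[:4] / 24.0,
                                   np.arange(1, 5), atol=0.02)
        assert np.all(res.peak_values > 0.95)

    def test_white_noise_acf_small(self):
        x = np.random.default_rng(3).normal(0, 1, 10000)
        res = autocorrelation(x, max_lag_steps=2400)
        frac_large = np.mean(np.abs(res.acf[1:]) > 3 / np.sqrt(len(x)))
        assert frac_large < 0.01

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            autocorrelation(np.full(5000, 7.0), max_lag_steps=100)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.arange(100.0), max_lag_steps=2400)

    def test_time_reversal_near_symmetry(self):
        x = np.random.default_rng(4).normal(0, 1, 4000).cumsum()
        a = autocorrelation(x, max_lag_steps=200).acf
        b = autocorrelation(x[::-1], max_lag_steps=200).acf
        np.testing.assert_allclose(a, b, rtol=1e-8, atol=1e-10)


def _constructed_peaks(b=0.5, a=0.0, n_peaks=8, period=24.0):
    res = ACFResult(lags=np.arange(0, 241, 0.1), acf=np.zeros(2401), dt=0.1,
                    n_samples=7200)
    k = np.arange(1, n_peaks + 1, dtype=float)
    res.peak_lags = k * period
    res.peak_values = a + np.exp(-b * k)
    return res


class TestDecayFit:
    def test_recovers_constructed_decay(self):
        res = fit_normalized_decay(_constructed_peaks(b=0.5))
        assert res.fit_success
        assert res.decay_rate == pytest.approx(0.5, abs=0.01)
        assert res.offset == pytest.approx(0.0, abs=0.01)
        assert res.period == pytest.approx(24.0, abs=0.1)

    @pytest.mark.parametrize("b", [0.1, 1.0, 3.0])
    def test_recovery_across_rates(self, b):
        res = fit_normalized_decay(_constructed_peaks(b=b))
        assert res.decay_rate == pytest.approx(b, abs=0.05)

    def test_undamped_oscillation_fits_near_zero(self):
        _, x = _cosine(periods=40)
        res = score_series(x)
        assert res.decay_rate < 0.05
        assert res.classification == "sustained"

    def test_too_few_peaks_fails_fit(self):
        res = _constructed_peaks(n_peaks=2)
        fit_normalized_decay(res)
        assert not res.fit_success
        assert res.classification == "not-sustained"

    def test_skipped_peaks_use_period_count_not_order(self):
        # drop peaks 2 and 4: indices must come from lag/period
        res = _constructed_peaks(b=0.4, n_peaks=8)
        keep = [0, 2, 4, 5, 6, 7]
        res.peak_lags = res.peak_lags[keep]
        res.peak_values = res.peak_values[keep]
        fit_normalized_decay(res)
        assert res.decay_rate == pytest.approx(0.4, abs=0.02)

    def test_affine_invariance_of_decay(self):
        _, x = _cosine(periods=35, noise=0.3, seed=7)
        r1 = score_series(x)
        r2 = score_series(5.0 * x + 40.0)
        assert r2.decay_rate == pytest.approx(r1.decay_rate, rel=1e-8)

    def test_phase_diffusion_decay_matches_ensemble_oracle(self):
        """Brownian phase noise: envelope decays as exp(-2 pi^2 D T k).

        The fitted per-period rate on the ensemble-averaged ACF must agree
        with the analytic value within 20%.
        """
        period, dt, days = 24.0, 0.1, 30
        b_true = 0.35                      # per period
        d = b_true / (2 * np.pi ** 2 * period)
        t = np.arange(0, days * 24.0, dt)
        rng = np.random.default_rng(11)
        acfs = []
        for _ in range(12):
            w = rng.normal(0, np.sqrt(d * dt), len(t)).cumsum()
            x = np.cos(2 * np.pi * (t / period + w))
            acfs.append(autocorrelation(x).acf)
        mean_acf = np.mean(acfs, axis=0)
        res = ACFResult(np.arange(0, 240.1, 0.1), mean_acf, dt,
                        n_samples=len(t))
        find_acf_peaks(res, period)
        fit_normalized_decay(res)
        assert res.decay_rate == pytest.approx(b_true, rel=0.20)

    def test_white_noise_not_sustained(self):
        x = np.random.default_rng(13).normal(0, 1, 9000)
        res = score_series(x)
        assert res.classification == "not-sustained"

    def test_cosine_crosscheck_agrees_on_clean_signal(self):
        _, x = _cosine(periods=40, noise=0.05, seed=5)
        res = score_series(x)
        assert res.cos_period == pytest.approx(res.period, rel=0.05)
        assert res.classification == "sustained"

    def test_aperiodic_wander_rejected_by_crosscheck(self):
        # integrated noise has no period; whatever peaks the finite-sample
        # ACF shows, the damped-cosine fit cannot agree with them
        x = np.random.default_rng(17).normal(0, 1, 9000).cumsum()
        res = score_series(x)
        assert res.classification == "not-sustained"

    def test_damped_cosine_parameter_recovery(self):
        t = np.arange(0, 240.1, 0.1)
        acf = 0.05 + np.cos(2 * np.pi * t / 30.0) * np.exp(-t / 60.0)
        res = ACFResult(t, acf, 0.1, n_samples=7200)
        a, period, bt = fit_damped_cosine(res, period_hint=25.0)
        assert period == pytest.approx(30.0, rel=0.01)
        assert bt == pytest.approx(30.0 / 60.0, rel=0.05)


class TestClassification:
    def test_threshold_monotonicity(self):
        res = _constructed_peaks(b=1.2)
        fit_normalized_decay(res)
        res.cos_decay_rate, res.cos_period = 1.2, 24.0
        assert not classify_sustained(res, decay_threshold=1.0)
        assert classify_sustained(res, decay_threshold=2.0)

    def test_period_disagreement_blocks_sustained(self):
        res = _constructed_peaks(b=0.5)
        fit_normalized_decay(res)
        res.cos_decay_rate, res.cos_period = 0.5, 24.0
        assert classify_sustained(res, 2.0)
        res.cos_period = 40.0  # cross-check found a different oscillation
        assert not classify_sustained(res, 2.0)


class TestKL:
    def test_identity_is_zero(self):
        edges = np.linspace(0, 3, 4)
        p = DistributionSummary(edges, np.array([300., 500., 200.]), 1000)
        q = DistributionSummary(edges, np.array([300., 500., 200.]), 1000)
        assert kl_divergence(p, q) < 0.01
        assert kl_divergence(p, q) >= 0.0

    def test_hand_computed_value(self):
        # p=(0.5,0.5), q=(0.9,0.1) -> 0.5 ln(0.5/0.9) + 0.5 ln(0.5/0.1)
        edges = np.array([0.0, 1.0, 2.0])
        p = DistributionSummary(edges, np.array([5.0, 5.0]), 10)
        q = DistributionSummary(edges, np.array([900000.0, 100000.0]), int(1e6))
        assert kl_divergence(p, q) == pytest.approx(0.5108, abs=1e-3)

    def test_mismatched_bins_rejected(self):
        p = DistributionSummary(np.linspace(0, 1, 5), np.ones(4), 4)
        q = DistributionSummary(np.linspace(0, 2, 5), np.ones(4), 4)
        with pytest.raises(ValueError):
            kl_divergence(p, q)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(deadline=None, max_examples=30)
    def test_non_negative(self, seed):
        rng = np.random.default_rng(seed)
        edges = np.linspace(0, 1, 21)
        p = DistributionSummary.from_samples(rng.random(500), edges)
        q = DistributionSummary.from_samples(rng.random(500), edges)
        assert kl_divergence(p, q) >= 0.0

    def test_shared_edges_cover_pooled_range(self):
        a = np.array([1.0, 5.0])
        b = np.array([3.0, 9.0])
        edges = shared_edges(a, b, n_bins=10)
        assert edges[0] == 1.0 and edges[-1] == 9.0 and len(edges) == 11


class TestCohortSummary:
    def test_small_example(self):
        recs = [{"sustained": True, "decay_rate": d} for d in (0.5, 1.0, 2.0)]
        s = summarize_cohort(recs)
        assert s["fraction_sustained"] == 1.0
        assert s["median_decay"] == 1.0
        assert s["q1_decay"] == 0.75 and s["q3_decay"] == 1.5

    def test_fraction_arithmetic(self):
        recs = [{"sustained": i < 905, "decay_rate": 1.0} for i in range(1000)]
        assert summarize_cohort(recs)["fraction_sustained"] == 0.905

    def test_order_invariance(self):
        rng = np.random.default_rng(5)
        recs = [{"sustained": bool(rng.integers(2)),
                 "decay_rate": float(rng.random())} for _ in range(50)]
        a = summarize_cohort(recs)
        b = summarize_cohort(list(reversed(recs)))
        assert a == b

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_cohort([])

    def test_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        rates = rng.exponential(2.0, 200)
        fracs = []
        for thr in (0.5, 1.0, 2.0, 4.0, 8.0):
            fracs.append(np.mean(rates <= thr))
        assert all(a <= b for a, b in zip(fracs, fracs[1:]))
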