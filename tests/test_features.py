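"""HRV/HRnV parameter computations against closed forms and brute-force oracles."""

import numpy as np
import pytest

from hrnv.features import (FEATURE_NAMES, dfa, dfa_fluctuations, entropy,
                           feature_vector, frequency_domain, poincare,
                           time_domain, InsufficientDataError)
from hrnv.rr import RRSeries, build_rrni

from conftest import make_seq


def sine_tachogram(freq_hz, amp_ms=30.0, mean_ms=800.0, duration_s=300.0):
    """Beat-by-beat tachogram modulated by a single sinusoid."""
    beats, t = [], 0.0
    while t < duration_s:
        rr = mean_ms + amp_ms * np.sin(2 * np.pi * freq_hz * t)
        beats.append(rr)
        t += rr / 1000.0
    return make_seq(beats)


class TestTimeDomain:
    def test_constant_series_has_zero_variability(self):
        out = time_domain(make_seq([800.0] * 10))
        assert out["sdnn"] == 0 and out["rmssd"] == 0
        assert out["nn50"] == 0 and out["pnn50"] == 0
        assert out["mean_nn"] == 800.0

    def test_rmssd_direct_formula(self):
        out = time_domain(make_seq([800, 850, 800]))
        assert out["rmssd"] == pytest.approx(50.0)

    def test_scaled_nn50_threshold_for_order_two(self):
        out = time_domain(make_seq([1600, 1710, 1600], n=2))
        # |differences| are 110 ms, above the 50*2 = 100 ms scaled threshold
        assert out["nn50n"] == 2 and out["pnn50n"] == pytest.approx(100.0)
        # but also above the plain 50 ms threshold
        assert out["nn50"] == 2

    def test_sdnn_is_sample_standard_deviation(self):
        vals = [700.0, 800.0, 900.0, 1000.0]
        out = time_domain(make_seq(vals))
        assert out["sdnn"] == pytest.approx(np.std(vals, ddof=1))

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            time_domain(make_seq([800, 810]))


class TestFrequencyDomain:
    def test_hf_oscillator_dominates_hf_band(self):
        out = frequency_domain(sine_tachogram(0.25))
        assert out["hf_norm"] > 95
        assert out["lf_hf"] < 0.05
        # a sinusoid of amplitude 30 ms carries 30^2/2 = 450 ms^2 of power
        assert out["total_power"] == pytest.approx(450.0, rel=0.1)

    def test_lf_oscillator_dominates_lf_band(self):
        out = frequency_domain(sine_tachogram(0.10))
        assert out["lf_norm"] > 95

    def test_constant_series_has_zero_power(self):
        out = frequency_domain(make_seq([800.0] * 100))
        assert out["total_power"] == 0.0
        assert np.isnan(out["lf_hf"])

    def test_norms_sum_to_100_and_total_is_band_sum(self):
        rng = np.random.default_rng(7)
        out = frequency_domain(make_seq(800 + rng.normal(0, 30, 400)))
        assert out["lf_norm"] + out["hf_norm"] == pytest.approx(100.0, abs=1e-6)
        assert out["total_power"] == pytest.approx(
            out["vlf"] + out["lf"] + out["hf"], abs=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            frequency_domain(make_seq([800.0] * 10))


class TestPoincare:
    def test_alternating_series(self):
        out = poincare(make_seq([800, 850] * 20))
        assert out["sd1"] == pytest.approx(50 / np.sqrt(2), rel=0.01)

    def test_constant_series(self):
        out = poincare(make_seq([800.0] * 10))
        assert out["sd1"] == 0 and out["sd2"] == 0
        assert np.isnan(out["sd1_sd2"])

    def test_sd1_equals_rmssd_over_sqrt2(self):
        rng = np.random.default_rng(3)
        vals = 800 + rng.normal(0, 50, 30)
        sd1 = poincare(make_seq(vals))["sd1"]
        rmssd = time_domain(make_seq(vals))["rmssd"]
        assert sd1 == pytest.approx(rmssd / np.sqrt(2), rel=0.01)

    def test_sd1_sd2_sdnn_identity(self):
        rng = np.random.default_rng(4)
        vals = 800 + rng.normal(0, 40, 400)
        p = poincare(make_seq(vals))
        sdnn = time_domain(make_seq(vals))["sdnn"]
        assert p["sd1"] ** 2 + p["sd2"] ** 2 == pytest.approx(
            2 * sdnn**2, rel=0.02)


def brute_force_entropy_counts(x, m, r):
    """O(N^2) template-matching oracle (Chebyshev distance, pairs once)."""
    N = len(x)
    def pairs(k):
        c = 0
        for i in range(N - m):
            for j in range(i + 1, N - m):
                if max(abs(x[i + l] - x[j + l]) for l in range(k)) <= r:
                    c += 1
        return c
    return pairs(m), pairs(m + 1)


class TestEntropy:
    def test_periodic_series_sampen_zero(self):
        s, _ = entropy(make_seq([800, 850, 900] * 20))
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_constant_series_apen_zero(self):
        _, a = entropy(make_seq([800.0] * 40))
        assert a == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("n,seed", [(100, 0), (200, 1), (300, 2)])
    def test_matches_brute_force_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        vals = 500 + 1000 * rng.uniform(size=n)
        s, _ = entropy(make_seq(vals), m=2, r_frac=0.2)
        r = 0.2 * np.std(vals, ddof=1)
        B, A = brute_force_entropy_counts(list(vals), 2, r)
        assert s == pytest.approx(-np.log(A / B), abs=1e-12)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            entropy(make_seq([800.0] * 10))


class TestDFA:
    def test_white_noise_short_range_exponent(self):
        # averaged over independent series to isolate the scaling exponent
        rng = np.random.default_rng(0)
        a1 = np.mean([dfa(make_seq(800 + 30 * rng.standard_normal(1000)))[0]
                      for _ in range(10)])
        assert 0.4 < a1 < 0.6

    def test_random_walk_short_range_exponent(self):
        rng = np.random.default_rng(0)
        vals = []
        for _ in range(10):
            w = np.cumsum(rng.standard_normal(1000))
            vals.append(dfa(make_seq(w - w.min() + 500))[0])
        assert 1.35 < np.mean(vals) < 1.65

    def test_linear_profile_annihilated_by_detrending(self):
        # a constant series integrates to an exactly linear profile, which
        # first-order detrending removes completely in every box
        F = dfa_fluctuations(np.full(200, 5.0), np.array([4, 10, 25]))
        np.testing.assert_allclose(F, 0.0, atol=1e-9)

    def test_short_series_flagged_missing(self):
        a1, a2 = dfa(make_seq([800.0] * 50))
        assert np.isnan(a2)


class TestFeatureVector:
    def test_registry_has_142_names_with_hrv_missing_scaled_counts(self):
        assert len(FEATURE_NAMES) == 142
        assert "hrv_nn50n" not in FEATURE_NAMES
        assert "hr2v_nn50n" in FEATURE_NAMES

    def test_full_series_yields_complete_named_vector(self):
        rng = np.random.default_rng(5)
        rr = RRSeries("p", 800 + rng.normal(0, 30, 420))
        fv = feature_vector(rr)
        assert list(fv.index) == list(FEATURE_NAMES)
        assert fv.notna().all()

    def test_hrv_block_equals_direct_computation(self):
        rng = np.random.default_rng(6)
        vals = 800 + rng.normal(0, 30, 400)
        fv = feature_vector(RRSeries("p", vals))
        direct = time_domain(build_rrni(RRSeries("p", vals), 1))
        assert fv["hrv_sdnn"] == pytest.approx(direct["sdnn"])
        assert fv["hrv_rmssd"] == pytest.approx(direct["rmssd"])

    def test_constant_series_vector(self):
        fv = feature_vector(RRSeries("p", np.full(400, 800.0)))
        assert fv["hrv_mean_nn"] == 800.0
        assert fv["hrv_sdnn"] == 0.0

    def test_scaling_covariance(self):
        # scaling RR by c scales ms-quantities by c and powers by c^2
        rng = np.random.default_rng(8)
        vals = 800 + rng.normal(0, 30, 420)
        f1 = feature_vector(RRSeries("p", vals))
        f2 = feature_vector(RRSeries("p", 1.5 * vals))
        for name in ("hrv_mean_nn", "hrv_sdnn", "hrv_rmssd", "hrv_sd1"):
            assert f2[name] == pytest.approx(1.5 * f1[name], rel=1e-6)
        assert f2["hrv_skewness"] == pytest.approx(f1["hrv_skewness"], abs=1e-9)
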