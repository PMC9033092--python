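"""Wavelet decomposition, universal thresholding, and wICA cleaning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wicaeeg.ica import fastica_decompose
from wicaeeg.wica import (
    WaveletCoefficients,
    WaveletError,
    default_n_levels,
    dwt_decompose,
    dwt_reconstruct,
    estimate_sigma,
    threshold_component,
    threshold_value,
    universal_threshold,
    wica_clean,
)


class TestDWT:
    def test_perfect_reconstruction_white_noise(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(4096)
        wc = dwt_decompose(x, "db4", 6)
        np.testing.assert_allclose(dwt_reconstruct(wc), x, atol=1e-8)

    def test_constant_signal_details_vanish(self):
        x = np.full(1024, 3.7)
        wc = dwt_decompose(x, "db4", 5)
        for d in wc.detail:
            assert np.max(np.abs(d)) < 1e-8
        # orthonormal periodized transform: approximation carries the mean
        assert wc.approximation.mean() == pytest.approx(3.7 * 2 ** (5 / 2), rel=1e-6)

    def test_impulse_sparsity(self):
        x = np.zeros(2048)
        x[1024] = 1.0
        n_levels = 5
        wc = dwt_decompose(x, "db4", n_levels)
        nnz = sum(int(np.sum(np.abs(c) > 1e-12)) for c in wc.coeffs)
        filter_len = 8  # db4
        assert nnz <= filter_len * (n_levels + 1)

    def test_too_many_levels_reports_admissible_maximum(self):
        with pytest.raises(WaveletError, match="admissible maximum"):
            dwt_decompose(np.zeros(64), "db4", 12)

    def test_default_depth_is_8_at_500hz(self):
        assert default_n_levels(500.0, 200_000) == 8
        assert default_n_levels(250.0, 100_000) == 7


class TestUniversalThreshold:
    @pytest.mark.parametrize("sigma", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("n", [100, 1000, 10_000])
    def test_closed_forms(self, sigma, n):
        assert threshold_value(sigma, n, "sqrt_2logN") == sigma * np.sqrt(2 * np.log(n))
        assert threshold_value(sigma, n, "literal_2logN") == 2 * np.log(n) * sigma

    def test_degenerate_length_gives_zero(self):
        assert threshold_value(1.0, 1, "sqrt_2logN") == 0.0
        assert threshold_value(1.0, 1, "literal_2logN") == 0.0

    def test_linearity_in_sigma(self):
        t1 = threshold_value(1.3, 5000)
        t2 = threshold_value(2.6, 5000)
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_mad_estimator_on_iid_normal_finest_details(self):
        rng = np.random.default_rng(1)
        n = 10_000
        wc = dwt_decompose(rng.standard_normal(n), "db4", 4)
        # white noise: every level is i.i.d. standard normal
        spec = universal_threshold(wc, sigma_method="finest")
        assert spec.sigma_hat == pytest.approx(1.0, rel=0.05)
        assert spec.T == pytest.approx(np.sqrt(2 * np.log(n)), rel=0.05)
        assert estimate_sigma(wc, "global") == pytest.approx(1.0, rel=0.05)
        per_level = universal_threshold(wc, sigma_method="per_level")
        assert np.allclose(per_level.level_sigmas, 1.0, rtol=0.10)

    def test_unknown_variant_and_sigma_method(self):
        wc = dwt_decompose(np.ones(64), "db4", 2)
        with pytest.raises(WaveletError):
            threshold_value(1.0, 10, "bogus")
        with pytest.raises(WaveletError):
            estimate_sigma(wc, "bogus")


class TestThresholdComponent:
    def test_zero_component(self):
        l, f, spec, frac = threshold_component(np.zeros(1024))
        assert np.all(l == 0) and np.all(f == 0)
        assert spec.T == 0.0

    def test_subthreshold_identity(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(4096)
        # literal variant: T ~ 2 ln(4096) sigma ~ 16.6 sigma, far above any coefficient
        l, f, spec, frac = threshold_component(x, variant="literal_2logN")
        assert frac == 0.0
        np.testing.assert_allclose(l, x, atol=1e-8)
        assert np.max(np.abs(f)) < 1e-8

    def test_isolated_transient_moves_to_artifact_part(self):
        rng = np.random.default_rng(3)
        n = 8192
        t = np.arange(n) / 250.0
        osc = np.sin(2 * np.pi * 10 * t) + 0.3 * rng.standard_normal(n)
        transient = np.zeros(n)
        transient[4000:4075] = 40.0 * np.hanning(75)
        s = osc + transient
        l, f, spec, frac = threshold_component(s, n_levels=6)

        def corr(a, b):
            return np.corrcoef(a, b)[0, 1]

        assert corr(l, osc) > corr(s, osc)
        assert np.sum(f * transient) / np.sum(transient**2) > 0.7

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        heavy=st.booleans(),
        variant=st.sampled_from(["sqrt_2logN", "literal_2logN"]),
        sigma_method=st.sampled_from(["per_level", "global", "finest"]),
    )
    def test_energy_never_increases(self, seed, heavy, variant, sigma_method):
        rng = np.random.default_rng(seed)
        x = rng.standard_t(2, size=2000) if heavy else rng.standard_normal(2000)
        l, f, spec, frac = threshold_component(x, variant=variant, sigma_method=sigma_method)
        assert np.linalg.norm(l) <= np.linalg.norm(x) * (1 + 1e-12)
        np.testing.assert_allclose(l + f, x, atol=1e-9)


class TestWicaClean:
    def test_artifact_free_recording_passes_through(self):
        # protocol-length segment: with no artifacts the threshold is rarely
        # exceeded and cleaning is near-transparent on every channel
        from wicaeeg.synthgen import SimulationConfig
        from wicaeeg import simulate_eeg

        cfg = SimulationConfig(
            n_channels=8, fs=250.0, duration=300.0, blink_amplitude=0.0,
            muscle_burst_rate=0.0, line_noise_amplitude=0.0, sensor_noise_rms=0.0,
            mixing_seed=11, noise_seed=11,
        )
        truth = simulate_eeg(cfg)
        res = wica_clean(truth.mixed, seed=0)
        a = res.cleaned.data - res.cleaned.data.mean(1, keepdims=True)
        b = truth.mixed.data - truth.mixed.data.mean(1, keepdims=True)
        corr = (a * b).sum(1) / (np.linalg.norm(a, axis=1) * np.linalg.norm(b, axis=1))
        assert np.all(corr >= 0.95)

    def test_neural_plus_artifact_parts_reproduce_reconstruction(self, small_artifact_truth):
        res = wica_clean(small_artifact_truth.mixed, seed=0)
        dec = res.decomposition
        lhs = dec.mixing @ (res.neural_components + res.artifact_components) + dec.mean[:, None]
        rhs = dec.mixing @ dec.sources + dec.mean[:, None]
        err = np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs)
        assert err < 1e-6

    def test_cleaned_equals_mixing_times_neural_parts(self, small_artifact_truth):
        res = wica_clean(small_artifact_truth.mixed, seed=0)
        dec = res.decomposition
        expect = dec.mixing @ res.neural_components + dec.mean[:, None]
        np.testing.assert_allclose(res.cleaned.data, expect, atol=1e-9)

    def test_second_pass_zeroes_no_more_coefficients(self, small_artifact_truth):
        res1 = wica_clean(small_artifact_truth.mixed, seed=0)
        res2 = wica_clean(res1.cleaned, seed=0)
        assert res2.fraction_coeffs_zeroed.mean() <= res1.fraction_coeffs_zeroed.mean() + 0.01

    def test_shared_decomposition_is_honoured(self, small_artifact_truth):
        dec = fastica_decompose(small_artifact_truth.mixed, seed=5)
        res = wica_clean(small_artifact_truth.mixed, decomposition=dec)
        assert res.decomposition is dec

    def test_unfiltered_broadband_recording_warns(self):
        from wicaeeg.preproc import Recording

        rng = np.random.default_rng(9)
        rec = Recording(data=rng.standard_normal((4, 30_000)) * 10, fs=250.0)
        with pytest.warns(UserWarning, match="unfiltered"):
            wica_clean(rec, seed=0, max_iter=20)
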