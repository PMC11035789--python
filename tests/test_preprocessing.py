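"""Windowing, band-pass filtering, entropies and DE feature extraction."""

import numpy as np
import pytest

from eegssl import (DEFAULT_BANDS, BandDefinition, Recording, SynthConfig,
                    bandpass, differential_entropy_gaussian,
                    extract_de_features, generate_trial, segment,
                    shannon_entropy, stft_band_power)

FS = 200.0
ALPHA = DEFAULT_BANDS[2]
BETA = DEFAULT_BANDS[3]


def _rec(signal, fs=FS, **kw):
    return Recording(signal=np.atleast_2d(signal), sampling_rate_hz=fs, **kw)


class TestSegment:
    @pytest.mark.parametrize("M,T,hop,expected_starts", [
        (1000, 200, 200, [0, 200, 400, 600, 800]),
        (1000, 200, 100, list(range(0, 801, 100))),
        (250, 200, 200, [0]),
    ])
    def test_tiling_arithmetic(self, M, T, hop, expected_starts):
        ws = segment(_rec(np.arange(M, dtype=float)), T, hop)
        assert ws.starts.tolist() == expected_starts
        assert ws.windows.shape == (len(expected_starts), 1, T)

    def test_window_content_is_half_open_slice(self):
        ws = segment(_rec(np.arange(600, dtype=float)), 200, 200)
        np.testing.assert_array_equal(ws.windows[1, 0],
                                      np.arange(200, 400, dtype=float))

    def test_window_longer_than_recording_raises(self):
        with pytest.raises(ValueError, match="exceeds"):
            segment(_rec(np.zeros(199)), 200)

    def test_default_window_is_one_second(self):
        ws = segment(_rec(np.zeros(500)))
        assert ws.window_length == 200


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, ALPHA, FS)
        assert y.std() == pytest.approx(x.std(), rel=0.05)

    def test_out_of_band_sinusoid_suppressed(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass(x, BETA, FS)
        assert np.sqrt((y**2).mean()) < 0.1 * np.sqrt((x**2).mean())

    def test_zero_in_zero_out(self):
        assert np.allclose(bandpass(np.zeros((2, 400)), ALPHA, FS), 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(np.zeros(400), BandDefinition("x", 150.0, 180.0), FS)

    def test_gamma_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            bandpass(np.random.default_rng(0).standard_normal(400),
                     DEFAULT_BANDS[4], FS)


class TestShannonEntropy:
    @pytest.mark.parametrize("p,expected", [
        ([0.5, 0.5], 1.0),
        ([1.0, 0.0, 0.0], 0.0),
        ([0.25] * 4, 2.0),
    ])
    def test_known_values_bits(self, p, expected):
        assert shannon_entropy(p) == pytest.approx(expected, abs=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            p = rng.dirichlet(np.ones(6))
            h = shannon_entropy(p)
            assert 0.0 <= h <= np.log2(6) + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            shannon_entropy([-0.1, 1.1])
        with pytest.raises(ValueError):
            shannon_entropy([0.5, 0.4])


class TestDifferentialEntropy:
    def test_unit_variance_closed_form(self):
        x = np.random.default_rng(0).standard_normal(100_000)
        expected = 0.5 * np.log(2 * np.pi * np.e)
        assert differential_entropy_gaussian(x) == pytest.approx(
            expected, abs=0.01)

    def test_variance_four(self):
        x = 2.0 * np.random.default_rng(1).standard_normal(100_000)
        expected = 0.5 * np.log(2 * np.pi * np.e * 4.0)
        assert differential_entropy_gaussian(x) == pytest.approx(
            expected, abs=0.01)

    def test_zero_entropy_variance(self):
        """sigma^2 = 1/(2 pi e) makes the log argument 1, hence DE = 0."""
        x = np.random.default_rng(2).standard_normal(200_000)
        x *= np.sqrt(1.0 / (2 * np.pi * np.e)) / x.std(ddof=1)
        assert differential_entropy_gaussian(x) == pytest.approx(0.0, abs=1e-9)

    def test_scale_equivariance(self):
        """Scaling a window by k shifts DE by exactly ln k."""
        x = np.random.default_rng(3).standard_normal(500)
        base = differential_entropy_gaussian(x)
        for k in (0.1, 2.0, 17.0):
            assert differential_entropy_gaussian(k * x) == pytest.approx(
                base + np.log(k), abs=1e-9)

    def test_strictly_increasing_in_variance(self):
        x = np.random.default_rng(4).standard_normal(500)
        des = [differential_entropy_gaussian(s * x)
               for s in np.linspace(0.5, 3.0, 8)]
        assert np.all(np.diff(des) > 0)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="zero-variance"):
            differential_entropy_gaussian(np.ones(100))
        with pytest.raises(ValueError, match="2 samples"):
            differential_entropy_gaussian([1.0])


class TestSTFTBandPower:
    def test_sinusoid_power_in_alpha(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        for band in DEFAULT_BANDS[:4]:
            p = stft_band_power(x, FS, band)[0]
            if band.name == "alpha":
                assert p == pytest.approx(0.5, rel=0.1)
            else:
                assert p < 0.05

    def test_white_noise_parseval(self):
        x = 1.5 * np.random.default_rng(5).standard_normal(int(60 * FS))
        total = sum(stft_band_power(x, FS, b)[0] for b in (
            BandDefinition("all_low", 1.0, 50.0),
            BandDefinition("all_high", 50.0, 99.0)))
        # bands cover 1-99 of the 0-100 Hz axis => ~98% of the variance
        assert total == pytest.approx(0.98 * x.var(), rel=0.1)

    def test_zero_signal(self):
        assert np.all(stft_band_power(np.zeros((2, 400)), FS, ALPHA) == 0.0)

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no STFT bins"):
            stft_band_power(np.zeros(400), FS,
                            BandDefinition("sliver", 10.1, 10.2))


class TestExtractDEFeatures:
    def test_shape_and_determinism(self, small_dataset):
        rec = small_dataset[0]
        f1 = extract_de_features(rec)
        f2 = extract_de_features(rec)
        n_expected = rec.n_samples // 200
        assert f1.values.shape == (n_expected, rec.n_channels, 5)
        np.testing.assert_array_equal(f1.values, f2.values)

    def test_alpha_dominant_trial_matches_closed_form(self):
        """Configured alpha SD 2 -> alpha DE ~ 0.5*ln(2*pi*e*4)."""
        prof = np.full((3, 5), 0.01)
        prof[:, 2] = 2.0
        cfg = SynthConfig(n_channels=2, trial_duration_s=60.0, noise_sd=0.0,
                          envelope_log_sd=0.0, band_power_profiles=prof)
        rec = generate_trial(cfg, 0, np.random.default_rng(11))
        de = extract_de_features(rec, method="filter")
        alpha_de = de.values[:, :, 2].mean()
        delta_de = de.values[:, :, 0].mean()
        assert alpha_de == pytest.approx(0.5 * np.log(2 * np.pi * np.e * 4.0),
                                         abs=0.15)
        assert delta_de < alpha_de - 3.0

    def test_filter_and_stft_methods_agree(self):
        cfg = SynthConfig(n_channels=2, trial_duration_s=30.0, noise_sd=0.0,
                          envelope_log_sd=0.0,
                          band_power_profiles=np.ones((3, 5)))
        rec = generate_trial(cfg, 0, np.random.default_rng(13))
        a = extract_de_features(rec, method="filter").values
        b = extract_de_features(rec, method="stft").values
        assert np.abs(a.mean(axis=0) - b.mean(axis=0)).max() < 0.2

    def test_sixty_second_trial_has_sixty_windows(self):
        cfg = SynthConfig(n_channels=1, trial_duration_s=60.0)
        rec = generate_trial(cfg, 0, np.random.default_rng(1))
        assert extract_de_features(rec).values.shape[0] == 60

    def test_unknown_method_rejected(self, small_dataset):
        with pytest.raises(ValueError, match="method"):
            extract_de_features(small_dataset[0], method="wavelet")
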