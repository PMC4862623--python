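"""Time-frequency front end: notch, Stockwell transform, band operations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eegfp.bands as bd
import eegfp.tf as tfm


def _rec(x, fs):
    return tfm.EEGRecording(np.atleast_2d(x), fs, ["Pz"])


def _rms(x):
    return np.sqrt(np.mean(np.square(x)))


class TestNotch:
    def test_line_frequency_attenuated(self):
        fs, t = 250.0, np.arange(0, 4, 1 / 250.0)
        out = tfm.notch_filter(_rec(np.sin(2 * np.pi * 50 * t), fs), 50.0)
        assert _rms(out.samples) < 0.1 * _rms(np.sin(2 * np.pi * 50 * t))

    def test_passband_preserved(self):
        fs, t = 250.0, np.arange(0, 4, 1 / 250.0)
        x = np.sin(2 * np.pi * 10 * t)
        out = tfm.notch_filter(_rec(x, fs), 50.0)
        assert abs(_rms(out.samples) / _rms(x) - 1) < 0.05

    def test_zeros_stay_zero(self):
        out = tfm.notch_filter(_rec(np.zeros(1000), 250.0), 50.0)
        assert np.allclose(out.samples, 0.0)

    def test_rejects_notch_at_nyquist(self):
        with pytest.raises(ValueError):
            tfm.notch_filter(_rec(np.zeros(100), 100.0), 60.0)


class TestStockwell:
    def test_peak_at_carrier_frequency(self):
        fs = 250.0
        t = np.arange(0, 2, 1 / fs)
        tf = tfm.stockwell(np.sin(2 * np.pi * 10 * t), fs)
        assert tf.freqs_hz[np.argmax(tf.amplitude.mean(axis=1))] == 10.0

    def test_zero_input_zero_map(self):
        tf = tfm.stockwell(np.zeros(500), 250.0)
        assert np.allclose(tf.amplitude, 0.0)

    def test_matches_direct_sum_oracle(self):
        """Brute-force Gaussian-window sum, sigma = 1/f, periodic images."""
        rng = np.random.default_rng(0)
        fs, dur = 64.0, 2.0
        n = int(fs * dur)
        x = rng.standard_normal(n)
        tf = tfm.stockwell(x, fs, fmin_hz=1, fmax_hz=20)
        ts = np.arange(n) / fs
        for i, f in enumerate(tf.freqs_hz):
            w = np.zeros((n, n))
            for p in range(-6, 7):
                dt = ts[:, None] - ts[None, :] - p * dur
                w += np.exp(-(dt**2) * f**2 / 2)
            w *= f / (fs * np.sqrt(2 * np.pi))
            phase = x * np.exp(-2j * np.pi * f * ts)
            oracle = np.abs((w * phase[None, :]).sum(axis=1))
            assert np.max(np.abs(oracle - tf.amplitude[i])) < 1e-6

    def test_rejects_fmax_above_nyquist(self):
        with pytest.raises(ValueError):
            tfm.stockwell(np.zeros(500), 50.0, fmax_hz=40.0)

    def test_window_longer_than_record(self):
        with pytest.raises(ValueError):
            tfm.stockwell(np.zeros(100), 250.0, fmin_hz=1.0)  # 0.4 s record


class TestResample:
    def test_constant_preserved(self):
        out = bd.resample_to_4hz(np.full(1000, 3.3), 250.0)
        assert np.allclose(out, 3.3)

    def test_block_count_at_250hz(self):
        # blocks of 62.5 samples: floor(1000 / 62.5) = 16
        assert bd.resample_to_4hz(np.arange(1000.0), 250.0).size == 16

    def test_bold_upsampling_interpolates(self):
        out = bd.resample_to_4hz(np.array([0.0, 3.0]), 1.0 / 3.0)
        # t = 0.75 s sits a quarter of the way through the TR
        assert out[3] == pytest.approx(0.75)

    def test_block_means_match_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(500)
        out = bd.resample_to_4hz(x, 250.0)
        bounds = np.ceil(np.arange(out.size + 1) * 62.5).astype(int)
        expected = [x[a:b].mean() for a, b in zip(bounds[:-1], bounds[1:])]
        assert np.allclose(out, expected)

    def test_rejects_incommensurate_upsampling(self):
        with pytest.raises(ValueError):
            bd.resample_to_4hz(np.arange(10.0), 2.5)


class TestCollapse:
    def test_constant_map(self):
        tf = tfm.TFMap(np.arange(1.0, 41.0), np.arange(5.0),
                       np.ones((40, 5)))
        out = bd.collapse_to_bands(tf, bd.BandScheme.uniform())
        assert np.allclose(out, 1.0)

    def test_matches_row_group_means(self):
        rng = np.random.default_rng(2)
        amp = np.abs(rng.standard_normal((40, 7)))
        tf = tfm.TFMap(np.arange(1.0, 41.0), np.arange(7.0), amp)
        scheme = bd.BandScheme((1.0, 3.0, 10.0, 22.0, 41.0))
        out = bd.collapse_to_bands(tf, scheme)
        for b in range(scheme.n_bands):
            sel = (tf.freqs_hz >= scheme.edges_hz[b]) & \
                  (tf.freqs_hz < scheme.edges_hz[b + 1])
            assert np.allclose(out[b], amp[sel].mean(axis=0))

    def test_equal_width_bands_conserve_mean(self):
        rng = np.random.default_rng(3)
        amp = np.abs(rng.standard_normal((40, 6)))
        tf = tfm.TFMap(np.arange(1.0, 41.0), np.arange(6.0), amp)
        out = bd.collapse_to_bands(tf, bd.BandScheme.uniform())
        assert np.allclose(out.mean(axis=0), amp.mean(axis=0))

    def test_empty_band_rejected(self):
        tf = tfm.TFMap(np.arange(1.0, 41.0), np.arange(3.0),
                       np.ones((40, 3)))
        with pytest.raises(ValueError):
            bd.collapse_to_bands(tf, bd.BandScheme((1.0, 1.2, 1.5, 41.0)))


class TestEqualAreaBands:
    def test_flat_spectrum_uniform_edges(self):
        scheme = bd.equal_area_bands(np.ones(40), np.arange(1.0, 41.0))
        assert np.allclose(np.diff(scheme.edges_hz), 4.0)

    def test_concentrated_mass_pulls_edges_left(self):
        """Nearly all area below 8 Hz packs the edges against the
        strict-monotonicity limit: interior edges occupy consecutive
        integers from 2 Hz."""
        spectrum = np.full(40, 1e-3)
        spectrum[:7] = 10.0  # bins 1..7 Hz
        scheme = bd.equal_area_bands(spectrum, np.arange(1.0, 41.0))
        assert list(scheme.edges_hz[:8]) == [1, 2, 3, 4, 5, 6, 7, 8]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.05, 10.0), min_size=40, max_size=40))
    def test_band_areas_within_one_bin(self, values):
        spectrum = np.asarray(values)
        scheme = bd.equal_area_bands(spectrum, np.arange(1.0, 41.0))
        areas = bd.band_areas(spectrum, scheme, np.arange(1.0, 41.0))
        target = spectrum.sum() / 10
        assert np.max(np.abs(areas - target)) <= spectrum.max() + 1e-9
        # bands partition the range exactly
        assert scheme.edges_hz[0] == 1.0 and scheme.edges_hz[-1] == 41.0

    def test_rejects_nonpositive_spectrum(self):
        with pytest.raises(ValueError):
            bd.equal_area_bands(np.zeros(40), np.arange(1.0, 41.0))

    def test_rejects_too_few_bins(self):
        with pytest.raises(ValueError):
            bd.equal_area_bands(np.ones(5), np.arange(1.0, 6.0))


class TestNormalize:
    def _series(self, values):
        return bd.BandPowerSeries(values, bd.BandScheme.uniform())

    def test_reference_mean_maps_to_zero(self):
        ref = bd.RestReference(np.arange(1.0, 11.0), np.ones(10))
        series = self._series(np.tile(np.arange(1.0, 11.0)[:, None], (1, 8)))
        out = bd.normalize(series, ref)
        assert np.allclose(out.values, 0.0)
        assert out.normalization == bd.Normalization.REFERENCE

    def test_one_sd_above_mean_maps_to_one(self):
        ref = bd.RestReference(np.full(10, 2.0), np.full(10, 0.5))
        series = self._series(np.full((10, 4), 2.5))
        assert np.allclose(bd.normalize(series, ref).values, 1.0)

    def test_roundtrip_is_exact(self, rng):
        ref = bd.RestReference(rng.normal(size=10), np.abs(rng.normal(size=10)) + 0.1)
        series = self._series(rng.normal(size=(10, 20)))
        back = bd.denormalize(bd.normalize(series, ref), ref)
        assert np.allclose(back.values, series.values, atol=1e-12)

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            bd.RestReference(np.zeros(10), np.zeros(10))


def test_pipeline_shift_equivariance():
    """Sliding the analysis window by 1 s shifts the 4 Hz output by 4
    samples in the interior (away from Stockwell edge effects)."""
    from eegfp.simulate import SimSpec, simulate_eeg

    spec = SimSpec(n_sessions=1, n_positive=1, duration_s=81.0, seed=5)
    x = simulate_eeg(spec, 0).channel("Pz")
    fs = 250.0
    n = int(80 * fs)
    shift = int(1.0 * fs)

    def bandpowers(seg):
        tf = tfm.stockwell(seg, fs)
        return bd.resample_to_4hz(
            bd.collapse_to_bands(tf, bd.BandScheme.uniform()), fs)

    a = bandpowers(x[:n])
    b = bandpowers(x[shift : n + shift])
    # columns >= 12 s from either boundary; b is a 4-column shift of a
    inner = slice(48, a.shape[1] - 52)
    assert np.allclose(a[:, 52 : a.shape[1] - 48], b[:, inner], atol=1e-6)
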