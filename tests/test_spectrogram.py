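"""Log-mel front-end: closed forms, the naive-DFT oracle, filterbank
geometry, normalization, and image rendering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import surgisound as ss
from surgisound.preprocessing import WindowedSegment
from surgisound.spectrogram import mel_to_hz


def _segment(samples, sr=44100):
    return WindowedSegment(
        samples=samples, start_ms=0.0, window_ms=len(samples) / sr * 1000, sample_rate=sr
    )


class TestHann:
    @pytest.mark.parametrize("M", [2, 3, 8, 100, 2048])
    def test_endpoints_are_zero(self, M):
        w = ss.hann(M)
        assert w[0] == 0.0 and w[-1] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("M", [3, 9, 101])
    def test_odd_length_midpoint_is_one(self, M):
        assert ss.hann(M)[(M - 1) // 2] == pytest.approx(1.0)

    def test_length_four_closed_form(self):
        assert ss.hann(4) == pytest.approx([0.0, 0.75, 0.75, 0.0])

    def test_rejects_degenerate_length(self):
        with pytest.raises(ValueError):
            ss.hann(1)


def naive_stft(x, n_fft, hop):
    """O(N^2) per-frame DFT oracle, written independently of the package."""
    w = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_fft) / (n_fft - 1)))
    n_frames = (len(x) - n_fft) // hop + 1
    out = np.empty((n_fft // 2 + 1, n_frames), dtype=complex)
    for j in range(n_frames):
        frame = x[j * hop : j * hop + n_fft] * w
        for k in range(n_fft // 2 + 1):
            out[k, j] = np.sum(frame * np.exp(-2j * np.pi * k * np.arange(n_fft) / n_fft))
    return out


class TestStft:
    def test_matches_naive_dft_on_random_signals(self):
        rng = np.random.default_rng(7)
        cfg = ss.SpectrogramConfig(n_fft=256, hop=64)
        for _ in range(5):
            x = rng.uniform(-1, 1, rng.integers(256, 1024))
            fast = ss.stft(_segment(x), cfg)
            slow = naive_stft(x, 256, 64)
            assert np.max(np.abs(fast - slow)) / np.max(np.abs(slow)) < 1e-6

    def test_zero_input_gives_zero_output(self):
        cfg = ss.SpectrogramConfig(n_fft=512, hop=128)
        assert np.all(ss.stft(_segment(np.zeros(2048)), cfg) == 0)

    def test_bin_centered_sine_with_rectangular_window(self):
        # bypass the Hann taper to check the DFT closed form for a sampled sine
        n_fft, k0 = 512, 20
        x = np.sin(2 * np.pi * k0 * np.arange(n_fft) / n_fft)
        X = np.fft.rfft(x)
        mags = np.abs(X)
        assert mags[k0] == pytest.approx(n_fft / 2, rel=1e-9)
        others = np.delete(mags, k0)
        assert np.max(others) < 1e-8 * n_fft

    def test_frame_layout_and_shape(self):
        cfg = ss.SpectrogramConfig(n_fft=256, hop=128)
        X = ss.stft(_segment(np.ones(1000)), cfg)
        assert X.shape == (129, (1000 - 256) // 128 + 1)

    def test_rejects_short_segment(self):
        cfg = ss.SpectrogramConfig(n_fft=2048, hop=512)
        with pytest.raises(ValueError):
            ss.stft(_segment(np.zeros(1000)), cfg)


class TestPowerToDb:
    @pytest.mark.parametrize("x,expected", [(1.0, 0.0), (10.0, 20.0), (0.1, -20.0)])
    def test_closed_forms(self, x, expected):
        assert ss.power_to_db(np.array([x])) == pytest.approx([expected])

    def test_zero_maps_to_floor_exactly(self):
        assert ss.power_to_db(np.array([0.0]), db_floor=-80.0)[0] == -80.0

    def test_floor_bounds_everything(self):
        rng = np.random.default_rng(0)
        out = ss.power_to_db(rng.uniform(0, 2, 100), db_floor=-60.0)
        assert np.all(out >= -60.0) and np.all(np.isfinite(out))


class TestMelScale:
    def test_zero_maps_to_zero(self):
        assert float(ss.hz_to_mel(0.0)) == 0.0

    def test_700_hz_closed_form(self):
        assert float(ss.hz_to_mel(700.0)) == pytest.approx(2595 * np.log10(2))

    def test_1000_hz_calibration(self):
        assert float(ss.hz_to_mel(1000.0)) == pytest.approx(1000.0, abs=0.1)

    def test_strictly_monotone(self):
        f = np.linspace(0, 22050, 2000)
        assert np.all(np.diff(ss.hz_to_mel(f)) > 0)

    def test_inverse_round_trip(self):
        f = np.linspace(0, 20000, 50)
        assert mel_to_hz(ss.hz_to_mel(f)) == pytest.approx(f, abs=1e-6)

    def test_rejects_negative_frequency(self):
        with pytest.raises(ValueError):
            ss.hz_to_mel(-1.0)


class TestMelFilterbank:
    CFG = ss.SpectrogramConfig(n_mels=64)

    def test_single_contiguous_support_per_filter(self):
        fb = ss.mel_filterbank(self.CFG)
        for row in fb:
            support = np.flatnonzero(row > 0)
            assert len(support) > 0
            assert np.all(np.diff(support) == 1)

    def test_centers_evenly_spaced_on_mel_scale(self):
        fb = ss.mel_filterbank(self.CFG)
        freqs = np.arange(self.CFG.n_fft // 2 + 1) * self.CFG.sample_rate / self.CFG.n_fft
        centers = freqs[fb.argmax(axis=1)]
        mel_centers = ss.hz_to_mel(centers)
        gaps = np.diff(mel_centers)
        assert np.all(np.diff(centers) > 0)
        # centers snap to the FFT grid; gaps are equal within one bin's mel width
        bin_mel = np.max(np.diff(ss.hz_to_mel(freqs[:2] + centers[0])))
        assert np.max(np.abs(gaps - gaps.mean())) <= 2 * bin_mel

    def test_exact_center_spacing_from_construction(self):
        # corner points (not grid-snapped argmaxes) are exactly even in mel
        lo, hi = ss.hz_to_mel(self.CFG.f_min), ss.hz_to_mel(self.CFG.f_max)
        pts = np.linspace(float(lo), float(hi), self.CFG.n_mels + 2)
        assert np.max(np.abs(np.diff(pts) - np.diff(pts)[0])) < 1e-9

    def test_low_cut_silences_sub_fmin_content(self):
        cfg = ss.SpectrogramConfig(n_mels=64, f_min=2000.0)
        fb = ss.mel_filterbank(cfg)
        freqs = np.arange(cfg.n_fft // 2 + 1) * cfg.sample_rate / cfg.n_fft
        spec_1k = np.exp(-0.5 * ((freqs - 1000) / 50) ** 2)
        spec_5k = np.exp(-0.5 * ((freqs - 5000) / 50) ** 2)
        assert (fb @ spec_1k).sum() <= 1e-12 * (fb @ spec_5k).sum()

    def test_rows_all_have_positive_sum(self):
        fb = ss.mel_filterbank(ss.SpectrogramConfig())
        assert np.all(fb.sum(axis=1) > 0)

    def test_bins_above_fmax_get_zero_weight(self):
        fb = ss.mel_filterbank(self.CFG)
        freqs = np.arange(self.CFG.n_fft // 2 + 1) * self.CFG.sample_rate / self.CFG.n_fft
        assert np.all(fb[:, freqs > self.CFG.f_max] == 0)

    def test_rejects_unresolvable_band_count(self):
        with pytest.raises(ValueError):
            ss.mel_filterbank(ss.SpectrogramConfig(n_fft=256, hop=64, n_mels=256))


class TestLogMel:
    def test_frame_count_for_500ms_window(self):
        cfg = ss.SpectrogramConfig()
        seg = _segment(np.random.default_rng(0).uniform(-0.5, 0.5, 22050))
        lm = ss.log_mel(seg, cfg)
        assert lm.values.shape == (256, (22050 - 2048) // 512 + 1)
        assert lm.values.shape[1] == 40

    def test_silence_sits_at_the_floor(self):
        cfg = ss.SpectrogramConfig()
        lm = ss.log_mel(_segment(np.zeros(22050)), cfg)
        assert np.all(lm.values == cfg.db_floor)

    def test_doubling_amplitude_adds_six_db(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 0.1, 22050)
        cfg = ss.SpectrogramConfig()
        a = ss.log_mel(_segment(x), cfg).values
        b = ss.log_mel(_segment(2 * x), cfg).values
        mask = a > cfg.db_floor + 6.5  # stay clear of the floor
        assert np.allclose((b - a)[mask], 20 * np.log10(2), atol=1e-6)

    def test_deterministic_for_identical_input(self):
        x = np.random.default_rng(1).uniform(-0.5, 0.5, 22050)
        cfg = ss.SpectrogramConfig()
        assert np.array_equal(ss.log_mel(_segment(x), cfg).values,
                              ss.log_mel(_segment(x.copy()), cfg).values)

    @settings(deadline=None, max_examples=20)
    @given(scale=st.floats(1.1, 8.0), seed=st.integers(0, 100))
    def test_energy_monotone_in_amplitude(self, scale, seed):
        x = np.random.default_rng(seed).normal(0, 0.05, 4096)
        cfg = ss.SpectrogramConfig(n_fft=1024, hop=512, n_mels=40)
        a = ss.log_mel(_segment(x), cfg).values
        b = ss.log_mel(_segment(scale * x), cfg).values
        above = a > cfg.db_floor
        assert np.all(b[above] >= a[above] - 1e-9)


class TestNormalization:
    def test_two_point_population_stats(self):
        cfg = ss.SpectrogramConfig()
        mk = lambda v: ss.LogMelSpectrogram(values=np.array([[v]]), config=cfg)
        stats = ss.fit_normalization([mk(0.0), mk(-80.0)])
        assert stats.mean == pytest.approx(-40.0)
        assert stats.std == pytest.approx(40.0)

    def test_standardization_identity(self):
        rng = np.random.default_rng(2)
        cfg = ss.SpectrogramConfig()
        specs = [
            ss.LogMelSpectrogram(values=rng.normal(-30, 12, (64, 40)), config=cfg)
            for _ in range(5)
        ]
        stats = ss.fit_normalization(specs)
        pooled = np.concatenate([(s.values - stats.mean) / stats.std for s in specs], axis=None)
        assert pooled.mean() == pytest.approx(0.0, abs=1e-9)
        assert pooled.std() == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_collections_rejected(self):
        cfg = ss.SpectrogramConfig()
        with pytest.raises(ValueError):
            ss.fit_normalization([])
        const = ss.LogMelSpectrogram(values=np.full((4, 4), -10.0), config=cfg)
        with pytest.raises(ValueError):
            ss.fit_normalization([const, const])


class TestRenderImage:
    STATS = ss.NormalizationStats(mean=-30.0, std=10.0)

    def test_constant_field_renders_constant(self):
        cfg = ss.SpectrogramConfig(n_mels=64)
        spec = ss.LogMelSpectrogram(values=np.full((64, 40), -20.0), config=cfg)
        img = ss.render_image(spec, self.STATS)
        assert img.pixels.shape == (299, 299, 3)
        assert np.allclose(img.pixels, (-20.0 + 30.0) / 10.0)

    @pytest.mark.parametrize("n_frames", [10, 40, 173])
    def test_output_shape_is_fixed_regardless_of_frames(self, n_frames):
        cfg = ss.SpectrogramConfig(n_mels=64, image_size=128)
        spec = ss.LogMelSpectrogram(values=np.zeros((64, n_frames)) - 30, config=cfg)
        img = ss.render_image(spec, self.STATS, image_size=128)
        assert img.pixels.shape == (128, 128, 3)

    def test_channels_identical(self):
        cfg = ss.SpectrogramConfig(n_mels=32)
        rng = np.random.default_rng(4)
        spec = ss.LogMelSpectrogram(values=rng.normal(-30, 5, (32, 20)), config=cfg)
        img = ss.render_image(spec, self.STATS)
        assert np.array_equal(img.pixels[:, :, 0], img.pixels[:, :, 1])
        assert np.array_equal(img.pixels[:, :, 0], img.pixels[:, :, 2])

    def test_bright_band_stays_contiguous_and_flips_to_bottom(self):
        cfg = ss.SpectrogramConfig(n_mels=64)
        values = np.full((64, 40), -60.0)
        values[5, :] = 0.0  # low mel band -> should end up near the image bottom
        spec = ss.LogMelSpectrogram(values=values, config=cfg)
        img = ss.render_image(spec, self.STATS)
        gray = img.pixels[:, :, 0]
        col = gray[:, 150]
        bright = np.flatnonzero(col > col.min() + 0.5 * (col.max() - col.min()))
        assert np.all(np.diff(bright) == 1)  # contiguous band, no wraparound
        assert bright.mean() > 299 * 0.8  # near the bottom of the image
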