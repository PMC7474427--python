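"""Filtering, epoching, STFT and image-construction contracts."""

import numpy as np
import pytest
from matplotlib import colormaps

from miaug.preprocess import (
    ContinuousRecording,
    ImageSet,
    SpectrogramImage,
    bandpass_filter,
    build_image,
    epoch_trials,
    stft_spectrogram,
    trials_to_images,
)
from miaug.simulate import SimConfig, simulate_trials


def _recording(fs=250.0, seconds=60.0, events=None, signal=None):
    n = int(fs * seconds)
    if signal is None:
        signal = np.zeros((3, n))
    return ContinuousRecording(signal, fs, events or [], ("C3", "Cz", "C4"))


class TestBandpass:
    def test_zero_in_zero_out(self):
        out = bandpass_filter(_recording())
        assert np.allclose(out.signal, 0.0)

    @pytest.mark.parametrize("freq,bound,kind", [(20.0, 0.9, "pass"),
                                                 (2.0, 0.1, "stop")])
    def test_passband_and_stopband_gain(self, freq, bound, kind):
        fs, n = 250.0, 25000
        t = np.arange(n) / fs
        sig = np.tile(np.sin(2 * np.pi * freq * t), (3, 1))
        out = bandpass_filter(_recording(fs, n / fs, signal=sig), 8.0, 30.0)
        mid = out.signal[0, n // 4 : 3 * n // 4]  # skip filter edges
        amplitude = np.abs(mid).max()
        if kind == "pass":
            assert amplitude >= bound
        else:
            assert amplitude <= bound

    def test_high_edge_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_recording(fs=50.0), 8.0, 30.0)

    def test_event_latencies_preserved(self):
        rec = _recording(events=[(100, "left"), (5000, "right")])
        out = bandpass_filter(rec)
        assert out.events == rec.events


class TestEpoching:
    @pytest.mark.parametrize("fs,expected", [(100.0, 400), (250.0, 1000)])
    def test_sample_counts_per_rate(self, fs, expected):
        rec = _recording(fs=fs, seconds=30.0,
                         events=[(0, "left"), (int(5 * fs), "right")])
        trials = epoch_trials(rec, duration=4.0)
        assert trials.data.shape == (2, 3, expected)
        assert trials.labels.tolist() == ["left", "right"]

    def test_marker_at_final_sample_raises_with_context(self):
        rec = _recording(fs=100.0, seconds=10.0, events=[(999, "left")])
        with pytest.raises(ValueError, match="999"):
            epoch_trials(rec, duration=4.0)

    def test_epochs_copy_signal_content(self):
        fs, n = 100.0, 3000
        sig = np.arange(3 * n, dtype=float).reshape(3, n)
        rec = _recording(fs, n / fs, events=[(100, "left")], signal=sig)
        trials = epoch_trials(rec, duration=4.0)
        np.testing.assert_array_equal(trials.data[0], sig[:, 100:500])


class TestSTFT:
    def test_zero_input_zero_magnitude(self):
        mag, _ = stft_spectrogram(np.zeros(400), 100.0, 128)
        assert mag.shape[0] > 0 and np.all(mag == 0)

    def test_band_restriction_bin_count(self):
        """fs=100, window 128: retained bins are k=11..38, i.e. 28 bins."""
        mag, freqs = stft_spectrogram(np.zeros(400), 100.0, 128, band=(8.0, 30.0))
        assert mag.shape[0] == 28
        assert freqs[0] == pytest.approx(11 * 100 / 128)
        assert freqs[-1] == pytest.approx(38 * 100 / 128)
        spacing = np.diff(freqs)
        np.testing.assert_allclose(spacing, 100.0 / 128)

    def test_sinusoid_peak_at_nearest_bin(self):
        t = np.arange(400) / 100.0
        x = np.sin(2 * np.pi * 10.0 * t)
        mag, freqs = stft_spectrogram(x, 100.0, 128)
        peak_bins = mag.argmax(axis=0)
        nearest = np.abs(freqs - 10.0).argmin()
        assert np.all(peak_bins == nearest)

    def test_window_longer_than_trial_rejected(self):
        with pytest.raises(ValueError):
            stft_spectrogram(np.zeros(100), 100.0, 128)

    def test_energy_monotonicity_under_amplitude_scaling(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(400)
        mag1, _ = stft_spectrogram(x, 100.0, 128)
        mag2, _ = stft_spectrogram(3.0 * x, 100.0, 128)
        assert np.all(mag2 >= mag1 - 1e-12)


class TestBuildImage:
    def test_output_shape_and_range(self):
        rng = np.random.default_rng(0)
        img = build_image(rng.standard_normal((3, 400)), 100.0, 128,
                          label="left")
        assert img.pixels.shape == (64, 64, 3)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        assert img.provenance == "real"

    def test_identical_channels_give_vertically_periodic_image(self):
        rng = np.random.default_rng(1)
        ch = rng.standard_normal(400)
        img = build_image(np.tile(ch, (3, 1)), 100.0, 128)
        third = 64 // 3
        top = img.pixels[:third]
        middle = img.pixels[third : 2 * third]
        # identical stacked blocks, so bands repeat within resize tolerance
        assert np.abs(top - middle).mean() < 0.1

    def test_all_zero_trial_gives_colormap_at_zero(self):
        img = build_image(np.zeros((3, 400)), 100.0, 128)
        expected = colormaps["viridis"](0.0)[:3]
        assert np.allclose(img.pixels, expected, atol=1e-6)

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError):
            build_image(np.zeros((2, 400)), 100.0, 128)

    def test_pipeline_determinism(self):
        trials = simulate_trials(SimConfig(n_trials_per_class=3, seed=9))
        a = trials_to_images(trials)
        b = trials_to_images(trials)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.labels.tolist() == trials.labels.tolist()


class TestImageSet:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            SpectrogramImage(np.zeros((32, 32, 3)), "left")
        with pytest.raises(ValueError):
            SpectrogramImage(np.full((64, 64, 3), 1.5), "left")
        with pytest.raises(ValueError):
            SpectrogramImage(np.zeros((64, 64, 3)), "left", provenance="bogus")

    def test_subset_and_concat_roundtrip(self):
        trials = simulate_trials(SimConfig(n_trials_per_class=4, seed=2))
        images = trials_to_images(trials)
        sub = images.subset([0, 2])
        assert len(sub) == 2
        merged = ImageSet.concat([sub, images.subset([1])])
        assert len(merged) == 3
        assert merged[0].label == str(images.labels[0])
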