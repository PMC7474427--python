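"""From continuous EEG to 64x64 stacked-spectrogram images.

The pipeline mirrors the standard motor-imagery preprocessing chain: a
zero-phase 8-30 Hz Butterworth band-pass, 4 s epochs cut at each imagery cue,
a Hann-window STFT per channel restricted to the motion-related 8-30 Hz band,
vertical stacking of the C3/Cz/C4 magnitude matrices (C3 on top, so channel
neighbourhood is preserved), a colormap applied to min-max-scaled
log-magnitudes, and a bilinear resize to 64x64 RGB.

Window sizes of 128 (100 Hz recordings) and 256 (250 Hz recordings) keep the
frequency resolution comparable across sampling rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann
from skimage.transform import resize

from .simulate import TrialSet

__all__ = [
    "ContinuousRecording",
    "SpectrogramImage",
    "ImageSet",
    "bandpass_filter",
    "epoch_trials",
    "stft_spectrogram",
    "build_image",
    "trials_to_images",
]

IMAGE_SIZE = 64
PROVENANCES = ("real", "generated", "gt", "na", "ae", "vae", "dcgan")


@dataclass
class ContinuousRecording:
    """A continuous multichannel recording with event markers.

    events : list of ``(sample_index, label)`` imagery-cue markers.
    """

    signal: np.ndarray
    fs: float
    events: list[tuple[int, str]]
    channel_names: tuple[str, ...] = ("C3", "Cz", "C4")

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be (channels, samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.signal.shape[1]
        for sample, _ in self.events:
            if not 0 <= sample < n:
                raise ValueError(f"event at sample {sample} outside recording")


@dataclass
class SpectrogramImage:
    """A 64x64x3 image in [0,1] encoding one trial, with label and provenance."""

    pixels: np.ndarray
    label: str
    provenance: str = "real"
    subject_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError(f"pixels must be {IMAGE_SIZE}x{IMAGE_SIZE}x3")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")
        if self.provenance not in PROVENANCES:
            raise ValueError(f"provenance must be one of {PROVENANCES}")


@dataclass
class ImageSet:
    """A batch of spectrogram images stored as one array.

    pixels : (n, 64, 64, 3) values in [0,1];
    labels : per-image class names;
    provenance : per-image origin tag (real/gt/na/ae/vae/dcgan).
    """

    pixels: np.ndarray
    labels: np.ndarray
    provenance: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.labels = np.asarray(self.labels)
        self.provenance = np.asarray(self.provenance)
        if self.pixels.ndim != 4 or self.pixels.shape[1:] != (IMAGE_SIZE, IMAGE_SIZE, 3):
            raise ValueError("pixels must be (n, 64, 64, 3)")
        if len(self.labels) != len(self.pixels) or len(self.provenance) != len(self.pixels):
            raise ValueError("labels/provenance length mismatch")

    def __len__(self):
        return len(self.pixels)

    def __getitem__(self, i) -> SpectrogramImage:
        return SpectrogramImage(self.pixels[i], str(self.labels[i]),
                                str(self.provenance[i]), self.subject_id)

    def subset(self, idx) -> "ImageSet":
        idx = np.asarray(idx)
        return ImageSet(self.pixels[idx], self.labels[idx], self.provenance[idx],
                        self.subject_id)

    @staticmethod
    def concat(sets: list["ImageSet"]) -> "ImageSet":
        if not sets:
            raise ValueError("cannot concatenate an empty list of image sets")
        return ImageSet(
            np.concatenate([s.pixels for s in sets]),
            np.concatenate([s.labels for s in sets]),
            np.concatenate([s.provenance for s in sets]),
            sets[0].subject_id,
        )

    @staticmethod
    def from_images(images: list[SpectrogramImage]) -> "ImageSet":
        return ImageSet(
            np.stack([im.pixels for im in images]),
            np.array([im.label for im in images]),
            np.array([im.provenance for im in images]),
            images[0].subject_id if images else "",
        )


def bandpass_filter(recording: ContinuousRecording, low: float = 8.0,
                    high: float = 30.0, order: int = 4) -> ContinuousRecording:
    """Zero-phase Butterworth band-pass; event latencies are preserved.

    The filter is applied forward and backward (``sosfiltfilt``) so the
    passband gain is ~1 and there is no phase shift.
    """
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= recording.fs / 2:
        raise ValueError(f"high edge {high} Hz must be below Nyquist "
                         f"({recording.fs / 2} Hz)")
    sos = butter(order, [low, high], btype="bandpass", fs=recording.fs, output="sos")
    filtered = sosfiltfilt(sos, recording.signal, axis=-1)
    return ContinuousRecording(filtered, recording.fs, list(recording.events),
                               recording.channel_names)


def epoch_trials(recording: ContinuousRecording, duration: float = 4.0,
                 offset: float = 0.0) -> TrialSet:
    """Cut one epoch per event marker, starting ``offset`` s after the cue."""
    n_samp = int(round(recording.fs * duration))
    start_off = int(round(recording.fs * offset))
    total = recording.signal.shape[1]
    trials, labels = [], []
    for sample, label in recording.events:
        lo = sample + start_off
        hi = lo + n_samp
        if lo < 0 or hi > total:
            raise ValueError(
                f"epoch for marker at sample {sample} (label {label!r}) spans "
                f"[{lo}, {hi}) outside the recording of {total} samples"
            )
        trials.append(recording.signal[:, lo:hi])
        labels.append(label)
    if not trials:
        raise ValueError("recording has no event markers")
    return TrialSet(np.stack(trials), np.array(labels), recording.fs,
                    tuple(recording.channel_names))


def stft_spectrogram(x: np.ndarray, fs: float, window_size: int,
                     overlap: int | None = None,
                     band: tuple[float, float] = (8.0, 30.0)):
    """Hann-window STFT magnitude of one channel, restricted to ``band``.

    The trial is zero-padded at the end so an integer number of hops covers
    every sample. Returns ``(magnitude, freqs)`` where magnitude is
    (n_bins, n_frames) and ``freqs`` are the retained bin frequencies
    (spacing ``fs / window_size``).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("x must be a single-channel 1-D array")
    n = x.size
    if window_size > n:
        raise ValueError(f"window_size {window_size} exceeds trial length {n}")
    if overlap is None:
        overlap = window_size // 2
    if not 0 <= overlap < window_size:
        raise ValueError("overlap must satisfy 0 <= overlap < window_size")
    hop = window_size - overlap
    n_frames = 1 + int(np.ceil((n - window_size) / hop))
    padded = np.zeros((n_frames - 1) * hop + window_size)
    padded[:n] = x
    frames = np.lib.stride_tricks.sliding_window_view(padded, window_size)[::hop]
    win = hann(window_size, sym=False)
    spec = np.abs(np.fft.rfft(frames * win, axis=-1))
    freqs = np.fft.rfftfreq(window_size, d=1.0 / fs)
    low, high = band
    mask = (freqs >= low) & (freqs <= high)
    return spec[:, mask].T, freqs[mask]


def _colormap_rgb(values: np.ndarray, colormap: str) -> np.ndarray:
    cmap = colormaps[colormap]
    return cmap(values)[..., :3]


def build_image(trial: np.ndarray, fs: float, window_size: int,
                overlap: int | None = None, band: tuple[float, float] = (8.0, 30.0),
                colormap: str = "viridis", log_scale: bool = True,
                label: str = "", subject_id: str = "") -> SpectrogramImage:
    """Stack per-channel spectrograms vertically and render a 64x64 RGB image.

    ``trial`` is (3, n_samples) ordered C3, Cz, C4; C3 ends up at the top of
    the image. Magnitudes are (optionally log-) scaled, min-max normalized per
    image, mapped through the colormap, and bilinearly resized to 64x64.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2 or trial.shape[0] != 3:
        raise ValueError("trial must be (3, n_samples) ordered C3, Cz, C4")
    mags = [stft_spectrogram(ch, fs, window_size, overlap, band)[0] for ch in trial]
    stacked = np.vstack(mags)
    if log_scale:
        stacked = np.log1p(stacked)
    lo, hi = stacked.min(), stacked.max()
    norm = (stacked - lo) / (hi - lo) if hi > lo else np.zeros_like(stacked)
    rgb = _colormap_rgb(norm, colormap)
    small = resize(rgb, (IMAGE_SIZE, IMAGE_SIZE), order=1, mode="edge",
                   anti_aliasing=False)
    return SpectrogramImage(np.clip(small, 0.0, 1.0), label=label,
                            provenance="real", subject_id=subject_id)


def default_window_size(fs: float) -> int:
    """128 samples for ~100 Hz recordings, 256 for ~250 Hz."""
    return 128 if fs <= 128 else 256


def trials_to_images(trials: TrialSet, window_size: int | None = None,
                     overlap: int | None = None,
                     band: tuple[float, float] = (8.0, 30.0),
                     colormap: str = "viridis", log_scale: bool = True,
                     subject_id: str = "") -> ImageSet:
    """Convert every trial of a TrialSet into a spectrogram image."""
    if window_size is None:
        window_size = default_window_size(trials.fs)
    images = [
        build_image(trials.data[i], trials.fs, window_size, overlap, band,
                    colormap, log_scale, label=str(trials.labels[i]),
                    subject_id=subject_id)
        for i in range(trials.n_trials)
    ]
    out = ImageSet.from_images(images)
    out.subject_id = subject_id
    return out
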