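"""Synthetic two-class motor-imagery EEG with ERD/ERS band-power structure.

Imagining a hand movement desynchronizes the mu (8–12 Hz) and beta (18–26 Hz)
rhythms over the contralateral motor cortex (ERD: amplitude drops) and can
enhance them ipsilaterally (ERS). The simulator reproduces exactly that
laterality on the standard C3/Cz/C4 montage: right-hand imagery attenuates the
oscillations at C3 (left motor cortex) by ``1 - erd_depth`` and scales C4 by
``1 + ers_gain``; left-hand imagery mirrors the two. Cz is never modulated.
Oscillations ride on 1/f-shaped background noise, and phases are drawn
uniformly per trial because motor imagery is an induced (non-phase-locked)
phenomenon.

The modulation is constant over the whole epoch — no ERD time course — which
is all the downstream spectrogram/classification pipeline needs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import periodogram

__all__ = ["SimConfig", "TrialSet", "simulate_trials", "bandpower", "LEFT", "RIGHT"]

LEFT = "left"
RIGHT = "right"

_DEFAULT_CHANNELS = ("C3", "Cz", "C4")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-class ERD/ERS simulation.

    Attributes
    ----------
    n_trials_per_class : trials per class (the output holds twice this many).
    fs : sampling rate in Hz (the benchmark datasets use 100 or 250).
    duration : epoch length in seconds; ``fs * duration`` must be integral.
    erd_depth : fractional mu/beta amplitude reduction at the contralateral
        electrode, in [0, 1].
    ers_gain : fractional amplitude increase at the ipsilateral electrode.
    noise_level : amplitude of the 1/f background noise (0 disables it).
    mu_amp, beta_amp : oscillation amplitudes before lateral modulation.
    """

    n_trials_per_class: int = 100
    fs: float = 100.0
    duration: float = 4.0
    channels: tuple[str, ...] = _DEFAULT_CHANNELS
    erd_depth: float = 0.5
    ers_gain: float = 0.0
    noise_level: float = 1.0
    mu_band: tuple[float, float] = (8.0, 12.0)
    beta_band: tuple[float, float] = (18.0, 26.0)
    mu_amp: float = 1.0
    beta_amp: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.ers_gain < 0:
            raise ValueError("ers_gain must be >= 0")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"fs*duration = {n} is not an integer sample count"
            )
        if len(self.channels) != 3:
            raise ValueError("exactly three channels (C3, Cz, C4) are supported")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass
class TrialSet:
    """Epoched multichannel trials with class labels.

    data : (n_trials, n_channels, n_samples) array.
    labels : per-trial class name, ``"left"`` or ``"right"``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = _DEFAULT_CHANNELS

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel dimension does not match channel_names")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def channel_index(self, name: str) -> int:
        try:
            return list(self.channel_names).index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}; have {self.channel_names}")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance 1/f-shaped noise via spectral shaping of white noise."""
    n_freq = n // 2 + 1
    spectrum = rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq)
    f = np.fft.rfftfreq(n)
    scale = np.zeros(n_freq)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    spectrum *= scale
    x = np.fft.irfft(spectrum, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _lateral_factors(label: str, erd_depth: float, ers_gain: float) -> np.ndarray:
    """Amplitude factors for (C3, Cz, C4); right imagery attenuates C3."""
    contra, ipsi = 1.0 - erd_depth, 1.0 + ers_gain
    if label == RIGHT:
        return np.array([contra, 1.0, ipsi])
    return np.array([ipsi, 1.0, contra])


def simulate_trials(config: SimConfig) -> TrialSet:
    """Generate a balanced, seed-deterministic two-class TrialSet.

    Per trial, each channel is the sum of a mu and a beta oscillation (random
    frequency within band, random phase per channel) scaled by the lateral
    ERD/ERS factors for the trial's class, plus 1/f background noise.
    """
    rng = np.random.default_rng(config.seed)
    n_s = config.n_samples
    t = np.arange(n_s) / config.fs
    n_per = config.n_trials_per_class

    labels = np.array([LEFT] * n_per + [RIGHT] * n_per)
    data = np.empty((2 * n_per, 3, n_s))
    for i, label in enumerate(labels):
        factors = _lateral_factors(label, config.erd_depth, config.ers_gain)
        f_mu = rng.uniform(*config.mu_band)
        f_beta = rng.uniform(*config.beta_band)
        for ch in range(3):
            phase_mu, phase_beta = rng.uniform(0.0, 2 * np.pi, size=2)
            sig = factors[ch] * (
                config.mu_amp * np.cos(2 * np.pi * f_mu * t + phase_mu)
                + config.beta_amp * np.cos(2 * np.pi * f_beta * t + phase_beta)
            )
            if config.noise_level > 0:
                sig = sig + config.noise_level * _pink_noise(rng, n_s)
            data[i, ch] = sig
    return TrialSet(data=data, labels=labels, fs=config.fs,
                    channel_names=tuple(config.channels))


def bandpower(trials: TrialSet, band: tuple[float, float], channel: str) -> np.ndarray:
    """Per-trial power in ``band`` (Hz) at one channel, via the periodogram.

    Returns the integral of the power spectral density over the band, one
    non-negative value per trial; quadratic in signal amplitude.
    """
    low, high = band
    if not 0 < low < high < trials.fs / 2:
        raise ValueError(f"band {band} must lie within (0, fs/2)")
    ci = trials.channel_index(channel)
    freqs, psd = periodogram(trials.data[:, ci, :], fs=trials.fs, axis=-1)
    mask = (freqs >= low) & (freqs <= high)
    df = freqs[1] - freqs[0]
    return psd[:, mask].sum(axis=-1) * df
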