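"""Turn trials into the stacked 64x64 spectrogram images the networks consume.

Each image vertically stacks the band-limited (8-30 Hz) STFT magnitudes of
C3, Cz and C4 (C3 on top), colormapped and resized to 64x64x3.
"""

import numpy as np

from miaug import SimConfig, simulate_trials, stft_spectrogram, trials_to_images

trials = simulate_trials(SimConfig(n_trials_per_class=10, fs=100.0, seed=1))

# one channel's raw time-frequency matrix first
mag, freqs = stft_spectrogram(trials.data[0, 0], fs=100.0, window_size=128,
                              band=(8.0, 30.0))
print(f"single-channel STFT: {mag.shape[0]} frequency bins x "
      f"{mag.shape[1]} frames, bins {freqs[0]:.2f}-{freqs[-1]:.2f} Hz "
      f"(spacing {freqs[1]-freqs[0]:.3f} Hz)")

images = trials_to_images(trials, subject_id="sim01")
print(f"image set: {len(images)} images of shape {images.pixels.shape[1:]}, "
      f"values in [{images.pixels.min():.2f}, {images.pixels.max():.2f}]")

# class-mean contrast: the mu-band rows of the C3 block (top third) are
# dimmer for right-hand imagery than for left-hand imagery
top_third = images.pixels[:, :21, :, :].mean(axis=(1, 2, 3))
for label in ("left", "right"):
    mean_top = top_third[images.labels == label].mean()
    print(f"mean intensity of the C3 block, {label:>5} imagery: {mean_top:.3f}")
print("the contralateral (C3) block is dimmer under right-hand imagery — "
      "that intensity gap is what the classifier learns")
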