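"""Train a width-scaled DCGAN on one class of spectrograms and score it.

The Fréchet distance between Gaussian fits to feature embeddings of real and
generated images quantifies sample quality (lower = closer to real). A
converging generator moves the distance below its value after one epoch.
"""

import numpy as np

from miaug import SimConfig, compute_fid, simulate_trials, trials_to_images
from miaug.generative import GANTrainConfig, sample_generated, train_dcgan

images = trials_to_images(simulate_trials(
    SimConfig(n_trials_per_class=50, noise_level=2.0, seed=4)))
left = images.subset(np.flatnonzero(images.labels == "left"))
train, held = left.subset(range(32)), left.subset(range(32, 50))

config = GANTrainConfig(base_width=64, batch_size=12, epochs=20, seed=0)
history = {}


def track(epoch, state):
    if epoch in (1, config.epochs):
        samples = sample_generated(state, len(held), "left", seed=9)
        history[epoch] = compute_fid(held, samples, dim=16).value


state = train_dcgan(train, config, callback=track)
print(f"trained {config.epochs} epochs; final discriminator loss "
      f"{state.d_losses[-1]:.3f}, generator loss {state.g_losses[-1]:.3f}")
print(f"FID vs held-out real images: epoch 1 = {history[1]:.1f}, "
      f"epoch {config.epochs} = {history[config.epochs]:.1f}")
real_ref = compute_fid(held, train, dim=16).value
print(f"reference real-vs-real FID = {real_ref:.1f} (the floor the generator "
      f"is converging toward)")

samples = sample_generated(state, 4, "left", seed=10)
print(f"sampled {len(samples)} images, shape {samples.pixels.shape[1:]}, "
      f"provenance {set(samples.provenance.tolist())}")
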