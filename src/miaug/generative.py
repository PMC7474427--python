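"""Generative augmenters: autoencoder, variational autoencoder, and DCGAN.

The DCGAN pair is all-convolutional with batch normalization and no fully
connected layers apart from the discriminator's final score:

* generator: 100-dim latent (shaped 100x1x1) -> projection to (1024,4,4), then
  four fractional-stride 3x3 deconvolutions halving the channel count and
  doubling the spatial size each step — (512,8,8), (256,16,16), (128,32,32) —
  to a (3,64,64) tanh output. Hidden activations are ReLU.
* discriminator: four stride-2 3x3 convolutions (128,32,32) -> (256,16,16) ->
  (512,8,8) -> (1024,4,4) with leaky-ReLU and dropout 0.25, flattened to
  16384 and squashed to a sigmoid real/fake score.

The first generator layer cannot be a 3x3 stride-2 deconvolution (no such
layer maps 1x1 to 4x4); it is realised as a 4x4 stride-1 projection, the
standard DCGAN idiom for that step. ``base_width`` scales all channel counts
together (1024 reproduces the reference architecture; smaller widths keep the
halving/doubling pattern for cheap experiments).

Training minimises the usual minimax objective; the discriminator loss is the
binary cross-entropy with real labels 1 and fake labels 0, and the generator
uses the non-saturating −log D(G(z)) form to avoid early vanishing gradients.
Optimizer: Adam, learning rate 2e-4, betas (0.5, 0.999), batch 128 (clamped to
the dataset size), 20 epochs. Batch-norm momentum is 0.8.

The AE compresses images through a convolutional encoder to a deterministic
100-dim bottleneck and decodes with the generator architecture; sampling
perturbs encoded latents with spherical noise (a plain AE has no prior). The
VAE adds a mean/log-variance head and a KL term to a standard normal prior,
and samples latents from that prior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Adam,
    BatchNorm,
    Conv2d,
    ConvTranspose2d,
    Dense,
    Dropout,
    Flatten,
    LeakyReLU,
    MaxPool2d,
    Network,
    ReLU,
    Sigmoid,
    Tanh,
)
from .nn.losses import binary_cross_entropy
from .preprocess import ImageSet

__all__ = [
    "GANTrainConfig",
    "GANState",
    "LATENT_DIM",
    "build_generator",
    "build_discriminator",
    "gan_losses",
    "train_dcgan",
    "sample_generated",
    "build_autoencoder",
    "build_vae",
    "train_autoencoder",
    "sample_autoencoder",
]

LATENT_DIM = 100
_BN_MOMENTUM = 0.8
_EPS = 1e-12


@dataclass(frozen=True)
class GANTrainConfig:
    """Adam-based adversarial training configuration."""

    learning_rate: float = 2e-4
    batch_size: int = 128
    epochs: int = 20
    beta1: float = 0.5
    beta2: float = 0.999
    base_width: int = 1024
    dropout: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.epochs <= 0:
            raise ValueError("learning rate, batch size and epochs must be positive")


@dataclass
class GANState:
    """Trained generator/discriminator plus per-epoch loss history."""

    generator: Network
    discriminator: Network
    d_losses: list[float] = field(default_factory=list)
    g_losses: list[float] = field(default_factory=list)
    epoch: int = 0
    config: GANTrainConfig = field(default_factory=GANTrainConfig)


def _check_channels(channels):
    channels = tuple(int(c) for c in channels)
    if len(channels) != 4:
        raise ValueError("expected 4 deconvolution/convolution widths")
    for a, b in zip(channels, channels[1:]):
        if a != 2 * b and b != 2 * a:
            raise ValueError(
                f"channel widths {channels} break the halving/doubling pattern"
            )
    return channels


def generator_channels(base_width: int = 1024) -> tuple[int, ...]:
    """Deconvolution widths (halving): e.g. (1024, 512, 256, 128)."""
    if base_width < 8 or base_width % 8:
        raise ValueError("base_width must be a positive multiple of 8")
    return (base_width, base_width // 2, base_width // 4, base_width // 8)


def build_generator(base_width: int = 1024, latent_dim: int = LATENT_DIM,
                    channels: tuple[int, ...] | None = None,
                    seed: int = 0) -> Network:
    """Latent (N,100,1,1) -> image (N,3,64,64) in [-1,1].

    ``channels`` overrides the per-layer widths but must keep the halving
    pattern; spatial sizes double at every deconvolution.
    """
    ch = _check_channels(channels if channels is not None
                         else generator_channels(base_width))
    if any(a != 2 * b for a, b in zip(ch, ch[1:])):
        raise ValueError(f"generator widths {ch} must halve layer by layer")
    rng = np.random.default_rng(seed)
    layers = [
        BatchNorm(latent_dim, momentum=_BN_MOMENTUM),
        # 1x1 -> 4x4 projection (a 3x3 stride-2 deconvolution cannot do this step)
        ConvTranspose2d(latent_dim, ch[0], kernel=4, stride=1, pad=0,
                        output_pad=0, rng=rng),
        BatchNorm(ch[0], momentum=_BN_MOMENTUM),
        ReLU(),
    ]
    for cin, cout in zip(ch, ch[1:]):
        layers += [
            ConvTranspose2d(cin, cout, kernel=3, stride=2, pad=1, output_pad=1,
                            rng=rng),
            BatchNorm(cout, momentum=_BN_MOMENTUM),
            ReLU(),
        ]
    layers += [
        ConvTranspose2d(ch[-1], 3, kernel=3, stride=2, pad=1, output_pad=1,
                        rng=rng),
        Tanh(),
    ]
    return Network(layers)


def build_discriminator(base_width: int = 1024,
                        channels: tuple[int, ...] | None = None,
                        dropout: float = 0.25, seed: int = 0) -> Network:
    """Image (N,3,64,64) -> real/fake probability in (0,1).

    Stride-2 3x3 convolutions with doubling widths, leaky-ReLU (0.2) and
    dropout after every block, batch norm on the middle two blocks, then a
    flatten (16*base_width features at the default width) and sigmoid score.
    """
    ch = _check_channels(channels if channels is not None
                         else tuple(reversed(generator_channels(base_width))))
    if any(b != 2 * a for a, b in zip(ch, ch[1:])):
        raise ValueError(f"discriminator widths {ch} must double layer by layer")
    rng = np.random.default_rng(seed)
    layers = [
        Conv2d(3, ch[0], kernel=3, stride=2, pad=1, rng=rng, init="dcgan"),
        LeakyReLU(0.2),
        Dropout(dropout),
        Conv2d(ch[0], ch[1], kernel=3, stride=2, pad=1, rng=rng, init="dcgan"),
        LeakyReLU(0.2),
        Dropout(dropout),
        BatchNorm(ch[1], momentum=_BN_MOMENTUM),
        Conv2d(ch[1], ch[2], kernel=3, stride=2, pad=1, rng=rng, init="dcgan"),
        LeakyReLU(0.2),
        Dropout(dropout),
        BatchNorm(ch[2], momentum=_BN_MOMENTUM),
        Conv2d(ch[2], ch[3], kernel=3, stride=2, pad=1, rng=rng, init="dcgan"),
        LeakyReLU(0.2),
        Dropout(dropout),
        Flatten(),
        Dense(ch[3] * 4 * 4, 1, rng=rng, init="dcgan"),
        Sigmoid(),
    ]
    return Network(layers)


def gan_losses(d_real, d_fake) -> tuple[float, float]:
    """Discriminator and generator losses from sigmoid scores in (0, 1).

    loss_D is the binary cross-entropy over the concatenated batch (real
    labelled 1, fake labelled 0); loss_G is the non-saturating
    −mean log D(G(z)).
    """
    d_real = np.asarray(d_real, dtype=float).ravel()
    d_fake = np.asarray(d_fake, dtype=float).ravel()
    for scores in (d_real, d_fake):
        if scores.size == 0:
            raise ValueError("empty score vector")
        if np.any(scores <= 0) or np.any(scores >= 1):
            raise ValueError("scores must lie strictly inside (0, 1)")
    n = d_real.size + d_fake.size
    loss_d = float((-np.log(d_real).sum() - np.log(1.0 - d_fake).sum()) / n)
    loss_g = float(-np.log(d_fake).mean())
    return loss_d, loss_g


def _images_to_gan_batch(images) -> np.ndarray:
    pixels = images.pixels if isinstance(images, ImageSet) else np.asarray(images)
    return (pixels.astype(np.float32).transpose(0, 3, 1, 2) * 2.0 - 1.0)


def train_dcgan(images, config: GANTrainConfig = GANTrainConfig(),
                callback=None) -> GANState:
    """Adversarial training on one image set (typically one subject+class).

    Per batch the discriminator sees a real and a fake half (labels 1 and 0),
    then the generator is updated against −log D(G(z)). ``callback(epoch,
    state)`` runs after every epoch (e.g. to track sample quality).
    Deterministic given ``config.seed``.
    """
    x = _images_to_gan_batch(images)
    n = x.shape[0]
    if n == 0:
        raise ValueError("cannot train a GAN on an empty image set")
    rng = np.random.default_rng(config.seed)
    gen = build_generator(config.base_width, seed=int(rng.integers(2**31)))
    disc = build_discriminator(config.base_width, dropout=config.dropout,
                               seed=int(rng.integers(2**31)))
    opt_g = Adam(gen.params(), lr=config.learning_rate, beta1=config.beta1,
                 beta2=config.beta2)
    opt_d = Adam(disc.params(), lr=config.learning_rate, beta1=config.beta1,
                 beta2=config.beta2)
    batch = min(config.batch_size, n)
    state = GANState(gen, disc, config=config)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        d_epoch, g_epoch = [], []
        for start in range(0, n - batch + 1, batch):
            real = x[order[start : start + batch]]
            m = real.shape[0]
            # --- discriminator step
            z = rng.standard_normal((m, LATENT_DIM, 1, 1)).astype(np.float32)
            fake = gen.forward(z, train=True, rng=rng)
            disc.zero_grad()
            d_real = disc.forward(real, train=True, rng=rng)
            _, grad_r = binary_cross_entropy(d_real, np.ones_like(d_real))
            disc.backward((grad_r / 2.0).astype(d_real.dtype))
            d_fake = disc.forward(fake, train=True, rng=rng)
            _, grad_f = binary_cross_entropy(d_fake, np.zeros_like(d_fake))
            disc.backward((grad_f / 2.0).astype(d_fake.dtype))
            opt_d.step()
            loss_d, _ = gan_losses(np.clip(d_real, _EPS, 1 - _EPS),
                                   np.clip(d_fake, _EPS, 1 - _EPS))
            # --- generator step (non-saturating)
            z = rng.standard_normal((m, LATENT_DIM, 1, 1)).astype(np.float32)
            fake = gen.forward(z, train=True, rng=rng)
            d_on_fake = disc.forward(fake, train=True, rng=rng)
            _, grad_g = binary_cross_entropy(d_on_fake, np.ones_like(d_on_fake))
            disc.zero_grad()
            dx = disc.backward(grad_g.astype(d_on_fake.dtype))
            disc.zero_grad()
            gen.zero_grad()
            gen.backward(dx)
            opt_g.step()
            loss_g = float(-np.log(np.clip(d_on_fake, _EPS, None)).mean())
            d_epoch.append(loss_d)
            g_epoch.append(loss_g)
        state.d_losses.append(float(np.mean(d_epoch)))
        state.g_losses.append(float(np.mean(g_epoch)))
        state.epoch = epoch + 1
        if callback is not None:
            callback(epoch + 1, state)
    return state


def sample_generated(state: GANState, n: int, label: str,
                     seed: int = 0) -> ImageSet:
    """Draw ``n`` images from the trained generator (provenance ``dcgan``).

    The tanh output in [-1,1] is linearly rescaled to [0,1].
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, LATENT_DIM, 1, 1)).astype(np.float32)
    out = state.generator.forward(z, train=False)
    pixels = np.clip((out.transpose(0, 2, 3, 1) + 1.0) / 2.0, 0.0, 1.0)
    return ImageSet(pixels, np.array([label] * n), np.array(["dcgan"] * n))


# ---------------------------------------------------------------------------
# Autoencoder / variational autoencoder


@dataclass
class AutoencoderModel:
    """Encoder/decoder pair; for the VAE the encoder head emits mean||logvar."""

    kind: str  # "ae" or "vae"
    encoder: Network
    decoder: Network
    latent_dim: int = LATENT_DIM
    losses: list[float] = field(default_factory=list)
    latent_bank: np.ndarray | None = None  # encoded real images (AE sampling)


def _build_encoder(base_width: int, out_dim: int, seed: int) -> Network:
    ch = tuple(reversed(generator_channels(base_width)))
    rng = np.random.default_rng(seed)
    layers = []
    cin = 3
    for cout in ch:
        layers += [
            Conv2d(cin, cout, kernel=3, stride=2, pad=1, rng=rng),
            LeakyReLU(0.2),
        ]
        cin = cout
    layers += [Flatten(), Dense(ch[-1] * 4 * 4, out_dim, rng=rng)]
    return Network(layers)


def build_autoencoder(base_width: int = 1024, seed: int = 0) -> AutoencoderModel:
    """Deterministic 100-dim bottleneck mirroring the DCGAN stacks."""
    rng = np.random.default_rng(seed)
    enc = _build_encoder(base_width, LATENT_DIM, int(rng.integers(2**31)))
    dec = build_generator(base_width, seed=int(rng.integers(2**31)))
    return AutoencoderModel("ae", enc, dec)


def build_vae(base_width: int = 1024, seed: int = 0) -> AutoencoderModel:
    """Encoder emits (mean, log-variance); decoder is the AE decoder."""
    rng = np.random.default_rng(seed)
    enc = _build_encoder(base_width, 2 * LATENT_DIM, int(rng.integers(2**31)))
    dec = build_generator(base_width, seed=int(rng.integers(2**31)))
    return AutoencoderModel("vae", enc, dec)


def vae_kl(mean: np.ndarray, logvar: np.ndarray) -> float:
    """KL(q(z|x) || N(0,I)) averaged over the batch; >= 0, zero at (0, 0)."""
    mean, logvar = np.asarray(mean, float), np.asarray(logvar, float)
    kl = 0.5 * (mean**2 + np.exp(logvar) - 1.0 - logvar)
    return float(kl.sum(axis=-1).mean())


def train_autoencoder(kind: str, images, config: GANTrainConfig = GANTrainConfig(),
                      kl_weight: float = 1e-3) -> AutoencoderModel:
    """Train an AE or VAE on an image set; returns the model with loss history.

    The reconstruction term is the mean squared error on tanh-scaled images;
    the VAE adds ``kl_weight`` times the KL to the standard normal prior.
    """
    if kind not in ("ae", "vae"):
        raise ValueError("kind must be 'ae' or 'vae'")
    x = _images_to_gan_batch(images)
    n = x.shape[0]
    if n == 0:
        raise ValueError("cannot train on an empty image set")
    rng = np.random.default_rng(config.seed)
    build = build_autoencoder if kind == "ae" else build_vae
    model = build(config.base_width, seed=int(rng.integers(2**31)))
    params = model.encoder.params() + model.decoder.params()
    opt = Adam(params, lr=config.learning_rate, beta1=config.beta1,
               beta2=config.beta2)
    batch = min(config.batch_size, n)
    d = model.latent_dim
    for _ in range(config.epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n - batch + 1, batch):
            xb = x[order[start : start + batch]]
            m = xb.shape[0]
            h = model.encoder.forward(xb, train=True, rng=rng)
            if kind == "ae":
                z = h
            else:
                mu, logvar = h[:, :d], h[:, d:]
                eps_n = rng.standard_normal((m, d)).astype(h.dtype)
                z = mu + np.exp(0.5 * logvar) * eps_n
            out = model.decoder.forward(z.reshape(m, d, 1, 1), train=True, rng=rng)
            diff = out - xb
            recon = float((diff**2).mean())
            dout = (2.0 * diff / diff.size).astype(out.dtype)
            model.encoder.zero_grad()
            model.decoder.zero_grad()
            dz = model.decoder.backward(dout).reshape(m, d)
            if kind == "ae":
                dh = dz
                loss = recon
            else:
                kl = vae_kl(mu, logvar)
                loss = recon + kl_weight * kl
                dmu = dz + kl_weight * mu / m
                dlogvar = (dz * eps_n * 0.5 * np.exp(0.5 * logvar)
                           + kl_weight * 0.5 * (np.exp(logvar) - 1.0) / m)
                dh = np.concatenate([dmu, dlogvar], axis=1)
            model.encoder.backward(dh.astype(h.dtype))
            opt.step()
            epoch_losses.append(loss)
        model.losses.append(float(np.mean(epoch_losses)))
    # encode the training set once for AE latent-perturbation sampling
    h = model.encoder.forward(x, train=False)
    model.latent_bank = h[:, :d] if kind == "vae" else h
    return model


def sample_autoencoder(model: AutoencoderModel, n: int, label: str,
                       seed: int = 0, noise_scale: float = 0.25) -> ImageSet:
    """Sample ``n`` images (provenance ``ae``/``vae``).

    VAE: latents drawn from the standard normal prior. AE: random encoded
    training latents perturbed with spherical noise of ``noise_scale`` times
    the per-dimension latent spread.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    d = model.latent_dim
    if model.kind == "vae":
        z = rng.standard_normal((n, d))
    else:
        if model.latent_bank is None or len(model.latent_bank) == 0:
            raise ValueError("AE must be trained before sampling")
        bank = model.latent_bank
        idx = rng.integers(len(bank), size=n)
        spread = bank.std(axis=0, keepdims=True) + 1e-8
        z = bank[idx] + noise_scale * spread * rng.standard_normal((n, d))
    out = model.decoder.forward(z.reshape(n, d, 1, 1).astype(np.float32),
                                train=False)
    pixels = np.clip((out.transpose(0, 2, 3, 1) + 1.0) / 2.0, 0.0, 1.0)
    return ImageSet(pixels, np.array([label] * n), np.array([model.kind] * n))
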