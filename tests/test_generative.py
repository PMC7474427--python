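"""DCGAN/AE/VAE: architecture conformance, loss oracles, training sanity."""

import numpy as np
import pytest

from miaug.generative import (
    GANTrainConfig,
    LATENT_DIM,
    build_autoencoder,
    build_discriminator,
    build_generator,
    build_vae,
    gan_losses,
    sample_autoencoder,
    sample_generated,
    train_autoencoder,
    train_dcgan,
    vae_kl,
    GANState,
)
from miaug.preprocess import ImageSet


def tiny_images(n=32, seed=0):
    rng = np.random.default_rng(seed)
    pixels = np.clip(0.5 + 0.2 * rng.standard_normal((n, 64, 64, 3)), 0, 1)
    return ImageSet(pixels, np.array(["left"] * n), np.array(["real"] * n))


SMALL = GANTrainConfig(base_width=16, batch_size=16, epochs=2, seed=0)


class TestArchitecture:
    GEN_SHAPES = [(1024, 4, 4), (512, 8, 8), (256, 16, 16), (128, 32, 32),
                  (3, 64, 64)]
    DISC_SHAPES = [(128, 32, 32), (256, 16, 16), (512, 8, 8), (1024, 4, 4)]

    def test_generator_layerwise_dimensions_at_full_width(self):
        gen = build_generator(base_width=1024, seed=0)
        z = np.random.default_rng(0).standard_normal(
            (1, LATENT_DIM, 1, 1)
        ).astype(np.float32)
        shapes = {out.shape[1:] for out in gen.layer_outputs(z)}
        for expected in self.GEN_SHAPES:
            assert expected in shapes
        assert gen.forward(z).shape == (1, 3, 64, 64)

    def test_discriminator_layerwise_dimensions_and_flatten(self):
        disc = build_discriminator(base_width=1024, seed=0)
        x = np.random.default_rng(1).standard_normal(
            (1, 3, 64, 64)
        ).astype(np.float32)
        outs = disc.layer_outputs(x)
        shapes = {o.shape[1:] for o in outs}
        for expected in self.DISC_SHAPES:
            assert expected in shapes
        assert (16384,) in shapes  # flattened feature length
        score = outs[-1]
        assert score.shape == (1, 1) and 0.0 <= score[0, 0] <= 1.0

    def test_zero_parameter_generator_outputs_zero(self):
        gen = build_generator(base_width=16, seed=0)
        for p in gen.params():
            p.value[...] = 0.0
        for layer in gen.layers:  # keep batch-norm gamma at 1 for a pure pass
            if hasattr(layer, "gamma"):
                layer.gamma.value[...] = 1.0
        z = np.zeros((2, LATENT_DIM, 1, 1), dtype=np.float32)
        out = gen.forward(z)
        np.testing.assert_allclose(out, 0.0, atol=1e-7)

    def test_zero_parameter_discriminator_scores_half(self):
        disc = build_discriminator(base_width=16, seed=0)
        for p in disc.params():
            p.value[...] = 0.0
        x = np.random.default_rng(2).standard_normal((3, 3, 64, 64)).astype(np.float32)
        np.testing.assert_allclose(disc.forward(x), 0.5, atol=1e-7)

    def test_halving_doubling_violation_rejected(self):
        with pytest.raises(ValueError, match="halving"):
            build_generator(channels=(1024, 512, 300, 128))
        with pytest.raises(ValueError):
            build_discriminator(channels=(128, 256, 512, 512))

    def test_scaled_width_keeps_spatial_progression(self):
        gen = build_generator(base_width=64, seed=1)
        z = np.zeros((1, LATENT_DIM, 1, 1), dtype=np.float32)
        spatial = [o.shape[-1] for o in gen.layer_outputs(z) if o.ndim == 4]
        assert spatial[-1] == 64 and sorted(set(spatial)) == [1, 4, 8, 16, 32, 64]


class TestGANLosses:
    def test_perfect_discrimination_drives_loss_to_zero(self):
        for eps in (1e-3, 1e-6, 1e-9):
            loss_d, _ = gan_losses([1 - eps] * 4, [eps] * 4)
            assert loss_d < 10 * eps

    def test_chance_scores_give_ln2(self):
        loss_d, loss_g = gan_losses([0.5], [0.5])
        assert loss_d == pytest.approx(np.log(2), abs=1e-12)
        assert loss_g == pytest.approx(np.log(2), abs=1e-12)

    def test_matches_brute_force_elementwise_evaluation(self):
        rng = np.random.default_rng(0)
        d_real = rng.uniform(0.01, 0.99, size=37)
        d_fake = rng.uniform(0.01, 0.99, size=41)
        loss_d, loss_g = gan_losses(d_real, d_fake)
        n = d_real.size + d_fake.size
        brute_d = (sum(-np.log(s) for s in d_real)
                   + sum(-np.log(1 - s) for s in d_fake)) / n
        brute_g = sum(-np.log(s) for s in d_fake) / d_fake.size
        assert loss_d == pytest.approx(brute_d, abs=1e-10)
        assert loss_g == pytest.approx(brute_g, abs=1e-10)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.3])
    def test_scores_outside_unit_interval_rejected(self, bad):
        with pytest.raises(ValueError):
            gan_losses([0.5, bad], [0.5])


class TestDCGANTraining:
    def test_fixed_seed_training_is_deterministic(self):
        images = tiny_images(16)
        s1 = train_dcgan(images, SMALL)
        s2 = train_dcgan(images, SMALL)
        assert s1.d_losses == s2.d_losses
        for a, b in zip(s1.generator.state(), s2.generator.state()):
            np.testing.assert_array_equal(a, b)

    def test_loss_history_length_equals_epochs(self):
        images = tiny_images(16)
        state = train_dcgan(images, SMALL)
        assert len(state.d_losses) == SMALL.epochs == state.epoch
        assert len(state.g_losses) == SMALL.epochs

    def test_empty_image_set_rejected(self):
        empty = ImageSet(np.zeros((0, 64, 64, 3)), np.array([]), np.array([]))
        with pytest.raises(ValueError, match="empty"):
            train_dcgan(empty, SMALL)

    def test_batch_clamped_to_small_datasets(self):
        images = tiny_images(10)
        state = train_dcgan(images, GANTrainConfig(base_width=16, batch_size=128,
                                                   epochs=1, seed=1))
        assert len(state.d_losses) == 1  # one clamped batch still trains


class TestSampling:
    def test_sample_shapes_range_and_provenance(self):
        state = train_dcgan(tiny_images(16), SMALL)
        out = sample_generated(state, 5, "left", seed=3)
        assert out.pixels.shape == (5, 64, 64, 3)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
        assert set(out.provenance.tolist()) == {"dcgan"}
        assert set(out.labels.tolist()) == {"left"}

    def test_same_state_and_seed_reproduce_samples(self):
        state = train_dcgan(tiny_images(16), SMALL)
        a = sample_generated(state, 4, "right", seed=9)
        b = sample_generated(state, 4, "right", seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_zero_parameter_generator_samples_mid_range(self):
        gen = build_generator(base_width=16, seed=0)
        for p in gen.params():
            p.value[...] = 0.0
        for layer in gen.layers:
            if hasattr(layer, "gamma"):
                layer.gamma.value[...] = 1.0
        state = GANState(gen, build_discriminator(base_width=16, seed=0))
        out = sample_generated(state, 3, "left", seed=0)
        np.testing.assert_allclose(out.pixels, 0.5, atol=1e-6)

    def test_nonpositive_count_rejected(self):
        state = train_dcgan(tiny_images(16), SMALL)
        with pytest.raises(ValueError):
            sample_generated(state, 0, "left")


class TestAutoencoders:
    def test_ae_reconstruction_shape(self):
        model = build_autoencoder(base_width=16, seed=0)
        x = np.random.default_rng(0).standard_normal((2, 3, 64, 64)).astype(np.float32)
        z = model.encoder.forward(x)
        assert z.shape == (2, LATENT_DIM)
        recon = model.decoder.forward(z.reshape(2, LATENT_DIM, 1, 1))
        assert recon.shape == (2, 3, 64, 64)

    def test_vae_head_emits_mean_and_logvar(self):
        model = build_vae(base_width=16, seed=0)
        x = np.zeros((2, 3, 64, 64), dtype=np.float32)
        h = model.encoder.forward(x)
        assert h.shape == (2, 2 * LATENT_DIM)

    def test_kl_nonnegative_and_zero_at_standard_normal(self):
        assert vae_kl(np.zeros((4, 8)), np.zeros((4, 8))) == 0.0
        rng = np.random.default_rng(1)
        for _ in range(5):
            mu = rng.standard_normal((4, 8))
            lv = rng.standard_normal((4, 8))
            assert vae_kl(mu, lv) >= 0.0

    @pytest.mark.parametrize("kind", ["ae", "vae"])
    def test_training_reduces_loss(self, kind):
        images = tiny_images(24, seed=2)
        cfg = GANTrainConfig(base_width=16, batch_size=24, epochs=5,
                             learning_rate=1e-3, seed=0)
        model = train_autoencoder(kind, images, cfg)
        assert len(model.losses) == 5
        assert model.losses[-1] < model.losses[0]

    @pytest.mark.parametrize("kind", ["ae", "vae"])
    def test_sampling_contract(self, kind):
        images = tiny_images(16, seed=3)
        model = train_autoencoder(kind, images,
                                  GANTrainConfig(base_width=16, batch_size=16,
                                                 epochs=1, seed=0))
        out = sample_autoencoder(model, 10, "right", seed=5)
        assert out.pixels.shape == (10, 64, 64, 3)
        assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0
        assert set(out.provenance.tolist()) == {kind}
        again = sample_autoencoder(model, 10, "right", seed=5)
        np.testing.assert_array_equal(out.pixels, again.pixels)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            train_autoencoder("gan", tiny_images(4), SMALL)


def test_discriminator_approaches_chance_on_converging_gan():
    """Adversarial balance: D's real/fake separation shrinks over training."""
    images = tiny_images(32, seed=4)
    gaps = []
    for seed in range(3):
        cfg = GANTrainConfig(base_width=16, batch_size=16, epochs=8, seed=seed)
        state = train_dcgan(images, cfg)
        early = abs(state.d_losses[0] - np.log(2))
        late = abs(state.d_losses[-1] - np.log(2))
        gaps.append(late < early + 0.25)
    assert sum(gaps) >= 2
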