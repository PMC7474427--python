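"""Fréchet-distance oracles, kappa/accuracy arithmetic, statistical guards."""

import numpy as np
import pytest

from miaug.metrics import (
    DegenerateInputError,
    FeatureEmbedding,
    accuracy,
    compute_fid,
    extract_features,
    frechet_distance,
    gaussian_frechet,
    kappa,
    one_way_anova,
    paired_ttest,
)


def eig_sqrtm(mat):
    """Eigendecomposition-based matrix square root (independent oracle)."""
    vals, vecs = np.linalg.eig(mat)
    return (vecs * np.sqrt(np.maximum(vals, 0.0))) @ np.linalg.inv(vecs)


def brute_force_frechet(a, b):
    mu1, mu2 = a.mean(axis=0), b.mean(axis=0)
    c1 = np.cov(a, rowvar=False) + 1e-6 * np.eye(a.shape[1])
    c2 = np.cov(b, rowvar=False) + 1e-6 * np.eye(b.shape[1])
    root = eig_sqrtm(c1 @ c2)
    return float(np.sum((mu1 - mu2) ** 2) + np.trace(c1 + c2 - 2 * root.real))


class TestFrechet:
    def test_identical_sets_give_zero(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((50, 4))
        emb = FeatureEmbedding(x, "test")
        assert frechet_distance(emb, emb).value == pytest.approx(0.0, abs=1e-6)

    def test_univariate_closed_form_with_exact_moments(self):
        # (mu1-mu2)^2 + s1^2 + s2^2 - 2 s1 s2 = 1 for N(0,1) vs N(1,1)
        value = gaussian_frechet([0.0], [[1.0]], [1.0], [[1.0]], jitter=0.0)
        assert value == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("d", [1, 2, 3])
    def test_matches_brute_force_eigendecomposition(self, d):
        rng = np.random.default_rng(d)
        a = rng.standard_normal((40, d)) @ rng.standard_normal((d, d))
        b = rng.standard_normal((40, d)) + 0.5
        result = frechet_distance(FeatureEmbedding(a, "t"),
                                  FeatureEmbedding(b, "t"))
        assert result.value == pytest.approx(brute_force_frechet(a, b), abs=1e-8)

    def test_symmetry(self):
        rng = np.random.default_rng(5)
        a = FeatureEmbedding(rng.standard_normal((30, 3)), "t")
        b = FeatureEmbedding(rng.standard_normal((30, 3)) * 2 + 1, "t")
        assert frechet_distance(a, b).value == pytest.approx(
            frechet_distance(b, a).value, abs=1e-8
        )

    def test_nonnegative_on_random_embeddings(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            a = FeatureEmbedding(rng.standard_normal((20, 5)), "t")
            b = FeatureEmbedding(rng.standard_normal((20, 5)), "t")
            assert frechet_distance(a, b).value >= -1e-8

    def test_dimension_mismatch_rejected(self):
        a = FeatureEmbedding(np.zeros((5, 2)), "t")
        b = FeatureEmbedding(np.zeros((5, 3)), "t")
        with pytest.raises(ValueError, match="dimensions"):
            frechet_distance(a, b)

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            FeatureEmbedding(np.array([[np.nan, 0.0]]), "t")


class TestEmbedders:
    def _images(self, n=12, seed=0):
        rng = np.random.default_rng(seed)
        return rng.random((n, 64, 64, 3))

    @pytest.mark.parametrize("embedder", ["flatten-pca", "small-cnn"])
    def test_deterministic_and_one_vector_per_image(self, embedder):
        images = self._images()
        a = extract_features(images, embedder)
        b = extract_features(images, embedder)
        assert a.vectors.shape[0] == 12
        np.testing.assert_array_equal(a.vectors, b.vectors)

    def test_rank_one_set_concentrates_variance_in_first_component(self):
        base = np.linspace(0, 1, 64 * 64 * 3).reshape(64, 64, 3)
        weights = np.linspace(0.1, 1.0, 10)
        images = np.stack([w * base for w in weights])
        emb = extract_features(images, "flatten-pca", dim=5)
        var = emb.vectors.var(axis=0)
        assert var[0] / var.sum() > 0.999

    def test_unknown_embedder_rejected(self):
        with pytest.raises(ValueError, match="unknown embedder"):
            extract_features(self._images(), "resnet")

    def test_inception_embedder_explains_weight_requirement(self):
        with pytest.raises(ValueError, match="weights"):
            extract_features(self._images(), "pretrained-inception")

    def test_fid_discriminates_real_from_noise(self):
        from miaug.preprocess import trials_to_images
        from miaug.simulate import SimConfig, simulate_trials

        images = trials_to_images(
            simulate_trials(SimConfig(n_trials_per_class=20, seed=7))
        )
        real_a = images.pixels[0::2]
        real_b = images.pixels[1::2]
        noise = np.random.default_rng(8).random((20, 64, 64, 3))
        close = compute_fid(real_b, real_a, dim=8).value
        far = compute_fid(real_b, noise, dim=8).value
        assert close < far


class TestAccuracyKappa:
    @pytest.mark.parametrize("pred,true,expected", [
        (["l", "r"], ["l", "r"], 1.0),
        (["l", "l"], ["r", "r"], 0.0),
        (["l", "r", "l", "r"], ["l", "r", "l", "l"], 0.75),
    ])
    def test_accuracy_fraction(self, pred, true, expected):
        assert accuracy(np.array(pred), np.array(true)) == expected

    def test_accuracy_empty_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.array([]), np.array([]))

    def test_kappa_zero_at_chance_both_formulas(self):
        assert kappa(0.5, 0.5, "cohen") == 0.0
        assert kappa(0.5, 0.5, "ratio") == 0.0

    def test_kappa_ratio_variant_arithmetic(self):
        assert kappa(0.75, 0.5, "ratio") == pytest.approx(0.5)

    def test_kappa_cohen_perfect_agreement(self):
        assert kappa(1.0, 0.5, "cohen") == pytest.approx(1.0)

    def test_kappa_strictly_increasing_in_accuracy(self):
        accs = np.linspace(0.4, 1.0, 13)
        for formula in ("cohen", "ratio"):
            vals = [kappa(a, 0.5, formula) for a in accs]
            assert all(x < y for x, y in zip(vals, vals[1:]))

    def test_kappa_chance_bounds(self):
        with pytest.raises(ValueError):
            kappa(0.8, 0.0)
        with pytest.raises(ValueError):
            kappa(0.8, 1.0)


class TestSignificance:
    def test_paired_t_sign_matches_hand_computation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.8, 0.02, size=10)
        b = a + 0.05 + rng.normal(0.0, 0.01, size=10)  # b larger
        t, p = paired_ttest(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(10))
        assert t == pytest.approx(t_hand, rel=1e-10)
        assert t < 0 and 0 < p <= 1

    def test_constant_difference_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            paired_ttest(np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0]))

    def test_anova_identical_constant_groups_degenerate(self):
        with pytest.raises(DegenerateInputError):
            one_way_anova([np.ones(5), np.ones(5)])

    def test_anova_two_groups_equals_t_squared(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 12)
        f, p_f = one_way_anova([a, b])
        from scipy.stats import ttest_ind

        t, p_t = ttest_ind(a, b)
        assert f == pytest.approx(t**2, abs=1e-8)
        assert p_f == pytest.approx(p_t, abs=1e-10)

    def test_anova_needs_two_groups(self):
        with pytest.raises(ValueError):
            one_way_anova([np.ones(5)])
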