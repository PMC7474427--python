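"""Quality and performance metrics.

Generated-image quality is scored with the Fréchet distance between Gaussian
fits to feature embeddings of the real and generated sets,

    FID(r, g) = ||mu_r - mu_g||^2 + Tr(S_r + S_g - 2 (S_r S_g)^{1/2}),

i.e. the squared Wasserstein-2 distance between N(mu_r, S_r) and N(mu_g, S_g).
The feature embedder is pluggable: the default is a deterministic flatten+PCA
fit on the real set, and a fixed-seed random CNN trunk is available; an
Inception-style pretrained embedder id is recognised but requires external
network weights and is therefore not bundled.

Classification performance uses accuracy and a chance-corrected kappa; for
balanced two-class motor imagery the chance level is 0.5. Two kappa
normalisations are exposed: Cohen's (acc - chance)/(1 - chance), the default,
and the variant (acc - chance)/chance. Significance testing wraps the paired
t-test and one-way ANOVA from scipy with explicit degenerate-input guards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "FeatureEmbedding",
    "FIDResult",
    "MetricReport",
    "extract_features",
    "frechet_distance",
    "gaussian_frechet",
    "compute_fid",
    "accuracy",
    "kappa",
    "paired_ttest",
    "one_way_anova",
    "DegenerateInputError",
]

EMBEDDERS = ("flatten-pca", "small-cnn", "pretrained-inception")


class DegenerateInputError(ValueError):
    """Raised when a statistic is undefined (e.g. zero-variance differences)."""


@dataclass
class FeatureEmbedding:
    """n x d feature vectors for a set of images."""

    vectors: np.ndarray
    embedder_id: str

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a 2-D (n, d) array")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("feature vectors contain non-finite entries")


@dataclass
class FIDResult:
    value: float
    mu_real: np.ndarray
    mu_generated: np.ndarray
    cov_real: np.ndarray
    cov_generated: np.ndarray
    n_real: int
    n_generated: int


@dataclass
class MetricReport:
    """Per-fold and aggregate classification results for one (method, ratio)."""

    method: str
    ratio: int
    fold_accuracies: list[float]
    fold_kappas: list[float]
    config: dict = field(default_factory=dict)
    audit: list[dict] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.fold_kappas))

    def summary(self) -> dict:
        return {
            "method": self.method,
            "ratio": self.ratio,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_kappa": self.mean_kappa,
            "n_folds": len(self.fold_accuracies),
        }


# ---------------------------------------------------------------------------
# Feature embedders


def _flatten(images) -> np.ndarray:
    pixels = images.pixels if hasattr(images, "pixels") else np.asarray(images)
    return pixels.reshape(pixels.shape[0], -1)


def _pca_embed(images, reference, dim):
    from sklearn.decomposition import PCA

    x = _flatten(images)
    ref = _flatten(reference) if reference is not None else x
    n_comp = min(dim, ref.shape[0], ref.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full", random_state=0)
    pca.fit(ref)
    return pca.transform(x)


def _small_cnn_embed(images, seed=1234):
    """Features from a fixed-seed random convolutional trunk (64x64x3 -> 128)."""
    from .nn import Conv2d, Flatten, LeakyReLU, MaxPool2d, Network

    rng = np.random.default_rng(seed)
    net = Network([
        Conv2d(3, 8, kernel=3, stride=2, pad=1, rng=rng),
        LeakyReLU(0.2),
        Conv2d(8, 16, kernel=3, stride=2, pad=1, rng=rng),
        LeakyReLU(0.2),
        Conv2d(16, 32, kernel=3, stride=2, pad=1, rng=rng),
        LeakyReLU(0.2),
        MaxPool2d(4),
        Flatten(),
    ])
    x = (_flatten(images).reshape(-1, 64, 64, 3).transpose(0, 3, 1, 2) * 2.0 - 1.0)
    return np.asarray(net.forward(x.astype(np.float32)), dtype=float)


def extract_features(images, embedder: str = "flatten-pca", *, reference=None,
                     dim: int = 64) -> FeatureEmbedding:
    """Embed images into feature vectors for Fréchet-distance estimation.

    Parameters
    ----------
    images : ImageSet or (n, 64, 64, 3) array.
    embedder : one of ``flatten-pca`` (PCA fit on ``reference`` or on the
        images themselves), ``small-cnn`` (fixed random trunk), or
        ``pretrained-inception`` (recognised but needs external weights).
    reference : the real set to fit the PCA on, for consistent projections of
        real and generated images.
    """
    n = _flatten(images).shape[0]
    if n == 0:
        raise ValueError("image set is empty")
    if embedder == "flatten-pca":
        vectors = _pca_embed(images, reference, dim)
    elif embedder == "small-cnn":
        vectors = _small_cnn_embed(images)
    elif embedder == "pretrained-inception":
        raise ValueError(
            "the pretrained-inception embedder needs external network weights; "
            "use 'flatten-pca' (default) or 'small-cnn'"
        )
    else:
        raise ValueError(f"unknown embedder {embedder!r}; choose from {EMBEDDERS}")
    return FeatureEmbedding(vectors, embedder)


# ---------------------------------------------------------------------------
# Fréchet distance


def gaussian_frechet(mu1, cov1, mu2, cov2, *, jitter: float = 1e-6) -> float:
    """Fréchet distance between two Gaussians given their exact moments.

    Uses the matrix square root of ``cov1 @ cov2``; a small diagonal jitter
    stabilises the root for near-singular covariances.
    """
    mu1, mu2 = np.atleast_1d(mu1).astype(float), np.atleast_1d(mu2).astype(float)
    cov1, cov2 = np.atleast_2d(cov1).astype(float), np.atleast_2d(cov2).astype(float)
    d = mu1.size
    eye = np.eye(d)
    c1, c2 = cov1 + jitter * eye, cov2 + jitter * eye
    covmean = linalg.sqrtm(c1 @ c2)
    if np.iscomplexobj(covmean):
        covmean = covmean.real
    value = float(np.sum((mu1 - mu2) ** 2) + np.trace(c1 + c2 - 2.0 * covmean))
    return value


def frechet_distance(real: FeatureEmbedding, generated: FeatureEmbedding,
                     *, jitter: float = 1e-6) -> FIDResult:
    """Fréchet distance between Gaussian fits to two embeddings.

    Symmetric in its arguments and non-negative up to numerical tolerance;
    exactly zero (to ~1e-6) when the two empirical distributions coincide.
    Covariances use the unbiased (n-1) estimator, so each side needs n >= 2.
    """
    a, b = real.vectors, generated.vectors
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"feature dimensions differ: {a.shape[1]} vs {b.shape[1]}"
        )
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 samples per side to estimate covariance")
    mu_r, mu_g = a.mean(axis=0), b.mean(axis=0)
    cov_r = np.cov(a, rowvar=False).reshape(a.shape[1], a.shape[1])
    cov_g = np.cov(b, rowvar=False).reshape(b.shape[1], b.shape[1])
    value = gaussian_frechet(mu_r, cov_r, mu_g, cov_g, jitter=jitter)
    return FIDResult(value, mu_r, mu_g, cov_r, cov_g, a.shape[0], b.shape[0])


def compute_fid(real_images, generated_images, embedder: str = "flatten-pca",
                *, dim: int = 64) -> FIDResult:
    """Convenience wrapper: embed both sets (PCA fit on the real set) and score."""
    emb_r = extract_features(real_images, embedder, reference=real_images, dim=dim)
    emb_g = extract_features(generated_images, embedder, reference=real_images,
                             dim=dim)
    return frechet_distance(emb_r, emb_g)


# ---------------------------------------------------------------------------
# Classification metrics


def accuracy(predicted, true) -> float:
    predicted, true = np.asarray(predicted), np.asarray(true)
    if predicted.shape != true.shape:
        raise ValueError("predicted and true labels must have the same length")
    if predicted.size == 0:
        raise ValueError("empty label arrays")
    return float((predicted == true).mean())


def kappa(acc: float, chance: float = 0.5, formula: str = "cohen") -> float:
    """Chance-corrected agreement.

    ``formula="cohen"`` gives (acc - chance)/(1 - chance); ``formula="ratio"``
    gives the variant (acc - chance)/chance. Both are zero at chance level and
    strictly increasing in accuracy.
    """
    if not 0.0 < chance < 1.0:
        raise ValueError("chance level must lie in (0, 1)")
    if formula == "cohen":
        return (acc - chance) / (1.0 - chance)
    if formula == "ratio":
        return (acc - chance) / chance
    raise ValueError("formula must be 'cohen' or 'ratio'")


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on per-fold scores.

    Raises :class:`DegenerateInputError` when the fold-wise differences have
    zero variance (the statistic is undefined).
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1-D arrays of equal length")
    if a.size < 2:
        raise ValueError("need at least 2 paired scores")
    if np.var(a - b) == 0:
        raise DegenerateInputError("paired differences have zero variance")
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F statistic and p-value across score groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValueError("every group needs at least 2 values")
    if all(np.var(g) == 0 for g in groups):
        raise DegenerateInputError("zero within-group variance in every group")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
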