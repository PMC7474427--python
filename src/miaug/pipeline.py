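"""The cross-validation evaluation protocol with augmentation ratio sweeps.

Real images are split into 10 stratified folds; per fold, 90% of the real
images plus generated images at a stated real:generated (RD:GD) ratio form the
training pool, and the held-out 10% — real images only, always — form the test
set. Generative models are retrained per fold on that fold's training portion
only, so no generated image can leak information about a test trial; an audit
trail records which real images each model saw. Generated counts are
``floor(ratio * n_train_real)``, balanced across the two classes.

Every (method, ratio, fold) cell derives an independent child seed from the
master seed by stable hashing, so cells are reproducible in isolation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .augment import AugmentConfig, augment_set
from .classifier import CNNTrainConfig, predict, train_cnn
from .generative import (
    GANTrainConfig,
    sample_autoencoder,
    sample_generated,
    train_autoencoder,
    train_dcgan,
)
from .metrics import DegenerateInputError, MetricReport, accuracy, kappa, one_way_anova, paired_ttest
from .preprocess import ImageSet
from .simulate import SimConfig

__all__ = [
    "FoldPlan",
    "ExperimentConfig",
    "make_folds",
    "generated_count",
    "build_fold_pools",
    "run_method",
    "ratio_sweep",
    "compare_methods",
    "audit_report",
    "child_seed",
    "LeakageError",
]

METHODS = ("none", "gt", "na", "ae", "vae", "dcgan")
DEFAULT_RATIOS = (1, 3, 5, 7, 9)


class LeakageError(RuntimeError):
    """Raised when the fold audit finds train/test contamination."""


@dataclass
class FoldPlan:
    """A stratified k-fold partition of real images.

    folds : list of (train_idx, test_idx) integer arrays; test sets are
    disjoint and cover every real image exactly once.
    """

    folds: list[tuple[np.ndarray, np.ndarray]]
    k: int
    seed: int

    def __iter__(self):
        return iter(self.folds)

    def __len__(self):
        return len(self.folds)


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed for a ratio sweep on synthetic data."""

    sim: SimConfig = SimConfig()
    methods: tuple[str, ...] = ("none", "dcgan")
    ratios: tuple[int, ...] = DEFAULT_RATIOS
    k_folds: int = 10
    master_seed: int = 0
    cnn: CNNTrainConfig = CNNTrainConfig()
    gan: GANTrainConfig = GANTrainConfig()
    augment: AugmentConfig = AugmentConfig()
    kappa_formula: str = "cohen"

    def __post_init__(self):
        if not self.methods:
            raise ValueError("need at least one method")
        unknown = set(self.methods) - set(METHODS)
        if unknown:
            raise ValueError(f"unknown methods {sorted(unknown)}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")


def child_seed(master: int, *parts) -> int:
    """Stable, independent sub-seed for a labelled cell (always < 2^31)."""
    tag = ":".join([str(master), *map(str, parts)])
    return zlib.crc32(tag.encode()) & 0x7FFFFFFF


def make_folds(images: ImageSet, k: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified k-fold plan over the real images."""
    labels = np.asarray(images.labels)
    if not np.all(np.asarray(images.provenance) == "real"):
        raise ValueError("fold plans must be built on real images only")
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(f"k={k} exceeds the smallest class count {counts.min()}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = [(np.asarray(tr), np.asarray(te))
             for tr, te in skf.split(np.zeros(len(labels)), labels)]
    return FoldPlan(folds, k, seed)


def generated_count(ratio: int, n_train_real: int) -> int:
    """GD pool size for one fold: floor(ratio * real-train count)."""
    return int(np.floor(ratio * n_train_real))


def _split_counts(n_needed: int, classes) -> dict:
    per_class = {c: n_needed // len(classes) for c in classes}
    for c in classes[: n_needed % len(classes)]:
        per_class[c] += 1
    return per_class


def _train_generative_models(method: str, train_images: ImageSet,
                             gan_config: GANTrainConfig, seed: int) -> dict:
    """One generative model per class, trained on ``train_images`` only."""
    models = {}
    for c in np.unique(np.asarray(train_images.labels)):
        cls_idx = np.flatnonzero(np.asarray(train_images.labels) == c)
        subset = train_images.subset(cls_idx)
        cfg = replace(gan_config, seed=child_seed(seed, method, str(c)))
        if method == "dcgan":
            models[str(c)] = train_dcgan(subset, cfg)
        else:
            models[str(c)] = train_autoencoder(method, subset, cfg)
    return models


def _sample_models(models: dict, method: str, n_needed: int, seed: int) -> ImageSet:
    classes = sorted(models)
    per_class = _split_counts(n_needed, classes)
    pieces = []
    for c in classes:
        if per_class[c] == 0:
            continue
        s = child_seed(seed, "sample", c)
        if method == "dcgan":
            pieces.append(sample_generated(models[c], per_class[c], c, seed=s))
        else:
            pieces.append(sample_autoencoder(models[c], per_class[c], c, seed=s))
    return ImageSet.concat(pieces)


def _train_generative(method: str, train_images: ImageSet, n_needed: int,
                      gan_config: GANTrainConfig, seed: int) -> ImageSet:
    """Fold-local generative training and sampling."""
    models = _train_generative_models(method, train_images, gan_config, seed)
    return _sample_models(models, method, n_needed, seed)


def build_fold_pools(images: ImageSet, plan: FoldPlan, method: str, ratio: int,
                     *, gan_config: GANTrainConfig = GANTrainConfig(),
                     augment_config: AugmentConfig = AugmentConfig(),
                     master_seed: int = 0,
                     train_generative_once: bool = False) -> list[dict]:
    """Assemble the per-fold training pools and audit records.

    Each element holds ``train`` (real + generated ImageSet), ``test_idx``,
    ``n_generated`` and ``model_train_idx`` (the real indices any generative or
    classical augmenter saw, for the leakage audit).

    ``train_generative_once=True`` trains the generative models a single time
    on the full real set instead of per fold — the looser reading of the
    protocol. Its samples leak test-trial information into training folds, so
    the audit flags it and must be told explicitly to accept it.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    shared_models = None
    if train_generative_once and method in ("ae", "vae", "dcgan"):
        shared_models = _train_generative_models(
            method, images, gan_config, child_seed(master_seed, method, "once"))
    pools = []
    for f, (train_idx, test_idx) in enumerate(plan):
        seed_f = child_seed(master_seed, method, ratio, f)
        real_train = images.subset(train_idx)
        n_gen = generated_count(ratio, len(train_idx)) if method != "none" else 0
        if n_gen > 0:
            if method in ("gt", "na"):
                gen = augment_set(real_train, method, n_gen, augment_config,
                                  seed=seed_f)
            elif shared_models is not None:
                gen = _sample_models(shared_models, method, n_gen, seed_f)
            else:
                gen = _train_generative(method, real_train, n_gen, gan_config,
                                        seed_f)
            train_pool = ImageSet.concat([real_train, gen])
        else:
            train_pool = real_train
        model_saw_all = shared_models is not None and n_gen > 0
        pools.append({
            "fold": f,
            "train": train_pool,
            "test_idx": test_idx,
            "train_idx": train_idx,
            "n_generated": n_gen,
            "model_train_idx": (np.arange(len(images)) if model_saw_all
                                else train_idx if method != "none"
                                else np.array([], int)),
            "seed": seed_f,
        })
    return pools


def audit_report(images: ImageSet, plan: FoldPlan, pools: list[dict],
                 ratio: int, method: str,
                 allow_generator_leakage: bool = False) -> list[dict]:
    """Walk every fold and verify the protocol invariants.

    Checks: test sets are disjoint, cover all real images, and contain only
    provenance=real images; generated counts equal floor(ratio*train size);
    no augmenter/generative model saw a test-fold image. Raises
    :class:`LeakageError` on any violation; returns per-fold audit dicts.
    """
    prov = np.asarray(images.provenance)
    all_test = np.concatenate([p["test_idx"] for p in pools])
    if len(np.unique(all_test)) != len(all_test):
        raise LeakageError("test folds overlap")
    if sorted(all_test.tolist()) != list(range(len(images))):
        raise LeakageError("test folds do not partition the real image set")
    records = []
    for p in pools:
        if not np.all(prov[p["test_idx"]] == "real"):
            raise LeakageError(f"fold {p['fold']}: non-real image in the test set")
        expected = generated_count(ratio, len(p["train_idx"])) if method != "none" else 0
        if p["n_generated"] != expected:
            raise LeakageError(
                f"fold {p['fold']}: generated count {p['n_generated']} != "
                f"floor(ratio*train) = {expected}"
            )
        overlap = np.intersect1d(p["model_train_idx"], p["test_idx"])
        if overlap.size and not allow_generator_leakage:
            raise LeakageError(
                f"fold {p['fold']}: augmentation model saw test images {overlap}"
            )
        records.append({
            "fold": p["fold"],
            "n_train_real": len(p["train_idx"]),
            "n_generated": p["n_generated"],
            "n_test": len(p["test_idx"]),
            "generator_leakage": bool(overlap.size),
        })
    return records


def run_method(images: ImageSet, method: str, ratio: int,
               plan: FoldPlan | None = None, *,
               cnn_config: CNNTrainConfig = CNNTrainConfig(),
               gan_config: GANTrainConfig = GANTrainConfig(),
               augment_config: AugmentConfig = AugmentConfig(),
               master_seed: int = 0, kappa_formula: str = "cohen",
               chance: float = 0.5,
               train_generative_once: bool = False) -> MetricReport:
    """Evaluate one (method, ratio) cell with k-fold CV; returns a MetricReport.

    ``method="none"`` is the no-augmentation baseline (the ratio is ignored).
    Generated images are used for training only, never for testing.
    ``train_generative_once`` opts into the looser shared-model protocol; the
    audit then records the leakage instead of rejecting it.
    """
    if plan is None:
        plan = make_folds(images, seed=master_seed)
    pools = build_fold_pools(images, plan, method, ratio, gan_config=gan_config,
                             augment_config=augment_config,
                             master_seed=master_seed,
                             train_generative_once=train_generative_once)
    audit = audit_report(images, plan, pools, ratio, method,
                         allow_generator_leakage=train_generative_once)
    accs, kappas = [], []
    for p in pools:
        cfg = replace(cnn_config, seed=p["seed"])
        model, _ = train_cnn(p["train"], cfg)
        test = images.subset(p["test_idx"])
        pred, _ = predict(model, test)
        acc = accuracy(pred, np.asarray(test.labels))
        accs.append(acc)
        kappas.append(kappa(acc, chance, kappa_formula))
    return MetricReport(method=method, ratio=ratio if method != "none" else 0,
                        fold_accuracies=accs, fold_kappas=kappas,
                        config={"master_seed": master_seed,
                                "k_folds": plan.k},
                        audit=audit)


def ratio_sweep(images: ImageSet, config: ExperimentConfig) -> pd.DataFrame:
    """One MetricReport per (method, ratio) cell plus the baseline, as tidy rows.

    Columns: method, ratio, fold, accuracy, kappa. The baseline (method
    ``none``) appears once with ratio 0 regardless of the ratio grid.
    """
    plan = make_folds(images, config.k_folds, seed=config.master_seed)
    rows = []

    def _add(report: MetricReport):
        for f, (acc, kap) in enumerate(zip(report.fold_accuracies,
                                           report.fold_kappas)):
            rows.append({"method": report.method, "ratio": report.ratio,
                         "fold": f, "accuracy": acc, "kappa": kap})

    if "none" in config.methods:
        _add(run_method(images, "none", 0, plan, cnn_config=config.cnn,
                        gan_config=config.gan, augment_config=config.augment,
                        master_seed=config.master_seed,
                        kappa_formula=config.kappa_formula))
    for method in config.methods:
        if method == "none":
            continue
        for ratio in config.ratios:
            _add(run_method(images, method, ratio, plan, cnn_config=config.cnn,
                            gan_config=config.gan,
                            augment_config=config.augment,
                            master_seed=config.master_seed,
                            kappa_formula=config.kappa_formula))
    return pd.DataFrame(rows)


def compare_methods(sweep: pd.DataFrame, reference: str = "dcgan") -> pd.DataFrame:
    """Significance report: ANOVA across methods plus paired t vs ``reference``.

    Each non-reference method is compared at its best ratio (highest mean
    accuracy) against the reference at its own best ratio. Degenerate cells
    (zero-variance differences) are flagged rather than failed.
    """
    methods = sweep["method"].unique().tolist()
    if reference not in methods:
        raise ValueError(f"reference method {reference!r} not in the sweep")

    def best_scores(method):
        sub = sweep[sweep["method"] == method]
        means = sub.groupby("ratio")["accuracy"].mean()
        best_ratio = means.idxmax()
        scores = sub[sub["ratio"] == best_ratio].sort_values("fold")["accuracy"]
        return int(best_ratio), scores.to_numpy()

    ref_ratio, ref_scores = best_scores(reference)
    rows = []
    groups = [best_scores(m)[1] for m in methods]
    try:
        f, p = one_way_anova(groups)
        rows.append({"comparison": "anova", "statistic": f, "p_value": p,
                     "note": f"{len(methods)} methods at best ratios"})
    except DegenerateInputError as err:
        rows.append({"comparison": "anova", "statistic": np.nan,
                     "p_value": np.nan, "note": f"degenerate: {err}"})
    for m in methods:
        if m == reference:
            continue
        m_ratio, m_scores = best_scores(m)
        name = f"{m}(1:{m_ratio}) vs {reference}(1:{ref_ratio})"
        try:
            t, p = paired_ttest(m_scores, ref_scores)
            rows.append({"comparison": name, "statistic": t, "p_value": p,
                         "note": ""})
        except DegenerateInputError as err:
            rows.append({"comparison": name, "statistic": np.nan,
                         "p_value": np.nan, "note": f"degenerate: {err}"})
    return pd.DataFrame(rows)
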