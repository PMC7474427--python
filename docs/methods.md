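# Methods

`miaug` implements a complete desk-scale version of a hybrid
augmentation-plus-classification workflow for two-class motor-imagery (MI)
EEG: simulate or load 3-channel trials, encode them as stacked spectrogram
images, augment the training pool with classical or generative methods, score
generated-image quality with a Fréchet distance, and evaluate a small CNN
under a leakage-audited 10-fold cross-validation protocol. This note records
the models, the defaults and why, and what the built-in evaluation does and
does not demonstrate.

## Signal model of the simulator

Motor imagery desynchronizes the mu (8–12 Hz) and beta (18–26 Hz) rhythms
over the contralateral sensorimotor cortex (ERD) and can enhance them
ipsilaterally (ERS). The simulator generates, per trial and channel,

    x(t) = a_ch * [ A_mu cos(2π f_mu t + φ) + A_beta cos(2π f_beta t + ψ) ]
           + σ n_1/f(t)

with `f_mu ~ U(8,12)`, `f_beta ~ U(18,26)` redrawn per trial, phases uniform
per channel (MI is an induced, non-phase-locked phenomenon, so trials must not
be phase-aligned), and `n_1/f` unit-variance 1/f-shaped noise obtained by
spectral shaping of white noise — a far better match to resting EEG spectra
than white noise. The lateral factor `a_ch` is `1 − erd_depth` at the
contralateral electrode, `1 + ers_gain` ipsilaterally, and 1 at Cz; the
convention is fixed (right-hand imagery attenuates C3, over the left motor
cortex) rather than configurable. Modulation is constant over the 4 s epoch;
a ramped ERD time course is deliberately out of scope because nothing
downstream resolves within-epoch dynamics.

Defaults: `fs=100 Hz`, `duration=4 s` (so 400 samples per trial; 1000 at
250 Hz), `A_mu=1`, `A_beta=0.5` (beta rhythms are weaker), `erd_depth=0.5`,
`ers_gain=0` (ERS is optional and off by default so the contralateral power
ratio has the clean closed form `(1 − erd_depth)²`), `noise_level=1`.
`bandpower` integrates the periodogram over a band and is the measurement
used to verify these contracts: with `erd_depth=0.5` and no noise the
contralateral/ipsilateral mu-power ratio is 0.25 by construction.

## Spectrogram images

Trials are band-passed 8–30 Hz with a zero-phase 4th-order Butterworth
(forward–backward application preserves event latencies; the order is a
conventional choice). Each channel is transformed with a Hann-window STFT —
window 128 samples at 100 Hz, 256 at 250 Hz, 50% overlap, trailing
zero-padding so every sample is covered — and only bins with
8 ≤ f ≤ 30 Hz are retained (28 bins for window 128 at 100 Hz). The three
magnitude matrices are stacked vertically in C3/Cz/C4 order so channel
adjacency is preserved, log-scaled (`log1p`; spectral energy spans orders of
magnitude), min–max normalized per image, mapped through a
perceptually-uniform colormap (viridis) to three planes, and bilinearly
resized to 64×64. Window taper, overlap, magnitude scaling, normalization
scope and colormap have no canonical values for this pipeline; all are
config-exposed, and the defaults above are the field-standard picks. Per-image
normalization was chosen over global normalization so images from different
subjects and sessions share the [0,1] range.

## Augmenters

Classical: a planar 180° rotation (an involution; a vertical-flip variant is
available behind a flag since "rotation about the x-axis" admits both
readings), a translation of at most `shift_max=8` px whose vacated pixels are
refilled with uniform noise, brightness/contrast jitter (±0.1 / ±10%), and
additive noise `x̃ = x + u·noise_scale` with `u ~ U(−0.5, 0.5)`, clipped to
[0,1]. The uniform form is the primary definition; a variance-matched
Gaussian variant is selectable. Shift and jitter magnitudes are exposed
guesses — no canonical values exist. Augmenters never touch labels or
subject metadata.

## Generative models

The DCGAN generator maps a 100-dim latent through a 4×4 stride-1 projection
to (1024,4,4), then four fractional-stride 3×3 deconvolutions with batch
normalization and ReLU, halving channels and doubling spatial size each step,
to a (3,64,64) tanh output. The first step is necessarily a projection: no
3×3 stride-2 deconvolution maps 1×1 to 4×4, so the standard DCGAN projection
idiom fills that slot. The discriminator is four stride-2 3×3 convolutions
(128→256→512→1024 channels at full width) with leaky-ReLU (0.2) and dropout
0.25, batch norm on the middle blocks, flattened (16384) to a sigmoid score.
`base_width` scales all channel counts together while preserving the
halving/doubling pattern; width 1024 is the reference configuration, smaller
widths make desk-scale training affordable.

Training: Adam (lr 2e-4, β₁=0.5 — the GAN-stable choice — β₂=0.999), batch
128 clamped to the dataset size (a 180-image training split cannot fill the
nominal batch), 20 epochs, batch-norm momentum 0.8. The discriminator loss is
the binary cross-entropy with real labels 1 and fake labels 0; the generator
trains on the non-saturating −log D(G(z)) rather than log(1−D(G(z))), the
standard remedy for vanishing early gradients (the minimax value is still
what `gan_losses` reports). One generator step follows each discriminator
step. Models are trained per class (and per subject), so samples inherit an
unambiguous label; conditioning would change the reference architecture.

The AE mirrors the discriminator's convolutional stack into a deterministic
100-dim bottleneck and decodes with the generator architecture; since a plain
AE has no sampling prior, sampling perturbs encoded training latents with
spherical noise (0.25 × per-dimension latent spread). The VAE adds a
mean/log-variance head and a KL term to N(0, I) (weight 1e-3 against the
pixel MSE — reconstruction must dominate at these tiny data sizes) and
samples latents from the prior.

## Metrics

Generated-image quality: `FID(r,g) = ‖μr−μg‖² + Tr(Σr+Σg−2(ΣrΣg)^{1/2})`,
the squared Wasserstein-2 distance between Gaussian fits. The matrix square
root is `scipy.linalg.sqrtm` with a 1e-6 diagonal jitter; covariances use the
unbiased estimator. The feature embedder is pluggable: the default is
flatten+PCA (dimension ≤ 64, fit on the real set so both sides share one
projection) — deterministic and self-contained; a fixed-seed random CNN trunk
is an alternative; an Inception-style pretrained embedder id is recognised
but requires external network weights, so it raises with an explanation. The
formula is embedder-agnostic, and all distance properties (symmetry,
non-negativity, zero on identical sets) are tested independently of the
embedder.

Classification: accuracy and chance-corrected kappa at chance 0.5 (balanced
two-class MI). Two kappa normalisations are exposed — Cohen's
`(acc−chance)/(1−chance)`, the default, and the variant `(acc−chance)/chance` (`formula="ratio"`)
— because both appear in the MI-BCI literature and they disagree everywhere
except at chance. Significance: two-sided paired t-test on per-fold scores
and classical one-way ANOVA, both via scipy, with explicit degenerate-input
errors when fold differences have zero variance (common at desk scale where
fold accuracies saturate); comparison reports flag such cells rather than
failing.

## Evaluation protocol

Real images are split with stratified 10-fold CV. Per fold, the training pool
is the 90% real portion plus `floor(ratio × n_train_real)` generated images
(balanced across classes, remainder to the first class), with
ratio ∈ {1,3,5,7,9}; the held-out 10% — always and only real images — is the
test set. Generative models are retrained inside each fold on that fold's
training portion only. This is stricter than training one model on all data,
and it is what makes the leakage audit enforceable (an explicit
``train_generative_once`` escape hatch reproduces the looser shared-model
protocol; the audit then records the resulting leakage per fold instead of
rejecting the plan). The audit walks every fold and verifies that test sets are disjoint, cover the real set, contain
only real images, that generated counts match the floor rule, and that no
augmentation model saw a test image. Every (method, ratio, fold) cell derives
its seed from the master seed by CRC-32 hashing of the cell label, so any
cell is reproducible in isolation. Sweep output is a tidy per-fold table;
`compare_methods` adds the ANOVA across methods and paired t-tests of each
method against the DCGAN at best ratios.

## Built-in reference experiments (`miaug.benchmarks`)

All self-contained evaluation runs use the simulator and scaled-down
schedules chosen to keep a full run in the minutes range on one CPU; the
architecture shapes and the protocol are never scaled.

* **Classifier sanity** — 100 trials/class at noise 0.3 ("high SNR": the
  oscillations dominate the 8–30 Hz band), reference 8-filter CNN trained 20 epochs at lr 3e-3 with momentum 0.9, 10-fold CV.
* **Augmentation benefit** — 40 trials/class at noise 2.0 ("moderate SNR":
  in-band background power comparable to the rhythms, so the baseline sits
  clearly below ceiling), DCGAN at ratio 1:3 versus the no-augmentation
  baseline, five independent master seeds. The fold-wise GANs use width 32,
  batch 12, 30 epochs at Adam lr 1e-3 — the higher rate compensates for the
  few optimizer steps a 36-image split permits.
* **GAN progress** — one class of moderate-SNR spectrograms (36 train / 24
  held out), width-64 DCGAN, Fréchet distance of samples to the held-out
  split after epoch 1 versus the final epoch, five seeds.
* **Statistical calibration** — 1000 null simulations of 10-fold score
  vectors through the package's own paired t-test and ANOVA.

## What the synthetic evaluation shows — and does not

The simulator reproduces the one property the pipeline is built around:
class-dependent, lateralized band-power differences on a realistic 1/f
background. It deliberately omits volume conduction, ocular/muscular
artifacts, inter-subject variability, session drift and ERD time courses.
Passing tests therefore demonstrate that the machinery is correct and that
the protocol is leak-free — that filtering, spectrogram encoding, the
networks, the distance and the CV plumbing do what they claim on data whose
ground truth is known. They do not certify classification accuracy or
augmentation gains on recorded EEG, where feature distributions are far less
Gaussian and less stationary than anything simulated here.

## Numerical choices and edge cases

* All network math is float32; gradient checks run the same layers in
  float64 against central differences (≤1e-4 relative).
* Cross-entropies clip probabilities at 1e-12 before logs.
* Min–max image normalization defines 0/0 (a constant spectrogram) as 0, so
  an all-zero trial renders as the colormap's zero colour.
* `sqrtm` products are symmetrized by the diagonal jitter; tiny negative
  distances from rounding are possible at the 1e-8 level and tolerated.
* Batch sizes are clamped to the dataset; a training split smaller than one
  batch still performs one step per epoch.
* Max-pool gradient routes to the first argmax on exact ties.
* Generated counts use floor(ratio × n); remainders are dropped, and the
  per-class split gives any odd image to the first class.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; full-width (1024) GAN
  training is architecture-conformant but impractical to train at length on
  one CPU — scaled widths are the intended desk configuration.
* The AE sampling scheme (latent perturbation) has no probabilistic
  guarantee; it is the pragmatic choice for a model class without a prior.
* EDF/GDF reading requires the optional `mne` dependency and real recording
  files; it is untested against the public benchmark archives inside this
  repository.
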