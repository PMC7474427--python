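"""Classical (non-generative) augmenters for spectrogram images.

Three geometric operators — a planar 180° rotation, a translation whose
vacated pixels are refilled with uniform noise, and a brightness/contrast
jitter — plus additive noise following

    x~ = x + random(-0.5, 0.5) * noise_scale

with the perturbed image clipped back to [0, 1]. Labels and subject metadata
are never touched; outputs carry provenance ``gt`` or ``na``.

The uniform draw above is implemented as printed even though such noise is
often described as Gaussian; a ``distribution="gaussian"`` switch (matched
variance) is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import IMAGE_SIZE, ImageSet, SpectrogramImage

__all__ = ["AugmentConfig", "gt_rotate", "gt_shift", "gt_color", "noise_addition",
           "augment_set"]


@dataclass(frozen=True)
class AugmentConfig:
    """Knobs for the classical augmenters.

    shift_max : largest |dx|,|dy| translation in pixels (< 64).
    noise_scale : the multiplier of the uniform(-0.5, 0.5) perturbation.
    brightness / contrast : half-widths of the jitter ranges for ``gt_color``.
    """

    shift_max: int = 8
    noise_scale: float = 0.2
    brightness: float = 0.1
    contrast: float = 0.1
    na_distribution: str = "uniform"
    rotate_mode: str = "planar"  # or "vertical-flip"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.shift_max < IMAGE_SIZE:
            raise ValueError("shift_max must be in [0, 64)")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")
        if self.na_distribution not in ("uniform", "gaussian"):
            raise ValueError("na_distribution must be 'uniform' or 'gaussian'")
        if self.rotate_mode not in ("planar", "vertical-flip"):
            raise ValueError("rotate_mode must be 'planar' or 'vertical-flip'")


def _with_pixels(image: SpectrogramImage, pixels: np.ndarray,
                 provenance: str) -> SpectrogramImage:
    return SpectrogramImage(pixels, image.label, provenance, image.subject_id)


def gt_rotate(image: SpectrogramImage, mode: str = "planar") -> SpectrogramImage:
    """180° rotation (an involution): pixel (r, c) maps to (63-r, 63-c).

    ``mode="vertical-flip"`` instead mirrors rows only, the alternative reading
    of a 180° turn "on the x-axis".
    """
    if mode == "planar":
        pixels = image.pixels[::-1, ::-1, :].copy()
    elif mode == "vertical-flip":
        pixels = image.pixels[::-1, :, :].copy()
    else:
        raise ValueError("mode must be 'planar' or 'vertical-flip'")
    return _with_pixels(image, pixels, "gt")


def gt_shift(image: SpectrogramImage, dx: int, dy: int,
             rng: np.random.Generator, shift_max: int = 8) -> SpectrogramImage:
    """Translate by (dx, dy) pixels; vacated rows/columns get uniform noise.

    dx > 0 moves content right, dy > 0 moves it down.
    """
    if abs(dx) > shift_max or abs(dy) > shift_max:
        raise ValueError(f"|dx|,|dy| must be <= shift_max ({shift_max})")
    pixels = rng.random(image.pixels.shape)
    src = image.pixels
    h = w = IMAGE_SIZE

    def _ranges(d, size):
        if d >= 0:
            return slice(d, size), slice(0, size - d)
        return slice(0, size + d), slice(-d, size)

    dst_r, src_r = _ranges(dy, h)
    dst_c, src_c = _ranges(dx, w)
    pixels[dst_r, dst_c, :] = src[src_r, src_c, :]
    return _with_pixels(image, pixels, "gt")


def gt_color(image: SpectrogramImage, rng: np.random.Generator,
             brightness: float = 0.1, contrast: float = 0.1) -> SpectrogramImage:
    """Brightness/contrast jitter in colour space, clipped to [0, 1].

    Applies ``(x - 0.5) * (1 + c) + 0.5 + b`` with b ~ U(-brightness,
    brightness) and c ~ U(-contrast, contrast).
    """
    b = rng.uniform(-brightness, brightness)
    c = rng.uniform(-contrast, contrast)
    pixels = np.clip((image.pixels - 0.5) * (1.0 + c) + 0.5 + b, 0.0, 1.0)
    return _with_pixels(image, pixels, "gt")


def noise_addition(image: SpectrogramImage, noise_scale: float,
                   rng: np.random.Generator,
                   distribution: str = "uniform") -> SpectrogramImage:
    """Per-pixel additive noise ``x + u * noise_scale``, clipped to [0, 1].

    ``u`` is uniform on (-0.5, 0.5) by default, so the unclipped perturbation
    is bounded by ``0.5 * noise_scale``; the Gaussian variant matches the
    uniform variance (sd = noise_scale / sqrt(12)).
    """
    if noise_scale < 0:
        raise ValueError("noise_scale must be >= 0")
    if distribution == "uniform":
        u = rng.uniform(-0.5, 0.5, size=image.pixels.shape)
        perturbed = image.pixels + u * noise_scale
    elif distribution == "gaussian":
        perturbed = image.pixels + rng.normal(
            0.0, noise_scale / np.sqrt(12.0), size=image.pixels.shape
        )
    else:
        raise ValueError("distribution must be 'uniform' or 'gaussian'")
    return _with_pixels(image, np.clip(perturbed, 0.0, 1.0), "na")


def augment_set(images: ImageSet, method: str, n: int, config: AugmentConfig,
                seed: int | None = None) -> ImageSet:
    """Produce ``n`` augmented copies by cycling over ``images``.

    ``method`` is ``"gt"`` (a uniformly random choice among rotation, shift and
    colour jitter per copy) or ``"na"``. Deterministic given the seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if len(images) == 0:
        raise ValueError("cannot augment an empty image set")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for i in range(n):
        src = images[i % len(images)]
        if method == "gt":
            op = rng.integers(3)
            if op == 0:
                out.append(gt_rotate(src, config.rotate_mode))
            elif op == 1:
                dx, dy = rng.integers(-config.shift_max, config.shift_max + 1, size=2)
                out.append(gt_shift(src, int(dx), int(dy), rng, config.shift_max))
            else:
                out.append(gt_color(src, rng, config.brightness, config.contrast))
        elif method == "na":
            out.append(noise_addition(src, config.noise_scale, rng,
                                      config.na_distribution))
        else:
            raise ValueError("method must be 'gt' or 'na'")
    result = ImageSet.from_images(out)
    result.subject_id = images.subject_id
    return result
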