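"""Training-set augmentation: gamma, rotation, blur, noise, flips.

The recipe is a fixed list of single-transform variants and must total
exactly 12 outputs per input image (the expansion factor the training
protocol is built around).  Geometric transforms (rotation, flip) are
applied identically to image and mask — the mask with nearest-neighbor
resampling so labels stay in {0,1,2}; photometric transforms (gamma, blur,
noise) touch the image only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthetic import LabeledImage

__all__ = ["AugmentConfig", "augment_pair", "AugmentConfigError"]


class AugmentConfigError(ValueError):
    """The configured recipe does not produce exactly 12 variants."""


@dataclass(frozen=True)
class AugmentConfig:
    """Default recipe: 3 gammas + 3 rotations + 2 blurs + 2 noise draws
    + 2 flips = 12 variants (originals are kept separately by the caller)."""

    gamma_values: tuple = (0.7, 1.3, 1.6)
    rotation_degrees: tuple = (-10.0, 10.0, 180.0)
    blur_sigmas: tuple = (1.0, 2.0)
    noise_sigmas: tuple = (5.0, 10.0)
    flips: tuple = ("horizontal", "vertical")
    seed: int = 0

    def __post_init__(self):
        bad = set(self.flips) - {"horizontal", "vertical"}
        if bad:
            raise AugmentConfigError(f"unknown flip direction(s): {sorted(bad)}")
        if self.count() != 12:
            raise AugmentConfigError(
                f"augmentation recipe yields {self.count()} variants; the "
                "training protocol requires exactly 12 per input")

    def count(self) -> int:
        return (len(self.gamma_values) + len(self.rotation_degrees)
                + len(self.blur_sigmas) + len(self.noise_sigmas)
                + len(self.flips))


def _gamma(image: np.ndarray, gamma: float) -> np.ndarray:
    out = 255.0 * (image.astype(float) / 255.0) ** gamma
    return np.round(out).astype(np.uint8)


def _rotate_pair(image, mask, angle):
    if angle % 360 == 180:  # exact, no interpolation
        return image[::-1, ::-1].copy(), mask[::-1, ::-1].copy()
    img = ndimage.rotate(image, angle, reshape=False, order=1, mode="constant",
                         cval=0)
    msk = ndimage.rotate(mask, angle, reshape=False, order=0, mode="constant",
                         cval=0)
    return np.clip(np.round(img), 0, 255).astype(np.uint8), msk.astype(np.uint8)


def _flip_pair(image, mask, direction):
    if direction == "horizontal":
        return image[:, ::-1].copy(), mask[:, ::-1].copy()
    return image[::-1, :].copy(), mask[::-1, :].copy()


def augment_pair(item: LabeledImage,
                 config: AugmentConfig = AugmentConfig()) -> list[LabeledImage]:
    """Produce the 12 augmented variants of one labeled image."""
    rng = np.random.default_rng(config.seed)
    img, mask = item.image, item.mask
    out: list[LabeledImage] = []

    def emit(i, m, tag):
        out.append(LabeledImage(image=i, mask=m, style_name=item.style_name,
                                true_loss_rate=item.true_loss_rate,
                                image_id=f"{item.image_id}_{tag}" if item.image_id else tag))

    for g in config.gamma_values:
        emit(_gamma(img, g), mask.copy(), f"gamma{g}")
    for a in config.rotation_degrees:
        ri, rm = _rotate_pair(img, mask, a)
        emit(ri, rm, f"rot{a}")
    for s in config.blur_sigmas:
        blurred = ndimage.gaussian_filter(img.astype(float), sigma=s)
        emit(np.clip(np.round(blurred), 0, 255).astype(np.uint8), mask.copy(),
             f"blur{s}")
    for s in config.noise_sigmas:
        noisy = img.astype(float) + rng.normal(0.0, s, size=img.shape)
        emit(np.clip(np.round(noisy), 0, 255).astype(np.uint8), mask.copy(),
             f"noise{s}")
    for d in config.flips:
        fi, fm = _flip_pair(img, mask, d)
        emit(fi, fm, f"flip-{d[0]}")
    return out
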