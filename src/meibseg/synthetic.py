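"""Synthetic meibography phantoms.

Real meibography shows the everted eyelid as a bright band in which healthy
meibomian glands appear as elongated, roughly parallel bright stripes running
from the lid margin toward the proximal tarsal plate.  Gland atrophy
("dropout") removes the distal portion of the stripes, exposing bare eyelid.
The generator reproduces exactly this geometry — an elliptical-band eyelid
filled with sinusoidally wavy vertical stripes — together with a three-class
label mask (0 background, 1 eyelid, 2 gland) and a controllable atrophy
fraction realized by distal truncation of each stripe.

Two built-in :class:`DeviceStyle` renderings ("deviceA", "deviceB") emulate
acquisition by two different instruments: identical geometry, but distinct
tone curves, base brightness, contrast, vignetting and noise, giving the two
populations clearly separated grayscale histograms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomSpec", "DeviceStyle", "LabeledImage", "builtin_style",
           "generate_phantom", "generate_dataset", "style_histogram_gap",
           "default_spec_sampler"]

BACKGROUND, EYELID, GLAND = 0, 1, 2


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and noise parameters of one phantom.

    atrophy_frac is the *target* Eq.-style MG loss rate
    (1 − gland area / eyelid area) of the generated mask.
    """

    height: int = 192
    width: int = 256
    n_glands: int = 12
    gland_width_frac: float = 0.98
    atrophy_frac: float = 0.0
    eyelid_curvature: float = 0.25
    noise_sigma: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.height < 64 or self.width < 64:
            raise ValueError("phantom dimensions must be at least 64x64")
        if not 0.0 <= self.atrophy_frac <= 1.0:
            raise ValueError("atrophy_frac must lie in [0, 1]")
        if self.n_glands < 1:
            raise ValueError("n_glands must be >= 1")
        if not 0.0 < self.gland_width_frac < 1.0:
            raise ValueError("gland_width_frac must lie in (0, 1)")


@dataclass(frozen=True)
class DeviceStyle:
    """Photometric rendering emulating one acquisition device."""

    name: str
    tone_curve: np.ndarray = field(repr=False)  # uint8 LUT, monotone
    base_intensity: float = 0.0
    contrast_gain: float = 1.0
    vignette_strength: float = 0.0
    noise_sigma: float = 0.0

    def __post_init__(self):
        lut = np.asarray(self.tone_curve)
        if lut.shape != (256,):
            raise ValueError("tone_curve must have 256 entries")
        if np.any(np.diff(lut.astype(np.int64)) < 0):
            raise ValueError("tone_curve must be monotone non-decreasing")
        object.__setattr__(self, "tone_curve", lut.astype(np.uint8))


@dataclass
class LabeledImage:
    """An 8-bit intensity image with its aligned {0,1,2} label mask."""

    image: np.ndarray
    mask: np.ndarray
    style_name: str = ""
    true_loss_rate: float = float("nan")
    image_id: str = ""

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask dimensions differ")
        if not set(np.unique(self.mask)).issubset({0, 1, 2}):
            raise ValueError("mask values must lie in {0, 1, 2}")


def _gamma_lut(gamma: float) -> np.ndarray:
    x = np.arange(256) / 255.0
    return np.round(255.0 * x**gamma).astype(np.uint8)


def builtin_style(name: str) -> DeviceStyle:
    """Two stock device renderings with strongly different histograms.

    "deviceA" plays the internal-device role (bright, high contrast);
    "deviceB" the external one (darker, compressed tone scale, vignetted).
    """
    if name == "deviceA":
        return DeviceStyle(name="deviceA", tone_curve=_gamma_lut(0.85),
                           base_intensity=10.0, contrast_gain=1.15,
                           vignette_strength=0.05, noise_sigma=3.0)
    if name == "deviceB":
        return DeviceStyle(name="deviceB", tone_curve=_gamma_lut(1.6),
                           base_intensity=-15.0, contrast_gain=0.7,
                           vignette_strength=0.35, noise_sigma=5.0)
    raise ValueError(f"unknown builtin style {name!r}")


def _eyelid_band(spec: PhantomSpec, rng: np.random.Generator):
    """Boolean eyelid mask plus per-column top/bottom row bounds."""
    h, w = spec.height, spec.width
    x = np.linspace(-1.0, 1.0, w)
    mid = h / 2.0
    half = h * (0.30 + 0.04 * rng.uniform(-1, 1))
    bow = spec.eyelid_curvature * h * 0.5
    top = mid - half + bow * x**2
    bottom = mid + half - bow * x**2 * 0.6
    rows = np.arange(h)[:, None]
    band = (rows >= top[None, :]) & (rows <= bottom[None, :])
    return band, top, bottom


def _paint_glands(spec: PhantomSpec, band, top, bottom, rng):
    """Label gland stripes inside the band; returns the {0,1,2} mask."""
    h, w = spec.height, spec.width
    mask = np.where(band, EYELID, BACKGROUND).astype(np.uint8)
    cols = np.arange(w, dtype=float)
    rows = np.arange(h, dtype=float)[:, None]
    spacing = w / spec.n_glands
    half_width = 0.5 * spacing * spec.gland_width_frac
    # shared sinusoidal tortuosity: parallel glands drift together with depth,
    # which preserves inter-gland spacing (and hence gland coverage) exactly
    amp = rng.uniform(0.05, 0.15) * spacing
    freq = rng.uniform(1.0, 2.5)
    phase = rng.uniform(0, 2 * np.pi)
    offset = amp * np.sin(2 * np.pi * freq * rows / h + phase)
    gland_cols = []
    for g in range(spec.n_glands):
        center = (g + 0.5) * spacing
        inside = np.abs(cols[None, :] - (center + offset)) <= half_width
        stripe = inside & band
        mask[stripe] = GLAND
        gland_cols.append(stripe)
    return mask, gland_cols


def _apply_atrophy(mask: np.ndarray, gland_stripes, target_rate: float):
    """Truncate the distal (top) part of each stripe so the realized Eq.-style
    loss rate matches ``target_rate``; truncated pixels revert to eyelid."""
    eyelid_area = int(np.count_nonzero(mask > 0))
    gland_area = int(np.count_nonzero(mask == GLAND))
    if eyelid_area == 0 or gland_area == 0:
        return mask
    wanted_gland = (1.0 - target_rate) * eyelid_area
    to_remove = gland_area - wanted_gland
    if to_remove <= 0:
        return mask
    frac = min(1.0, to_remove / gland_area)
    for stripe in gland_stripes:
        stripe_now = stripe & (mask == GLAND)
        per_row = stripe_now.sum(axis=1)
        total = per_row.sum()
        if total == 0:
            continue
        cum = np.cumsum(per_row)
        n_cut = frac * total
        cut_row = int(np.searchsorted(cum, n_cut))
        mask[:cut_row][stripe_now[:cut_row]] = EYELID
        # partial row: remove leftover pixels from that row, left to right
        removed = int(cum[cut_row - 1]) if cut_row > 0 else 0
        leftover = int(round(n_cut)) - removed
        if leftover > 0 and cut_row < mask.shape[0]:
            idx = np.flatnonzero(stripe_now[cut_row])[:leftover]
            mask[cut_row, idx] = EYELID
    return mask


def _render(mask: np.ndarray, spec: PhantomSpec, style: DeviceStyle,
            rng: np.random.Generator) -> np.ndarray:
    """Turn a label mask into an 8-bit image in the given device style."""
    h, w = mask.shape
    base = np.empty((h, w), dtype=float)
    base[mask == BACKGROUND] = 35.0
    base[mask == EYELID] = 110.0
    base[mask == GLAND] = 185.0
    # mild smooth illumination texture so the phantom is not piecewise-flat
    yy, xx = np.mgrid[0:h, 0:w]
    texture = 8.0 * np.sin(2 * np.pi * xx / w * rng.uniform(1, 3)) \
        * np.cos(2 * np.pi * yy / h * rng.uniform(1, 2))
    img = base + texture + rng.normal(0.0, spec.noise_sigma, size=(h, w))
    # device photometry: contrast about mid-gray, offset, tone curve, vignette
    img = 128.0 + style.contrast_gain * (img - 128.0) + style.base_intensity
    img = np.clip(img, 0, 255)
    img = style.tone_curve[img.astype(np.uint8)].astype(float)
    if style.vignette_strength:
        ry = (yy - h / 2.0) / (h / 2.0)
        rx = (xx - w / 2.0) / (w / 2.0)
        img *= 1.0 - style.vignette_strength * (rx**2 + ry**2) / 2.0
    if style.noise_sigma:
        img += rng.normal(0.0, style.noise_sigma, size=(h, w))
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def generate_phantom(spec: PhantomSpec, style: DeviceStyle) -> LabeledImage:
    """Generate one labeled phantom; deterministic for a fixed spec seed.

    The mask's realized loss rate (1 − gland/eyelid area) matches
    ``spec.atrophy_frac`` up to pixel rounding.  Gland pixels are brighter
    than the surrounding eyelid before noise is added.
    """
    geom_rng = np.random.default_rng(spec.seed)
    band, top, bottom = _eyelid_band(spec, geom_rng)
    mask, stripes = _paint_glands(spec, band, top, bottom, geom_rng)
    mask = _apply_atrophy(mask, stripes, spec.atrophy_frac)
    eyelid_area = int(np.count_nonzero(mask > 0))
    gland_area = int(np.count_nonzero(mask == GLAND))
    rate = 1.0 - gland_area / eyelid_area if eyelid_area else float("nan")
    image = _render(mask, spec, style, geom_rng)
    return LabeledImage(image=image, mask=mask, style_name=style.name,
                        true_loss_rate=rate)


def _derive_seed(master_seed: int, index: int) -> int:
    """Stable per-item seed from a master seed and a counter (order-free)."""
    digest = hashlib.sha256(f"{master_seed}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31 - 1)


def default_spec_sampler(rng: np.random.Generator, **overrides) -> PhantomSpec:
    """Draw a random spec: atrophy uniform in [0, 0.85], mild geometry jitter."""
    params = dict(
        n_glands=int(rng.integers(9, 15)),
        atrophy_frac=float(rng.uniform(0.0, 0.85)),
        eyelid_curvature=float(rng.uniform(0.15, 0.35)),
        noise_sigma=float(rng.uniform(3.0, 6.0)),
    )
    params.update(overrides)
    return PhantomSpec(**params)


def generate_dataset(n: int, spec_sampler, style: DeviceStyle,
                     seed: int) -> list[LabeledImage]:
    """Generate ``n`` phantoms; per-image seeds are hashed from ``seed`` and
    the item index, so the collection is reproducible and order-independent.

    ``spec_sampler(rng) -> PhantomSpec`` draws the geometry; pass
    :func:`default_spec_sampler` (or ``None``) for the stock distribution.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sampler = spec_sampler or default_spec_sampler
    out = []
    for i in range(n):
        item_seed = _derive_seed(seed, i)
        rng = np.random.default_rng(item_seed)
        spec = replace(sampler(rng), seed=item_seed)
        item = generate_phantom(spec, style)
        item.image_id = f"{style.name}_{seed}_{i:04d}"
        out.append(item)
    return out


def style_histogram_gap(set_a, set_b) -> float:
    """L1 distance between the two sets' average normalized histograms.

    0 for identical populations, 2 for disjoint intensity supports.
    """
    if not len(set_a) or not len(set_b):
        raise ValueError("both image sets must be non-empty")

    def avg_hist(items):
        hists = []
        for it in items:
            img = it.image if isinstance(it, LabeledImage) else np.asarray(it)
            h = np.bincount(img.ravel(), minlength=256).astype(float)
            hists.append(h / h.sum())
        return np.mean(hists, axis=0)

    return float(np.abs(avg_hist(set_a) - avg_hist(set_b)).sum())
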