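"""Histogram specification and CLAHE for 8-bit meibography images.

Two preprocessing operators are provided:

* **Histogram specification (HS)** — remaps an image's gray levels so its
  histogram matches a 256-bin template built by averaging the normalized
  histograms of a reference image population (the "internal" device set).
  The mapping composes the image's empirical CDF with the generalized
  inverse of the template CDF and is returned explicitly as a monotone LUT.

* **CLAHE** — contrast-limited adaptive histogram equalization: the image is
  divided into tiles, each tile's histogram is clipped at a multiple of the
  mean bin height (excess redistributed uniformly), a per-tile equalization
  LUT is built from the clipped CDF, and per-pixel outputs bilinearly
  interpolate between the four surrounding tile LUTs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HistogramTemplate", "IntensityMapping", "CLAHEParams",
           "average_histogram", "specify_histogram", "clahe", "to_uint8"]


def to_uint8(image: np.ndarray) -> np.ndarray:
    """Coerce an input image to 2-D uint8.

    Color inputs are collapsed with luma weights; 16-bit/float inputs are
    rescaled to the full 8-bit range.
    """
    img = np.asarray(image)
    if img.ndim == 3:
        img = img[..., :3] @ np.array([0.299, 0.587, 0.114])
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.dtype == np.uint8:
        return img
    img = img.astype(float)
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = (img - lo) / (hi - lo) * 255.0
    return np.round(img).astype(np.uint8)


@dataclass(frozen=True)
class HistogramTemplate:
    """256-bin average intensity distribution of an image population."""

    bins: np.ndarray
    source_set: str = ""
    n_images: int = 0

    def __post_init__(self):
        b = np.asarray(self.bins, dtype=float)
        if b.shape != (256,):
            raise ValueError("template must have 256 bins")
        if np.any(b < 0):
            raise ValueError("template bins must be non-negative")
        if abs(b.sum() - 1.0) > 1e-9:
            raise ValueError("template bins must sum to 1")
        object.__setattr__(self, "bins", b)

    def cdf(self) -> np.ndarray:
        return np.cumsum(self.bins)

    def save(self, path) -> None:
        np.savetxt(path, self.bins, fmt="%.12e",
                   header=f"source_set={self.source_set} n_images={self.n_images}")

    @classmethod
    def load(cls, path) -> "HistogramTemplate":
        bins = np.loadtxt(path)
        return cls(bins=bins / bins.sum())


@dataclass(frozen=True)
class IntensityMapping:
    """A monotone gray-level LUT {0..255} -> {0..255}."""

    lut: np.ndarray

    def __post_init__(self):
        lut = np.asarray(self.lut)
        if lut.shape != (256,):
            raise ValueError("lut must have 256 entries")
        if np.any(np.diff(lut.astype(np.int64)) < 0):
            raise ValueError("lut must be monotone non-decreasing")
        object.__setattr__(self, "lut", lut.astype(np.uint8))

    def apply(self, image: np.ndarray) -> np.ndarray:
        return self.lut[to_uint8(image)]


@dataclass(frozen=True)
class CLAHEParams:
    tile_size: int = 64
    clip_limit: float = 2.0

    def __post_init__(self):
        if self.tile_size < 8:
            raise ValueError("tile_size must be >= 8")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be positive")


def _normalized_hist(image: np.ndarray) -> np.ndarray:
    h = np.bincount(image.ravel(), minlength=256).astype(float)
    return h / h.sum()


def average_histogram(images, source_set: str = "") -> HistogramTemplate:
    """Average the per-image normalized 256-bin histograms of a population."""
    images = list(images)
    if not images:
        raise ValueError("need at least one image to build a template")
    hists = []
    for img in images:
        img = np.asarray(getattr(img, "image", img))
        if img.dtype != np.uint8:
            raise TypeError("histogram template requires 8-bit images")
        hists.append(_normalized_hist(img))
    bins = np.mean(hists, axis=0)
    return HistogramTemplate(bins=bins / bins.sum(), source_set=source_set,
                             n_images=len(images))


def specify_histogram(image: np.ndarray, template: HistogramTemplate):
    """Histogram specification: match ``image`` to ``template``.

    Each input level v maps to the smallest target level t with
    templateCDF(t) >= imageCDF(v); ties break toward the smallest level.
    Returns the remapped image and the LUT as an :class:`IntensityMapping`.
    """
    image = to_uint8(image)
    src_cdf = np.cumsum(_normalized_hist(image))
    tgt_cdf = template.cdf()
    # guard against floating error at the top of the CDF
    tgt_cdf = np.minimum(tgt_cdf / tgt_cdf[-1], 1.0)
    # the 1e-12 slack keeps the inversion stable when source and target CDFs
    # agree up to floating-point rounding (e.g. self-specification)
    lut = np.searchsorted(tgt_cdf, np.minimum(src_cdf, 1.0) - 1e-12,
                          side="left")
    lut = np.minimum(lut, 255).astype(np.uint8)
    mapping = IntensityMapping(lut=np.maximum.accumulate(lut))
    return mapping.apply(image), mapping


def _equalize_lut(hist: np.ndarray) -> np.ndarray:
    """Equalization LUT from a (possibly clipped) histogram: round(255·CDF)."""
    total = hist.sum()
    if total == 0:
        return np.arange(256, dtype=np.uint8)
    cdf = np.cumsum(hist) / total
    return np.round(255.0 * cdf).astype(np.uint8)


def clahe(image: np.ndarray, params: CLAHEParams = CLAHEParams()) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    The clip threshold is ``clip_limit`` times the mean tile bin height;
    clipped excess is redistributed uniformly over all 256 bins.  A constant
    image is returned unchanged (equalizing a single-bin histogram is
    ill-defined).
    """
    image = to_uint8(image)
    h, w = image.shape
    ts = params.tile_size
    if ts > min(h, w):
        raise ValueError("tile_size exceeds image dimensions")
    if image.min() == image.max():
        return image.copy()
    ny, nx = max(1, round(h / ts)), max(1, round(w / ts))
    y_edges = np.linspace(0, h, ny + 1).astype(int)
    x_edges = np.linspace(0, w, nx + 1).astype(int)
    luts = np.empty((ny, nx, 256), dtype=np.uint8)
    for i in range(ny):
        for j in range(nx):
            tile = image[y_edges[i]:y_edges[i + 1], x_edges[j]:x_edges[j + 1]]
            hist = np.bincount(tile.ravel(), minlength=256).astype(float)
            clip = params.clip_limit * tile.size / 256.0
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / 256.0
            luts[i, j] = _equalize_lut(hist)
    centers_y = (y_edges[:-1] + y_edges[1:]) / 2.0
    centers_x = (x_edges[:-1] + x_edges[1:]) / 2.0

    # bilinear interpolation between the four surrounding tile LUTs
    yy = np.arange(h, dtype=float)
    xx = np.arange(w, dtype=float)
    iy = np.clip(np.searchsorted(centers_y, yy) - 1, 0, max(ny - 2, 0))
    ix = np.clip(np.searchsorted(centers_x, xx) - 1, 0, max(nx - 2, 0))
    if ny > 1:
        wy = (yy - centers_y[iy]) / (centers_y[iy + 1] - centers_y[iy])
        wy = np.clip(wy, 0.0, 1.0)
    else:
        wy = np.zeros(h)
        iy = np.zeros(h, dtype=int)
    if nx > 1:
        wx = (xx - centers_x[ix]) / (centers_x[ix + 1] - centers_x[ix])
        wx = np.clip(wx, 0.0, 1.0)
    else:
        wx = np.zeros(w)
        ix = np.zeros(w, dtype=int)

    iy2 = np.minimum(iy + 1, ny - 1)
    ix2 = np.minimum(ix + 1, nx - 1)
    IY, IX = np.meshgrid(iy, ix, indexing="ij")
    IY2, IX2 = np.meshgrid(iy2, ix2, indexing="ij")
    WY, WX = np.meshgrid(wy, wx, indexing="ij")
    v = image
    tl = luts[IY, IX, v].astype(float)
    tr = luts[IY, IX2, v].astype(float)
    bl = luts[IY2, IX, v].astype(float)
    br = luts[IY2, IX2, v].astype(float)
    out = ((1 - WY) * ((1 - WX) * tl + WX * tr)
           + WY * ((1 - WX) * bl + WX * br))
    return np.clip(np.round(out), 0, 255).astype(np.uint8)
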