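"""Image/mask file I/O and tabular output helpers.

Phantoms are persisted as paired 8-bit PNGs (``<id>_img.png`` /
``<id>_mask.png``, mask pixels literally 0/1/2) plus a CSV manifest.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .synthetic import LabeledImage

__all__ = ["read_labeled_pair", "write_labeled_pair", "write_dataset",
           "read_dataset", "MaskFormatError"]

log = logging.getLogger("meibseg")


class MaskFormatError(ValueError):
    """Mask file contains labels outside {0, 1, 2}."""


def _load_gray(path) -> np.ndarray:
    arr = np.asarray(Image.open(path))
    if arr.ndim == 3:
        arr = arr[..., :3] @ np.array([0.299, 0.587, 0.114])
        arr = np.round(arr).astype(np.uint8)
    if arr.dtype != np.uint8:
        info = np.iinfo(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
        top = info.max if info else max(float(arr.max()), 1.0)
        log.warning("converting %s from %s to 8-bit with range rescaling",
                    path, arr.dtype)
        arr = np.round(arr.astype(float) / top * 255.0).astype(np.uint8)
    return arr


def read_labeled_pair(img_path, mask_path) -> LabeledImage:
    """Load and validate an image/mask pair (mask labels must be {0,1,2})."""
    image = _load_gray(img_path)
    mask = np.asarray(Image.open(mask_path))
    bad = sorted(set(np.unique(mask)) - {0, 1, 2})
    if bad:
        raise MaskFormatError(
            f"mask {mask_path} contains out-of-range label values {bad}")
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} "
                         "dimensions differ")
    return LabeledImage(image=image, mask=mask.astype(np.uint8),
                        image_id=Path(img_path).stem.removesuffix("_img"))


def write_labeled_pair(item: LabeledImage, out_dir, image_id=None) -> tuple:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iid = image_id or item.image_id or "phantom"
    img_path = out_dir / f"{iid}_img.png"
    mask_path = out_dir / f"{iid}_mask.png"
    Image.fromarray(item.image).save(img_path)
    Image.fromarray(item.mask).save(mask_path)
    return img_path, mask_path


def write_dataset(items, out_dir, seed=None) -> Path:
    """Write paired PNGs plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, item in enumerate(items):
        iid = item.image_id or f"phantom_{i:04d}"
        write_labeled_pair(item, out_dir, iid)
        rows.append({"id": iid, "style": item.style_name,
                     "true_loss_rate": item.true_loss_rate,
                     "seed": seed if seed is not None else ""})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_dataset(in_dir) -> list[LabeledImage]:
    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.csv"
    items = []
    if manifest.exists():
        table = pd.read_csv(manifest)
        for _, row in table.iterrows():
            item = read_labeled_pair(in_dir / f"{row['id']}_img.png",
                                     in_dir / f"{row['id']}_mask.png")
            item.style_name = str(row.get("style", ""))
            item.true_loss_rate = float(row.get("true_loss_rate", "nan"))
            items.append(item)
        return items
    for img_path in sorted(in_dir.glob("*_img.png")):
        mask_path = img_path.with_name(img_path.name.replace("_img", "_mask"))
        items.append(read_labeled_pair(img_path, mask_path))
    return items
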