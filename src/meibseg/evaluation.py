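"""Segmentation and atrophy metrics, group statistics, and the 2-D
embedding domain-gap diagnostic.

Per-region overlap metrics (DSC, recall, precision) are computed by
binarizing predicted and ground-truth masks at a region label.  Gland
atrophy is quantified as the MG loss rate 1 − gland area / eyelid area and
graded into the clinical 0–3 meiboscore in one-third increments.  Group
comparisons use the two-sided Mann–Whitney U test (exact enumeration for
small samples, tie-corrected normal approximation otherwise), with p < 0.01
as the significance threshold.  The domain-gap diagnostic embeds two image
populations with t-SNE and scores their separation with the silhouette
coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats

__all__ = ["MetricsRecord", "LossRateRecord", "ComparisonResult",
           "region_metrics", "mg_loss_rate", "meiboscore", "loss_rate_rmse",
           "compare_groups", "domain_embedding", "aggregate_metrics"]

SIGNIFICANCE_LEVEL = 0.01


@dataclass(frozen=True)
class MetricsRecord:
    image_id: str
    region: int  # 1 = eyelid, 2 = MG
    dsc: float
    recall: float
    precision: float
    defined: bool = True  # False when the truth region is empty


@dataclass(frozen=True)
class LossRateRecord:
    image_id: str
    predicted_rate: float
    true_rate: float

    @property
    def predicted_grade(self) -> int:
        return meiboscore(self.predicted_rate)

    @property
    def true_grade(self) -> int:
        return meiboscore(self.true_rate)


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    group_a: str
    group_b: str
    u_statistic: float
    p_value: float

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def region_metrics(pred: np.ndarray, truth: np.ndarray, region_label: int,
                   image_id: str = "") -> MetricsRecord:
    """DSC, recall and precision for one region of a {0,1,2} mask pair.

    With P = predicted region, T = truth region: DSC = 2|P∩T|/(|P|+|T|),
    recall = |P∩T|/|T|, precision = |P∩T|/|P|.  An empty truth region makes
    recall (and DSC) undefined: the record is flagged ``defined=False`` and
    callers exclude it from aggregates.
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("mask dimensions differ")
    if region_label not in (1, 2):
        raise ValueError("region_label must be 1 (eyelid) or 2 (MG)")
    p = pred == region_label
    t = truth == region_label
    np_, nt = int(p.sum()), int(t.sum())
    inter = int((p & t).sum())
    if nt == 0:
        return MetricsRecord(image_id, region_label, float("nan"),
                             float("nan"), float("nan"), defined=False)
    dsc = 2.0 * inter / (np_ + nt) if (np_ + nt) else float("nan")
    recall = inter / nt
    precision = inter / np_ if np_ else 0.0
    return MetricsRecord(image_id, region_label, dsc, recall, precision)


def mg_loss_rate(mask: np.ndarray) -> float:
    """MG loss rate = 1 − gland area / eyelid area (eyelid = labels 1∪2)."""
    mask = np.asarray(mask)
    if not set(np.unique(mask)).issubset({0, 1, 2}):
        raise ValueError("mask values must lie in {0, 1, 2}")
    eyelid = int(np.count_nonzero(mask > 0))
    if eyelid == 0:
        raise ValueError("mask has no eyelid area; loss rate undefined")
    gland = int(np.count_nonzero(mask == 2))
    return float(np.clip(1.0 - gland / eyelid, 0.0, 1.0))


def meiboscore(rate: float) -> int:
    """Clinical 0–3 atrophy grade: one grade per third of gland loss.

    0 for no loss; 1 for loss in (0, 1/3]; 2 for (1/3, 2/3]; 3 above 2/3.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("loss rate must lie in [0, 1]")
    if rate == 0.0:
        return 0
    if rate <= 1.0 / 3.0:
        return 1
    if rate <= 2.0 / 3.0:
        return 2
    return 3


def loss_rate_rmse(records) -> float:
    """Root-mean-squared error between predicted and true loss rates."""
    records = list(records)
    if not records:
        raise ValueError("need at least one loss-rate record")
    diffs = np.array([r.predicted_rate - r.true_rate for r in records])
    return float(np.sqrt(np.mean(diffs**2)))


def _u_statistic(ranks_a: np.ndarray, n_a: int, n_b: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


_EXACT_MAX_COMBINATIONS = 200_000


def compare_groups(a, b, metric: str = "", group_a: str = "A",
                   group_b: str = "B") -> ComparisonResult:
    """Two-sided Mann–Whitney U comparison of two metric samples.

    For small samples (≤ 200k group assignments) the p-value is exact:
    every assignment of the pooled midranks to the two groups is
    enumerated and p = min(1, 2·min(P(U ≤ u), P(U ≥ u))).  Larger samples
    use scipy's tie-corrected normal approximation.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample must contain at least 2 values")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks for ties
    u_obs = _u_statistic(ranks[:n_a], n_a, n_b)
    if comb(n_a + n_b, n_a) <= _EXACT_MAX_COMBINATIONS:
        us = np.array([
            _u_statistic(ranks[list(idx)], n_a, n_b)
            for idx in combinations(range(n_a + n_b), n_a)])
        eps = 1e-9
        p_le = np.mean(us <= u_obs + eps)
        p_ge = np.mean(us >= u_obs - eps)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                     method="asymptotic").pvalue)
    return ComparisonResult(metric, group_a, group_b, u_obs, float(p))


def _embedding_vectors(images, size: int = 32) -> np.ndarray:
    from .model import _resize_bilinear
    rows = []
    for item in images:
        img = np.asarray(getattr(item, "image", item), dtype=float)
        if img.shape != (size, size):
            img = _resize_bilinear(img, (size, size))
        rows.append(img.ravel() / 255.0)
    return np.asarray(rows)


def domain_embedding(set_a, set_b, seed: int = 0, *, vector_size: int = 32):
    """t-SNE 2-D embedding of two image populations plus a separation score.

    Images are downscaled to ``vector_size``² and flattened; the score is
    the silhouette coefficient of the two set labels on the embedding
    (≈0 when the populations mix, →1 when they separate).
    Returns ``(coords, labels, score)``.
    """
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    set_a, set_b = list(set_a), list(set_b)
    n = len(set_a) + len(set_b)
    if n < 5:
        raise ValueError("need at least 5 images for a 2-D embedding")
    vectors = np.vstack([_embedding_vectors(set_a, vector_size),
                         _embedding_vectors(set_b, vector_size)])
    labels = np.array([0] * len(set_a) + [1] * len(set_b))
    perplexity = min(30.0, (n - 1) / 3.0)
    coords = TSNE(n_components=2, random_state=seed, init="pca",
                  perplexity=perplexity).fit_transform(vectors)
    score = float(silhouette_score(coords, labels))
    return coords, labels, score


def aggregate_metrics(records) -> dict:
    """Mean ± SD of each metric over the defined records; counts exclusions."""
    records = list(records)
    defined = [r for r in records if r.defined]
    out = {"n": len(records), "n_excluded": len(records) - len(defined)}
    for name in ("dsc", "recall", "precision"):
        vals = np.array([getattr(r, name) for r in defined])
        out[f"{name}_mean"] = float(vals.mean()) if vals.size else float("nan")
        out[f"{name}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else float("nan")
    return out
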