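"""Four-stage under-sampling cascade for pixel training sets.

Vessel pixels are a small minority (roughly 5-6% of a frame) and neighboring
pixels carry nearly identical features, so training directly on all pixels
is both wasteful and biased toward the background class.  The cascade
reduces the majority class in four stages:

1. uniform   — keep a stride-2 lattice of background pixels so no two
               retained pixels are 8-neighbors;
2. unsupervised — drop background pixels brighter than an intensity
               threshold derived from the contrast-enhanced image's
               histogram (clear background); the removed set is kept as the
               "unsupervised background mask" for post-processing;
3. Tomek links — remove mutually-nearest-neighbor pairs with opposite
               labels (both members), sharpening the class boundary;
4. cluster centroids — replace each class by a fixed number of k-means
               centroids, yielding an exactly balanced set.

Stages 1-2 act on the majority class only and never touch vessel pixels.
A per-stage audit report records counts and class percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import medfilt
from sklearn.cluster import KMeans
from sklearn.neighbors import NearestNeighbors

from .preprocess import EnhancedImage


@dataclass
class PixelDataset:
    """Rows of (feature vector, label) surviving the cascade.

    origin holds (image index, row, col) per row, or None for synthesized
    rows (cluster centroids); stage names the last sampling stage applied.
    """

    features: np.ndarray  # (N, D)
    labels: np.ndarray  # (N,) in {0, 1}
    origin: np.ndarray | None = None  # (N, 3) int, or None
    stage: str = "raw"

    def __post_init__(self):
        self.labels = np.asarray(self.labels).astype(int)
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary")
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("features and labels disagree in length")
        if self.origin is not None:
            uniq = np.unique(self.origin, axis=0)
            if uniq.shape[0] != self.origin.shape[0]:
                raise ValueError("duplicate (image, row, col) origins")

    @property
    def n(self) -> int:
        return self.labels.shape[0]

    @property
    def positive_fraction(self) -> float:
        return float(self.labels.mean()) if self.n else 0.0

    def subset(self, idx: np.ndarray, stage: str | None = None) -> "PixelDataset":
        return PixelDataset(
            features=self.features[idx],
            labels=self.labels[idx],
            origin=None if self.origin is None else self.origin[idx],
            stage=stage or self.stage,
        )

    @staticmethod
    def concatenate(parts: list["PixelDataset"], stage: str) -> "PixelDataset":
        feats = np.concatenate([p.features for p in parts])
        labs = np.concatenate([p.labels for p in parts])
        if all(p.origin is not None for p in parts):
            origin = np.concatenate([p.origin for p in parts])
        else:
            origin = None
        return PixelDataset(features=feats, labels=labs, origin=origin, stage=stage)


@dataclass
class SamplerReport:
    """Per-stage retained counts and class percentages."""

    rows: list = field(default_factory=list)  # dicts: stage, pos_pct, neg_pct, total

    def add(self, stage: str, n_pos: int, n_neg: int):
        total = n_pos + n_neg
        self.rows.append(
            {
                "stage": stage,
                "positive_pct": round(100.0 * n_pos / total, 3) if total else 0.0,
                "negative_pct": round(100.0 * n_neg / total, 3) if total else 0.0,
                "total": int(total),
            }
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path):
        self.to_dataframe().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# stage 1: uniform


def uniform_undersample(
    negative_mask: np.ndarray,
    border_mask: np.ndarray,
    offset: tuple[int, int] = (0, 0),
) -> np.ndarray:
    """Stride-2 lattice sampling of background pixels.

    Returns a boolean mask of retained negatives.  The lattice guarantees
    that no two retained pixels are 8-neighbors (pairwise Chebyshev distance
    >= 2) and retains at most 25% of the negatives; the per-image offset
    decorrelates the lattice across frames.
    """
    if negative_mask.shape != border_mask.shape:
        raise ValueError("masks must share shape")
    h, w = negative_mask.shape
    lattice = np.zeros((h, w), dtype=bool)
    lattice[offset[0] % 2 :: 2, offset[1] % 2 :: 2] = True
    return lattice & negative_mask & border_mask


# ---------------------------------------------------------------------------
# stage 2: unsupervised (intensity-based)


def unsupervised_threshold(
    enhanced_pixels: np.ndarray,
    valid_mask: np.ndarray | None = None,
    median_width: int = 5,
) -> tuple[float, int]:
    """Intensity threshold separating clear background, from the histogram.

    A 256-bin histogram of the contrast-enhanced image is turned into a
    discrete pdf and smoothed with a 1-D median filter; the bin where the
    raw pdf most exceeds the smoothed one marks the over-saturation peak
    created by enhancement clipping.  Excluding that peak's pixels, the
    median of the remaining intensities is the threshold.

    Returns (threshold, peak_bin).
    """
    vals = enhanced_pixels[valid_mask] if valid_mask is not None else enhanced_pixels.ravel()
    counts, edges = np.histogram(vals, bins=256, range=(0.0, 1.0))
    pdf = counts / max(counts.sum(), 1)
    smooth = medfilt(pdf, kernel_size=median_width)
    peak_bin = int(np.argmax(pdf - smooth))
    in_peak = (vals >= edges[peak_bin]) & (vals < edges[peak_bin + 1])
    if peak_bin == 255:  # top bin includes the right edge
        in_peak = vals >= edges[peak_bin]
    rest = vals[~in_peak]
    if rest.size == 0:
        return float(np.median(vals)), peak_bin
    return float(np.median(rest)), peak_bin


def unsupervised_undersample(
    enhanced: EnhancedImage,
    retained_negatives: np.ndarray,
    valid_mask: np.ndarray | None = None,
    median_width: int = 5,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Remove clear-background negatives by intensity.

    Negatives brighter than the histogram-derived threshold are removed;
    the removed set over the whole frame (every in-border pixel brighter
    than the threshold) is returned as the unsupervised background mask,
    reused at post-processing time to force those pixels to background.

    Returns (kept negative mask, background mask, threshold).
    """
    pix = enhanced.pixels
    if np.ptp(pix[valid_mask] if valid_mask is not None else pix) <= 0:
        warnings.warn("degenerate single-intensity image; keeping all negatives")
        return retained_negatives.copy(), np.zeros_like(retained_negatives), float("nan")
    thr, _ = unsupervised_threshold(pix, valid_mask, median_width)
    background_mask = pix > thr
    if valid_mask is not None:
        background_mask &= valid_mask
    kept = retained_negatives & ~background_mask
    if not kept.any():
        warnings.warn("unsupervised stage removed every retained negative")
    return kept, background_mask, thr


# ---------------------------------------------------------------------------
# stage 3: Tomek links


def _mutual_nn_links(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Boolean mask of points participating in an opposite-label mutual-NN pair."""
    n = X.shape[0]
    nbrs = NearestNeighbors(n_neighbors=min(2, n)).fit(X)
    _, idx = nbrs.kneighbors(X)
    nn = np.where(idx[:, 0] != np.arange(n), idx[:, 0], idx[:, -1])
    mutual = nn[nn] == np.arange(n)
    link = mutual & (y != y[nn])
    return link


def tomek_links(dataset: PixelDataset) -> PixelDataset:
    """Remove all Tomek links (both members of each link).

    Removal is iterated to a fixpoint so that a re-scan of the output finds
    no remaining opposite-label mutual-nearest-neighbor pair, which makes
    the operation idempotent.
    """
    if len(np.unique(dataset.labels)) < 2:
        warnings.warn("single-class dataset; Tomek stage is the identity")
        return dataset.subset(np.arange(dataset.n), stage="tomek")
    keep = np.arange(dataset.n)
    X = dataset.features
    y = dataset.labels
    while keep.size >= 2 and len(np.unique(y[keep])) == 2:
        link = _mutual_nn_links(X[keep], y[keep])
        if not link.any():
            break
        keep = keep[~link]
    return dataset.subset(keep, stage="tomek")


# ---------------------------------------------------------------------------
# stage 4: cluster centroids


def cluster_centroid(
    dataset: PixelDataset, per_class_target: int, seed: int = 0
) -> PixelDataset:
    """Replace each class by ``per_class_target`` k-means centroids.

    Output rows are synthesized (origin is dropped) and exactly balanced:
    50/50 classes with 2 x per_class_target rows.  If a class has fewer
    points than the target, all its points are used instead, with a warning
    (balance is then only as exact as the counts allow).
    """
    feats, labs = [], []
    for cls in (0, 1):
        Xc = dataset.features[dataset.labels == cls]
        if Xc.shape[0] == 0:
            warnings.warn(f"class {cls} empty; centroid stage keeps nothing for it")
            continue
        if Xc.shape[0] <= per_class_target:
            warnings.warn(
                f"class {cls} has {Xc.shape[0]} <= target {per_class_target}; using all points"
            )
            cents = Xc
        else:
            km = KMeans(
                n_clusters=per_class_target, n_init=3, random_state=seed, algorithm="lloyd"
            ).fit(Xc)
            cents = km.cluster_centers_
        feats.append(cents)
        labs.append(np.full(cents.shape[0], cls))
    return PixelDataset(
        features=np.concatenate(feats),
        labels=np.concatenate(labs),
        origin=None,
        stage="centroid",
    )


# ---------------------------------------------------------------------------
# cascade orchestration


def build_report(stages: list[tuple[str, PixelDataset]]) -> SamplerReport:
    """Audit report over cascade outputs in order."""
    rep = SamplerReport()
    for name, ds in stages:
        n_pos = int(ds.labels.sum())
        rep.add(name, n_pos, ds.n - n_pos)
    return rep


def dataset_from_image(
    stack,
    labels: np.ndarray,
    mask: np.ndarray,
    image_index: int,
    stage: str = "raw",
) -> PixelDataset:
    """Rows for the True pixels of ``mask`` from one feature stack."""
    rows, cols = np.nonzero(mask)
    feats = stack.maps[:, rows, cols].T
    origin = np.column_stack([np.full(rows.size, image_index), rows, cols])
    return PixelDataset(
        features=feats, labels=labels[rows, cols].astype(int), origin=origin, stage=stage
    )


def run_cascade(
    stacks: list,
    label_masks: list[np.ndarray],
    border_masks: list[np.ndarray],
    enhanced_images: list[EnhancedImage],
    per_class_target: int | None = 4000,
    stages: tuple[str, ...] = ("uniform", "unsupervised", "tomek", "centroid"),
    seed: int = 0,
) -> tuple[PixelDataset, SamplerReport, list[np.ndarray]]:
    """Apply the cascade per image and pool the survivors.

    Returns the pooled dataset after the last requested stage, the audit
    report over all stages, and the per-image unsupervised background masks
    (empty masks when that stage is not requested).
    """
    per_stage_parts: dict[str, list[PixelDataset]] = {
        s: [] for s in ("raw",) + stages
    }
    bg_masks = []
    for i, (stack, labels, border, enh) in enumerate(
        zip(stacks, label_masks, border_masks, enhanced_images)
    ):
        pos_mask = labels.astype(bool) & border
        neg_mask = ~labels.astype(bool) & border
        current_neg = neg_mask
        ds_raw = dataset_from_image(stack, labels, pos_mask | current_neg, i, "raw")
        per_stage_parts["raw"].append(ds_raw)
        bg = np.zeros_like(border)

        if "uniform" in stages:
            current_neg = uniform_undersample(neg_mask, border, offset=(i % 2, (i // 2) % 2))
            per_stage_parts["uniform"].append(
                dataset_from_image(stack, labels, pos_mask | current_neg, i, "uniform")
            )
        if "unsupervised" in stages:
            current_neg, bg, _ = unsupervised_undersample(enh, current_neg, border)
            per_stage_parts["unsupervised"].append(
                dataset_from_image(stack, labels, pos_mask | current_neg, i, "unsupervised")
            )
        bg_masks.append(bg)

        ds = dataset_from_image(stack, labels, pos_mask | current_neg, i, "sampled")
        if "tomek" in stages:
            ds = tomek_links(ds)
            per_stage_parts["tomek"].append(ds)
        if "centroid" in stages:
            if per_class_target is None:
                raise ValueError("per_class_target required for the centroid stage")
            ds = cluster_centroid(ds, per_class_target, seed=seed + i)
            per_stage_parts["centroid"].append(ds)

    ordered = [("raw", PixelDataset.concatenate(per_stage_parts["raw"], "raw"))]
    for s in stages:
        if per_stage_parts[s]:
            ordered.append((s, PixelDataset.concatenate(per_stage_parts[s], s)))
    report = build_report(ordered)
    return ordered[-1][1], report, bg_masks


def planned_centroid_rows(n_train_images: int, per_class_target: int) -> int:
    """Final row count of a per-image centroid stage: images x 2 x target."""
    return int(n_train_images) * 2 * int(per_class_target)
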