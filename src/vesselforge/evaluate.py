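"""Post-processing of probability maps and segmentation evaluation.

Probability maps are binarized with Otsu's method, cleaned (border pixels
and unsupervised-background pixels forced to background, small artifacts
removed), and scored image-wise with six metrics: precision, sensitivity,
specificity, F1, IoU and AUROC.  Permutation importance quantifies each
feature's contribution on held-out pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label
from sklearn.metrics import roc_auc_score

MIN_ARTIFACT_AREA = 50  # connected components below this area are removed

#: 8-connectivity structuring element for component analysis
_STRUCT8 = np.ones((3, 3), dtype=int)


def binarize(prob_map: np.ndarray, n_levels: int = 256) -> np.ndarray:
    """Otsu threshold on the probability histogram.

    The threshold maximizing the between-class variance over ``n_levels``
    candidate levels in [0,1) is selected, ties broken toward the lower
    threshold; pixels strictly above it are foreground.  A constant map
    yields an all-background mask with a warning.
    """
    p = np.asarray(prob_map, dtype=float)
    if np.ptp(p) <= 0:
        warnings.warn("constant probability map; returning all-background")
        return np.zeros_like(p, dtype=bool)
    counts, edges = np.histogram(p, bins=n_levels, range=(0.0, 1.0))
    total = counts.sum()
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(counts)
    sum0 = np.cumsum(counts * centers)
    mu_total = sum0[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = sum0 / w0
        mu1 = (mu_total - sum0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~np.isfinite(between)] = -np.inf
    k = int(np.argmax(between))  # argmax returns the first (lowest) maximizer
    thr = edges[k + 1]
    return p > thr


def postprocess(
    mask: np.ndarray,
    border_mask: np.ndarray,
    unsupervised_background_mask: np.ndarray | None = None,
    min_area: int = MIN_ARTIFACT_AREA,
) -> np.ndarray:
    """Clean a binary prediction.

    (1) border pixels forced to background; (2) pixels of the unsupervised
    background mask forced to background; (3) 8-connected components with
    area < ``min_area`` removed.
    """
    if mask.shape != border_mask.shape:
        raise ValueError("masks must share shape")
    out = mask & border_mask
    if unsupervised_background_mask is not None:
        out = out & ~unsupervised_background_mask
    labels, n = cc_label(out, structure=_STRUCT8)
    if n:
        areas = np.bincount(labels.ravel())
        small = np.nonzero(areas < min_area)[0]
        small = small[small > 0]
        if small.size:
            out = out & ~np.isin(labels, small)
    return out


def metrics(
    pred_mask: np.ndarray, truth_mask: np.ndarray, border_mask: np.ndarray
) -> dict:
    """Precision, sensitivity, specificity, F1 and IoU over in-border pixels.

    Zero-denominator metrics are reported as None (undefined), never 0 —
    silently coercing them would bias image-wise averages.
    """
    if not (pred_mask.shape == truth_mask.shape == border_mask.shape):
        raise ValueError("masks must share shape")
    p = pred_mask[border_mask].astype(bool)
    t = truth_mask[border_mask].astype(bool)
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))

    def ratio(num, den):
        return num / den if den > 0 else None

    precision = ratio(tp, tp + fp)
    sensitivity = ratio(tp, tp + fn)
    specificity = ratio(tn, tn + fp)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    iou = ratio(tp, tp + fp + fn)
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "specificity": specificity,
        "f1": f1,
        "iou": iou,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "tn": tn,
    }


def auroc(
    prob_map: np.ndarray, truth_mask: np.ndarray, border_mask: np.ndarray
) -> float | None:
    """Area under the ROC over in-border pixels (rank statistic, ties
    half-credited); None when only one class is present."""
    scores = prob_map[border_mask]
    labels = truth_mask[border_mask].astype(int)
    if len(np.unique(labels)) < 2:
        warnings.warn("single-class truth; AUROC undefined")
        return None
    return float(roc_auc_score(labels, scores))


@dataclass
class SegmentationResult:
    """One frame's probability map, cleaned mask and metric set."""

    probability_map: np.ndarray
    mask: np.ndarray
    metrics: dict
    log: list = field(default_factory=list)


def evaluate_frame(
    prob_map: np.ndarray,
    truth_mask: np.ndarray,
    border_mask: np.ndarray,
    unsupervised_background_mask: np.ndarray | None = None,
) -> SegmentationResult:
    """Binarize, post-process and score one probability map.

    AUROC is computed on the pre-binarization probability map (the only
    information-bearing choice); the five count metrics on the cleaned mask.
    """
    log = []
    mask = binarize(prob_map)
    log.append("otsu binarization")
    mask = postprocess(mask, border_mask, unsupervised_background_mask)
    log.append("border removal, background mask, area<%d removal" % MIN_ARTIFACT_AREA)
    mets = metrics(mask, truth_mask, border_mask)
    mets["auroc"] = auroc(prob_map, truth_mask, border_mask)
    return SegmentationResult(
        probability_map=prob_map, mask=mask, metrics=mets, log=log
    )


def summarize_results(results: list[SegmentationResult]) -> pd.DataFrame:
    """Image-wise metric table with mean and std rows appended.

    Undefined (None) metrics are excluded from the mean/std, mirroring
    image-wise averaging over defined values only.
    """
    keys = ["precision", "sensitivity", "specificity", "f1", "auroc", "iou"]
    rows = [{k: r.metrics.get(k) for k in keys} for r in results]
    df = pd.DataFrame(rows, index=[f"image_{i}" for i in range(len(rows))])
    stats = pd.DataFrame(
        {k: [df[k].dropna().mean(), df[k].dropna().std()] for k in keys},
        index=["mean", "std"],
    )
    return pd.concat([df, stats])


# ---------------------------------------------------------------------------
# permutation feature importance


@dataclass
class ImportanceReport:
    """Mean and spread of criterion increase per permuted feature."""

    feature_names: list[str]
    mean_importance: np.ndarray
    std_importance: np.ndarray
    repeats: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "importance_mean": self.mean_importance,
                "importance_std": self.std_importance,
            }
        )


def permutation_importance(
    model,
    pixels,
    repeats: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Permutation importance on held-out pixels.

    For each feature column, the column is shuffled ``repeats`` times and
    the squared-error criterion of the model's vessel probability against
    the labels is recomputed; importance is the mean criterion increase over
    the unpermuted baseline.  A constant column has exactly zero importance.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    X = np.array(pixels.features, dtype=float)
    y = np.asarray(pixels.labels, dtype=float)
    rng = np.random.default_rng(seed)

    def criterion(mat):
        p = model.predict_proba_rows(mat)
        return float(np.mean((p - y) ** 2))

    base = criterion(X)
    n_feat = X.shape[1]
    means = np.zeros(n_feat)
    stds = np.zeros(n_feat)
    for j in range(n_feat):
        if np.ptp(X[:, j]) == 0:
            continue  # permuting a constant changes nothing
        deltas = []
        for _ in range(repeats):
            Xp = X.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            deltas.append(criterion(Xp) - base)
        means[j] = np.mean(deltas)
        stds[j] = np.std(deltas)
    names = getattr(model, "feature_names", None) or [f"f{i}" for i in range(n_feat)]
    return ImportanceReport(
        feature_names=list(names),
        mean_importance=means,
        std_importance=stds,
        repeats=repeats,
    )
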