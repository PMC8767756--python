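"""Ensemble pixel classifiers: stratified splits, GBDT tuning, cascade forest.

The classifiers operate on standardized per-pixel feature vectors (21
filter-based, optionally + 16 deep).  Splits are image-level — pixels from
one frame never straddle sets — and stratified by view label (and source
when present).  GBDT hyper-parameters are tuned by 4-fold cross-validation
with cyclically-permuted folds, selecting the grid point with the highest
mean pooled validation AUROC.  The cascade forest ("deep forest") stacks
layers of random forests and completely-random forests, each layer consuming
the original features plus the previous layer's class-probability vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import joblib
import numpy as np
from sklearn.ensemble import ExtraTreesClassifier, GradientBoostingClassifier, RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import cross_val_predict

from .features_filter import FeatureStack
from .sampling import PixelDataset

#: hyper-parameter grids explored during GBDT tuning
GBDT_GRID = {
    "learning_rate": (0.01, 0.05, 0.1),
    "n_stages": (100, 500, 1000, 2000),
    "max_depth": (3, 5, 10, 20),
}


@dataclass(frozen=True)
class GBDTConfig:
    learning_rate: float = 0.1
    n_stages: int = 100
    max_depth: int = 3

    def estimator(self, seed: int = 0) -> GradientBoostingClassifier:
        # deviance loss; trees split on Friedman-MSE (the library's internal
        # criterion); everything else stays at library defaults
        return GradientBoostingClassifier(
            learning_rate=self.learning_rate,
            n_estimators=self.n_stages,
            max_depth=self.max_depth,
            random_state=seed,
        )


@dataclass
class SplitPlan:
    """Image-level assignment of frames to train/validation/test."""

    assignment: dict  # image id -> "train" | "validation" | "test"
    mode: str  # "ensemble" (4:1) or "deep" (3:1:1)
    seed: int

    def ids(self, role: str) -> list:
        return [k for k, v in self.assignment.items() if v == role]


def make_split(images: list, mode: str = "ensemble", seed: int = 0) -> SplitPlan:
    """Deterministic stratified image-level split.

    mode "deep" gives train:validation:test = 3:1:1; mode "ensemble" gives
    train:test = 4:1 where the test images are exactly the 3:1:1 test set
    (the deep-learning hold-out) and validation images join the training
    pool.  Strata are (view label, source); a stratum smaller than 5 images
    is merged into its neighbor with a warning.
    """
    if len(images) < 5:
        raise ValueError("need at least 5 images to split")

    def key(img):
        view = getattr(img, "view_label", "NA")
        source = getattr(img, "source", "synthetic")
        return (view, source)

    def ident(img):
        return getattr(img, "image_id", None) or id(img)

    strata: dict = {}
    for img in images:
        strata.setdefault(key(img), []).append(ident(img))
    small = [k for k, v in strata.items() if len(v) < 5]
    if small and len(strata) > 1:
        warnings.warn(f"merging small strata {small}")
        merged = []
        for k in small:
            merged.extend(strata.pop(k))
        big = max(strata, key=lambda k: len(strata[k]))
        strata[big].extend(merged)

    rng = np.random.default_rng(seed)
    assignment: dict = {}
    for k in sorted(strata):
        ids = sorted(strata[k], key=str)
        rng.shuffle(ids)
        n = len(ids)
        n_test = max(1, round(n / 5))
        n_val = max(1, round(n / 5))
        for i, iid in enumerate(ids):
            if i < n_test:
                role = "test"
            elif i < n_test + n_val:
                role = "validation" if mode == "deep" else "train"
            else:
                role = "train"
            assignment[iid] = role
    return SplitPlan(assignment=assignment, mode=mode, seed=seed)


@dataclass
class TrainedModel:
    """A fitted pixel classifier with everything prediction needs."""

    kind: str  # "gbdt" | "deep_forest"
    model: object
    feature_names: list[str]
    standardization: dict | None = None
    config: GBDTConfig | None = None

    def save(self, path):
        joblib.dump(self, path)

    @classmethod
    def load(cls, path):
        return joblib.load(path)

    def predict_proba_rows(self, X: np.ndarray) -> np.ndarray:
        if self.kind == "gbdt":
            return self.model.predict_proba(X)[:, 1]
        return self.model.predict_proba(X)[:, 1]


# ---------------------------------------------------------------------------
# GBDT


def cyclic_folds(n_items: int, n_folds: int = 4) -> list[tuple[np.ndarray, np.ndarray]]:
    """Cyclic-permutation folds with a 3:1 train:validation ratio.

    Items (training images, in order) are cut into ``n_folds`` contiguous
    blocks; each fold validates on one block and trains on the other three,
    rotating the validation block.
    """
    idx = np.arange(n_items)
    blocks = np.array_split(idx, n_folds)
    folds = []
    for f in range(n_folds):
        val = blocks[f]
        train = np.concatenate([blocks[g] for g in range(n_folds) if g != f])
        folds.append((train, val))
    return folds


def tune_gbdt(
    fold_datasets: list[tuple[PixelDataset, PixelDataset]],
    grid: dict | None = None,
    seed: int = 0,
    log: list | None = None,
) -> GBDTConfig:
    """Pick the grid point with the highest mean validation AUROC.

    ``fold_datasets`` holds (train, validation) pixel datasets per fold,
    built image-level upstream (standardization already re-fit within each
    fold; no pixel of a validation image appears in that fold's training
    rows).  ``log`` (if given) collects one record per individual fit.
    """
    grid = grid or GBDT_GRID
    combos = list(
        product(grid["learning_rate"], grid["n_stages"], grid["max_depth"])
    )
    if not combos:
        raise ValueError("empty grid")
    best_cfg, best_score = None, -np.inf
    for lr, n_stages, depth in combos:
        cfg = GBDTConfig(learning_rate=lr, n_stages=n_stages, max_depth=depth)
        scores = []
        for k, (tr, va) in enumerate(fold_datasets):
            est = cfg.estimator(seed)
            est.fit(tr.features, tr.labels)
            proba = est.predict_proba(va.features)[:, 1]
            score = roc_auc_score(va.labels, proba)  # pooled over the fold's pixels
            scores.append(score)
            if log is not None:
                log.append({"config": cfg, "fold": k, "auroc": float(score)})
        mean = float(np.mean(scores))
        if mean > best_score:
            best_score, best_cfg = mean, cfg
    return best_cfg


def fit(
    pixels: PixelDataset,
    config: GBDTConfig | None = None,
    feature_names: list[str] | None = None,
    standardization: dict | None = None,
    seed: int = 0,
) -> TrainedModel:
    """Fit the GBDT pixel classifier."""
    if len(np.unique(pixels.labels)) < 2:
        raise ValueError("single-class input")
    if not np.all(np.isfinite(pixels.features)):
        raise ValueError("features must be finite")
    cfg = config or GBDTConfig()
    est = cfg.estimator(seed)
    est.fit(pixels.features, pixels.labels)
    names = feature_names or [f"f{i}" for i in range(pixels.features.shape[1])]
    return TrainedModel(
        kind="gbdt",
        model=est,
        feature_names=list(names),
        standardization=standardization,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# cascade ("deep") forest


class CascadeForest:
    """Layered forest ensemble in the deep-forest style.

    Each layer holds ``n_rf`` random forests and ``n_crf`` completely-random
    forests (extra-trees with single-feature splits).  A layer's input is
    the original feature matrix concatenated with the previous layer's
    class-probability vectors (2 per forest).  Layer probabilities are
    estimated out-of-sample by internal 3-fold cross-validation; depth grows
    while the cross-validated accuracy improves, up to ``max_layers``.
    """

    def __init__(
        self,
        n_rf: int = 2,
        n_crf: int = 2,
        n_trees: int = 50,
        max_layers: int = 5,
        cv: int = 3,
        seed: int = 0,
    ):
        self.n_rf = n_rf
        self.n_crf = n_crf
        self.n_trees = n_trees
        self.max_layers = max_layers
        self.cv = cv
        self.seed = seed
        self.layers_: list[list] = []
        self.n_layers_ = 0

    @property
    def forests_per_layer(self) -> int:
        return self.n_rf + self.n_crf

    def _make_forests(self, layer: int):
        forests = []
        for j in range(self.n_rf):
            forests.append(
                RandomForestClassifier(
                    n_estimators=self.n_trees,
                    random_state=self.seed + 97 * layer + j,
                    n_jobs=1,
                )
            )
        for j in range(self.n_crf):
            forests.append(
                ExtraTreesClassifier(
                    n_estimators=self.n_trees,
                    max_features=1,
                    random_state=self.seed + 97 * layer + self.n_rf + j,
                    n_jobs=1,
                )
            )
        return forests

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CascadeForest":
        if len(np.unique(y)) < 2:
            raise ValueError("single-class input")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        aug = X
        best_acc = -np.inf
        for layer in range(self.max_layers):
            forests = self._make_forests(layer)
            probas, accs = [], []
            for f in forests:
                oof = cross_val_predict(f, aug, y, cv=self.cv, method="predict_proba")
                probas.append(oof)
                f.fit(aug, y)
            layer_proba = np.mean(probas, axis=0)
            acc = float((layer_proba.argmax(axis=1) == y).mean())
            if layer > 0 and acc <= best_acc + 1e-6:
                break  # no improvement: discard this layer and stop growing
            self.layers_.append(forests)
            self.n_layers_ = layer + 1
            best_acc = acc
            aug = np.hstack([X] + probas)
        return self

    def _augmented(self, X: np.ndarray, upto: int) -> np.ndarray:
        """Layer input at depth ``upto`` (0 = original features)."""
        aug = X
        for layer in self.layers_[:upto]:
            probas = [f.predict_proba(aug) for f in layer]
            aug = np.hstack([X] + probas)
        return aug

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        aug = self._augmented(X, self.n_layers_ - 1)
        final = self.layers_[-1]
        return np.mean([f.predict_proba(aug) for f in final], axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)


def fit_deep_forest(
    pixels: PixelDataset,
    feature_names: list[str] | None = None,
    standardization: dict | None = None,
    seed: int = 0,
    **kwargs,
) -> TrainedModel:
    """Fit the cascade-forest pixel classifier (default hyper-parameters)."""
    cf = CascadeForest(seed=seed, **kwargs)
    cf.fit(pixels.features, pixels.labels)
    names = feature_names or [f"f{i}" for i in range(pixels.features.shape[1])]
    return TrainedModel(
        kind="deep_forest",
        model=cf,
        feature_names=list(names),
        standardization=standardization,
    )


# ---------------------------------------------------------------------------
# prediction


def predict_proba(
    model: TrainedModel, stack: FeatureStack, border_mask: np.ndarray
) -> np.ndarray:
    """Per-pixel vessel probability map; border pixels are set to 0.

    The stack must carry the model's feature manifest (and is expected to
    be standardized with the model's saved training parameters).
    """
    if list(stack.names) != list(model.feature_names):
        raise ValueError("feature manifest mismatch between model and stack")
    h, w = stack.maps.shape[1:]
    out = np.zeros((h, w))
    if not border_mask.any():
        return out
    X = stack.as_matrix(border_mask)
    out[border_mask] = model.predict_proba_rows(X)
    return out
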