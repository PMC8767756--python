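"""End-to-end segmentation pipeline.

Wires the stages together: preprocessing, filter-based (and optionally
deep) feature extraction, training-set standardization, the under-sampling
cascade, ensemble training, and per-frame prediction with post-processing.
The pipeline caches per-frame features so fitting and evaluating on the
same frames never recomputes filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import features_deep as fd
from .ensemble import (
    GBDTConfig,
    SplitPlan,
    TrainedModel,
    fit,
    fit_deep_forest,
    make_split,
    predict_proba,
)
from .evaluate import SegmentationResult, evaluate_frame, summarize_results, binarize, postprocess, metrics, auroc
from .features_filter import (
    FeatureStack,
    N_ORIENTATIONS,
    extract_filter_features,
    fit_standardization,
    standardize,
)
from .preprocess import PreprocessConfig, PreprocessedFrame, preprocess_frame
from .sampling import run_cascade, unsupervised_threshold
from .synthdata import Angiogram, VesselMask


@dataclass
class FrameFeatures:
    """Cached per-frame artifacts."""

    frame: PreprocessedFrame
    raw_stack: FeatureStack


class SegmentationPipeline:
    """Train-and-predict pipeline for coronary-vessel segmentation.

    Parameters
    ----------
    classifier : {"gbdt", "deep_forest"}
    sampling_stages : tuple of stage names among
        ("uniform", "unsupervised", "tomek", "centroid"), applied in order.
    per_class_target : int
        k-means centroids per class when the centroid stage is active.
    gbdt_config : GBDTConfig
        Hyper-parameters for the GBDT (tuning is a separate, explicit step;
        see :func:`vesselforge.ensemble.tune_gbdt`).
    use_deep_features : bool
        When True a small encoder-decoder is trained on the training frames
        and its 16 final-decoder maps join the 21 filter features.
    """

    def __init__(
        self,
        classifier: str = "gbdt",
        sampling_stages: tuple = ("uniform", "unsupervised", "tomek"),
        per_class_target: int = 4000,
        gbdt_config: GBDTConfig | None = None,
        use_deep_features: bool = False,
        train_config: fd.TrainConfig | None = None,
        preprocess_config: PreprocessConfig | None = None,
        n_orientations: int = N_ORIENTATIONS,
        seed: int = 0,
    ):
        self.classifier = classifier
        self.sampling_stages = tuple(sampling_stages)
        self.per_class_target = per_class_target
        self.gbdt_config = gbdt_config or GBDTConfig()
        self.use_deep_features = use_deep_features
        self.train_config = train_config
        self.preprocess_config = preprocess_config or PreprocessConfig()
        self.n_orientations = n_orientations
        self.seed = seed

        self.checkpoint_: fd.Checkpoint | None = None
        self.model_: TrainedModel | None = None
        self.standardization_: dict | None = None
        self.split_: SplitPlan | None = None
        self.report_ = None
        self._cache: dict[str, FrameFeatures] = {}

    # -- feature extraction --------------------------------------------------

    def extract(self, angiogram: Angiogram) -> FrameFeatures:
        """Preprocess a frame and build its (unstandardized) feature stack."""
        key = angiogram.image_id
        if key in self._cache:
            return self._cache[key]
        frame = preprocess_frame(angiogram, self.preprocess_config)
        stack = extract_filter_features(frame, self.n_orientations)
        if self.use_deep_features:
            if self.checkpoint_ is None:
                raise RuntimeError("deep features requested but no trained checkpoint")
            deep = fd.extract_deep_features(self.checkpoint_, frame.denoised)
            stack = FeatureStack(
                maps=np.concatenate([stack.maps, deep]),
                names=stack.names + [f"deep.{i + 1:02d}" for i in range(deep.shape[0])],
            )
        ff = FrameFeatures(frame=frame, raw_stack=stack)
        self._cache[key] = ff
        return ff

    # -- training ------------------------------------------------------------

    def fit(self, pairs: list[tuple[Angiogram, VesselMask]]) -> "SegmentationPipeline":
        """Split image-level, train (optionally) the deep extractor, build
        the pixel training set through the cascade, and fit the classifier."""
        images = [a for a, _ in pairs]
        self.split_ = make_split(images, mode="ensemble", seed=self.seed)
        by_id = {a.image_id: (a, m) for a, m in pairs}
        train_ids = self.split_.ids("train")

        if self.use_deep_features:
            deep_split = make_split(images, mode="deep", seed=self.seed)
            dl_train = [by_id[i] for i in deep_split.ids("train")]
            dl_val = [by_id[i] for i in deep_split.ids("validation")]
            cfg = self.train_config or fd.TrainConfig(seed=self.seed)
            self.checkpoint_ = fd.train_network(
                [(a.pixels, m.labels) for a, m in dl_train],
                [(a.pixels, m.labels) for a, m in dl_val],
                cfg,
            )

        feats = [self.extract(by_id[i][0]) for i in train_ids]
        borders = [f.frame.border_mask for f in feats]
        self.standardization_ = fit_standardization(
            [f.raw_stack for f in feats], borders
        )
        stacks = [standardize(f.raw_stack, self.standardization_) for f in feats]
        labels = [by_id[i][1].labels for i in train_ids]
        enhanced = [f.frame.enhanced for f in feats]

        dataset, self.report_, _ = run_cascade(
            stacks,
            labels,
            borders,
            enhanced,
            per_class_target=self.per_class_target,
            stages=self.sampling_stages,
            seed=self.seed,
        )
        names = stacks[0].names
        if self.classifier == "gbdt":
            self.model_ = fit(
                dataset,
                config=self.gbdt_config,
                feature_names=names,
                standardization=self.standardization_,
                seed=self.seed,
            )
        elif self.classifier == "deep_forest":
            self.model_ = fit_deep_forest(
                dataset,
                feature_names=names,
                standardization=self.standardization_,
                seed=self.seed,
            )
        else:
            raise ValueError(f"unknown classifier {self.classifier!r}")
        return self

    # -- prediction ----------------------------------------------------------

    def predict_frame(self, angiogram: Angiogram) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(probability map, border mask, unsupervised background mask)."""
        if self.model_ is None:
            raise RuntimeError("pipeline is not fitted")
        ff = self.extract(angiogram)
        stack = standardize(ff.raw_stack, self.standardization_)
        prob = predict_proba(self.model_, stack, ff.frame.border_mask)
        bg = np.zeros_like(ff.frame.border_mask)
        if "unsupervised" in self.sampling_stages:
            thr, _ = unsupervised_threshold(
                ff.frame.enhanced.pixels, ff.frame.border_mask
            )
            bg = (ff.frame.enhanced.pixels > thr) & ff.frame.border_mask
        return prob, ff.frame.border_mask, bg

    def segment(
        self, angiogram: Angiogram, truth: VesselMask
    ) -> SegmentationResult:
        prob, border, bg = self.predict_frame(angiogram)
        return evaluate_frame(prob, truth.labels, border, bg)

    def evaluate(self, pairs: list[tuple[Angiogram, VesselMask]]):
        """Segment every pair; returns (results, image-wise summary table)."""
        results = [self.segment(a, m) for a, m in pairs]
        return results, summarize_results(results)

    def test_pairs(self, pairs):
        """The held-out pairs of the fitted split."""
        ids = set(self.split_.ids("test"))
        return [(a, m) for a, m in pairs if a.image_id in ids]


def baseline_frangi_otsu(
    frame: PreprocessedFrame, truth: VesselMask
) -> SegmentationResult:
    """Single-feature baseline: Frangi z_max, Otsu threshold, cleanup.

    The reference point any learned pipeline must beat: it uses the best
    single filter map and no classifier.
    """
    from .features_filter import frangi_zprofile

    zp = frangi_zprofile(frame.diffused, frame.scale_set)
    resp = zp.z_max
    lo, hi = resp.min(), resp.max()
    prob = (resp - lo) / (hi - lo) if hi > lo else np.zeros_like(resp)
    mask = binarize(prob)
    mask = postprocess(mask, frame.border_mask)
    mets = metrics(mask, truth.labels, frame.border_mask)
    mets["auroc"] = auroc(prob, truth.labels, frame.border_mask)
    return SegmentationResult(probability_map=prob, mask=mask, metrics=mets)
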