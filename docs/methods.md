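# Methods

`vesselforge` segments contrast-filled coronary arteries in X-ray
angiography (XCA) frames by classifying every pixel with an ensemble model
trained on a compact, physically-anchored feature vector. This note records
the model, its assumptions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Problem setting and assumptions

An XCA frame is a 512×512 gray-scale projection in which arteries appear as
dark, tree-structured tubes on a brighter, non-uniformly illuminated
background, confounded by the injection catheter, spine/rib shadows and
image noise. Vessel pixels are a small minority — about 5–6% of a frame —
and neighboring pixels carry nearly identical information. The catheter
diameter in pixels ("Cath", mean 8.0 ± 1.2 px) is the physical length
reference: filter scales are tied to it, and ground-truth annotation covers
only vessels with diameter ≥ 0.75 × Cath. When no catheter metadata is
available the mean value 8.0 px is assumed.

## Scale space and the Z-profile

Every filter is evaluated over a scale set Λ of `n_scales` values
log-spaced from 0.66 × Cath to 6.33 × Cath. The per-pixel response vector
across scales is condensed into four statistics — maximum, mean, variance,
and interquartile range — called the Z-profile. Two conventions are fixed
here because the summary values depend on them: the variance is the
population variance (divide by the number of scales), and quartiles use
linear interpolation between order statistics. `n_scales` defaults to 10.

## Preprocessing

1. **Border exclusion.** Pixels outside the imaging window (a dark frame or
   circular collimator shadow, detected as near-constant regions connected
   to the frame edge) are excluded from sampling and evaluation.
2. **Denoising** with non-local means; patch size 5, search radius 5, and
   filter strength h = 0.8 × the noise std estimated from the image.
3. **Contrast enhancement.** With disk structuring elements SE_λ of
   diameter λ over the scale set,
   `I_top = max_λ (I − opening(I, SE_λ))`,
   `I_bottom = max_λ (closing(I, SE_λ) − I)`, and
   `I_enhanced = clip(I + m·I_top − n·I_bottom, 0, 1)`.
   The strengths default to m = n = 1 (configurable). Disks were chosen for
   rotation invariance; enhancement brightens small bright structures and
   deepens dark ones, so dark vessels gain contrast and clear background
   saturates — a property the intensity-based under-sampling stage exploits.
4. **Vesselness-steered diffusion** (5 iterations, step 0.15): a diffusion
   tensor built from the Hessian at a mid-range scale smooths along the
   vessel direction and suppresses diffusion across it where the local
   tubularity is high.

## Features (21 filter-based + 16 deep = 37)

Differentiable domain (13): Z-profiles of (a) Frangi vesselness with
dark-ridge polarity, β = 0.5, structural constant at half the maximum
Hessian norm, Hessian scale σ = λ/2; (b) oriented Gaussian matched filters
(12 orientations at 15° steps, cross-section σ = λ/3, length 3λ, zero-mean,
normalized by ‖k‖·√length so the response measures cross-section shape
match rather than growing with kernel length); (c) Gaussian-smoothed
gradient magnitude at σ = λ/2; plus (d) one vessel-confidence map — the
normalized cross-correlation between the local patch and the ideal dark-bar
profile, max-pooled over orientations and scales and clipped to [0,1].

Spatial domain (4): Z-profile of the granulometric decomposition of the
enhanced image — residues `opening(I, SE_{λk−1}) − opening(I, SE_{λk})`,
the bright content between consecutive size classes.

Frequency domain (4): Z-profile of a real, DC-corrected Gabor bank
(12 orientations, unit aspect ratio, wavelength λ) applied to the
complement of the enhanced image, where vessels are bright.

Deep features (16): the activation maps of the final decoder layer of a
small two-level encoder–decoder with skip connections (dense 3×3 blocks,
16-channel final decoder layer, 1-channel sigmoid head), implemented
directly on numpy with im2col convolutions and manual backpropagation so
training is CPU-friendly and bit-deterministic under a seed. The network
is trained on synthetic pairs with the Generalized Dice loss
(t = 2 classes, background map = 1 − sigmoid output, ε = 1e-8 in the class
weights), Adam at 1e-3, batch 8, up to 100 epochs with early stopping after
15 non-improving validation epochs, and affine augmentation (probability
0.7; rotation ±20°, shift up to 10% per axis, zoom up to 10%). Only the
16-channel final-decoder contract matters downstream; the deep path is
optional and the pipeline runs in 21-feature mode without a checkpoint.

Each feature map is standardized by the per-feature mean/std pooled over
the in-border training pixels; the saved parameters transform validation
and test data unchanged. Zero-spread features standardize to zeros with a
warning.

## Under-sampling cascade

Applied per frame, majority (background) class first:

1. **Uniform**: a stride-2 lattice (offset rotated per frame) keeps at most
   25% of background pixels with no two retained pixels 8-adjacent.
2. **Unsupervised**: on the enhanced image's 256-bin histogram, the bin
   where the raw pdf most exceeds its 5-bin-median-filtered version marks
   the saturation peak; excluding that peak's pixels, the median intensity
   is the threshold, and brighter negatives (clear background) are dropped.
   The dropped set is kept as the "unsupervised background mask" and reused
   at post-processing time.
3. **Tomek links**: opposite-label mutual-nearest-neighbor pairs (Euclidean
   metric on standardized features) are removed, both members, iterated to
   a fixpoint so the operation is idempotent.
4. **Cluster centroids**: each class is replaced by k-means centroids
   (a fixed per-class count, default 4,000 per frame), giving an exactly
   balanced 50/50 set of synthesized rows.

Stages 3–4 run per frame rather than on the pooled training set: with 104
training frames and 4,000 centroids per class this is what makes the final
set 104 × 2 × 4,000 = 832,000 rows; a pooled application would collapse it
to 8,000. A per-stage audit report records counts and class percentages.

## Classifiers

- **GBDT**: scikit-learn gradient boosting with deviance loss and
  Friedman-MSE split criterion. The tuning grid is learning rate
  {0.01, 0.05, 0.1} × stages {100, 500, 1000, 2000} × depth {3, 5, 10, 20},
  scored by mean pooled validation AUROC over 4 cyclic folds: training
  frames are ordered, cut into 4 blocks, and the validation block rotates
  (3:1 within each fold), with standardization re-fit inside each fold.
  Pooled (rather than per-image-averaged) fold AUROC was chosen for
  variance reduction at small validation sizes.
- **Cascade forest** ("deep forest"): self-contained layers of 2 random
  forests + 2 completely-random forests (extra-trees with single-feature
  splits), each layer consuming the original features plus the previous
  layer's class-probability vectors (width D + 8). Layer probabilities are
  estimated by internal 3-fold cross-validation; depth grows while the
  cross-validated accuracy improves (cap 5 layers).

Splits are image-level and stratified by view label (LCA/RCA) and source;
the 4:1 ensemble split reuses the 3:1:1 deep-learning split's test frames,
so no pixel of a test frame ever enters training or tuning of either path.

## Post-processing and evaluation

Probability maps are thresholded with Otsu's method (256 levels, ties
toward the lower threshold); border pixels and unsupervised-background
pixels are forced to background; 8-connected components smaller than 50
pixels are removed (8-connectivity chosen, configurable). Six metrics are
computed image-wise over in-border pixels — precision, sensitivity,
specificity, F1, IoU, and AUROC — and reported as mean ± std over test
frames. AUROC uses the pre-binarization probability map, the only
information-bearing choice. Zero-denominator metrics are reported as
undefined (None), never coerced to 0, so image-wise averages are not
silently biased. Permutation importance permutes each feature column 10
times on held-out pixels and reports the mean increase of the squared-error
criterion over the unpermuted baseline.

## Synthetic data

Because clinical angiograms are private, the generator emulates their
statistical structure: a connected tree of polyline segments rooted at one
frame edge (child diameters strictly thinner than parents, all within
[0.3, 2.0] × Cath), rendered as dark tubes with inverted-Gaussian
cross-sections whose depth grows with diameter; per-frame Cath drawn from
Normal(8.0, 1.2) truncated positive; a vessel-pixel fraction calibrated to
5.6% (the generator adjusts the annotated width by a global factor until
the realized fraction is within 0.4 percentage points of target); LCA/RCA
labels at an 80:50 ratio; and three confounders — a straight low-contrast
catheter tube, 2–3 broad soft vertical bands, and a planar illumination
gradient — chosen to be exactly the structures that defeat naive intensity
thresholding. Segments thinner than 0.75 × Cath are rendered but excluded
from the mask, mimicking the annotation protocol.

What the generator does **not** emulate: projection foreshortening and
vessel overlap from varying acquisition angles, temporal dye dynamics,
heart-motion blur, and realistic X-ray noise statistics. Passing tests on
synthetic data therefore demonstrate the mechanics and internal consistency
of the pipeline, not clinical-grade accuracy.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full pipeline at reduced
problem sizes chosen as the package's own desk-scale defaults: bookkeeping
checks use the full 130 frames at 512×512 (generation only), while the
end-to-end training runs use 20 frames at 256×256 with a fixed GBDT
configuration (learning rate 0.1, 100 stages, depth 3) instead of the full
tuning grid, whose 192 fits are exercised structurally on toy folds.
Degenerate inputs are handled explicitly throughout: constant images keep
all negatives in the intensity stage (with a warning), constant probability
maps binarize to all-background, single-class inputs are rejected by the
classifiers, and k-means targets larger than a class fall back to the
whole class.

## Known limitations

- The vessel-confidence measure is a normalized-correlation stand-in with
  the stated definition; published variants of such confidence measures
  differ in detail.
- The diffusion scheme is a compact vesselness-steered tensor diffusion,
  not a full reimplementation of any specific published discretization.
- The cascade forest uses fixed internal defaults (50 trees per forest);
  it is intentionally small for CPU training.
- Image-level stratification assumes the view label is known; with unknown
  labels all frames fall into one stratum.
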