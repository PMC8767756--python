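"""Multi-scale filter-based per-pixel features.

Twenty-one features in three domains, each a function of the catheter-anchored
scale set:

* differentiable (13): Z-profiles of Frangi vesselness, of oriented
  Gaussian matched filters, and of the Gaussian-smoothed gradient magnitude
  (4 each), plus a single vessel-confidence map;
* spatial (4): Z-profile of the granulometric (size-class) decomposition of
  the contrast-enhanced image;
* frequency (4): Z-profile of an oriented Gabor bank applied to the
  complement of the contrast-enhanced image.

Deep features (16 decoder activation maps) are appended by
:func:`assemble_stack` when available, giving the full 37-map stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_gradient_magnitude
from scipy.signal import fftconvolve
from skimage.filters import frangi as _frangi
from skimage.filters import gabor_kernel
from skimage.morphology import opening

from .preprocess import EnhancedImage, ScaleSet, _se
from .scalespace import ZProfile, zprofile

N_ORIENTATIONS = 12  # 15-degree steps over half the circle
N_DIFFERENTIABLE = 13
N_FILTER_FEATURES = 21
N_DEEP_FEATURES = 16
N_TOTAL_FEATURES = 37


# ---------------------------------------------------------------------------
# differentiable domain


def frangi_zprofile(image: np.ndarray, scale_set: ScaleSet) -> ZProfile:
    """Frangi vesselness at Hessian scale sigma = lambda/2 per scale.

    Dark-ridge polarity (contrast-filled vessels are dark); beta = 0.5 and
    the structural constant at half the maximum Hessian norm per image.
    """
    stack = np.stack(
        [
            _frangi(image, sigmas=[lam / 2.0], beta=0.5, black_ridges=True)
            for lam in scale_set
        ]
    )
    return zprofile(stack, "frangi")


def _conv(image: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Correlation with reflect padding so constants respond exactly per the
    kernel sum everywhere (no zero-padding boundary artifacts)."""
    ry, rx = kernel.shape[0] // 2, kernel.shape[1] // 2
    padded = np.pad(image, ((ry, ry), (rx, rx)), mode="reflect")
    out = fftconvolve(padded, kernel, mode="same")
    return out[ry : ry + image.shape[0], rx : rx + image.shape[1]]


def _matched_kernel(scale: float, theta: float) -> np.ndarray:
    """Oriented Gaussian-profile matched-filter kernel, zero mean.

    ``theta`` is the vessel direction (angle of the bar the kernel matches,
    measured like the image-grid angle of a line row = col*tan(theta)).
    Cross-section sigma = scale/3, length 3*scale; the profile is negated so
    dark vessels give positive responses; the mean over the rectangular
    support is removed so constant regions respond zero.
    """
    sigma = scale / 3.0
    half_len = 1.5 * scale
    half_wid = max(3.0 * sigma, 2.0)
    r = int(np.ceil(max(half_len, half_wid)))
    y, x = np.mgrid[-r : r + 1, -r : r + 1].astype(float)
    u = -x * np.sin(theta) + y * np.cos(theta)  # across the vessel
    v = x * np.cos(theta) + y * np.sin(theta)  # along the vessel
    support = (np.abs(v) <= half_len) & (np.abs(u) <= half_wid)
    k = np.where(support, -np.exp(-(u**2) / (2 * sigma**2)), 0.0)
    k[support] -= k[support].mean()
    # normalize by ||k|| * sqrt(length): the response to an elongated bar then
    # measures cross-section shape match only (scale-selective), instead of
    # growing with however much bar the longer kernels happen to cover
    norm = np.linalg.norm(k) * np.sqrt(2 * half_len + 1)
    if norm > 0:
        k /= norm
    return k


def _orientations(n: int = N_ORIENTATIONS) -> np.ndarray:
    return np.arange(n) * np.pi / n


def matched_filter_zprofile(
    image: np.ndarray, scale_set: ScaleSet, n_orientations: int = N_ORIENTATIONS
) -> ZProfile:
    """Max-over-orientation matched-filter response per scale, Z-profiled."""
    maps = []
    for lam in scale_set:
        best = None
        for theta in _orientations(n_orientations):
            resp = _conv(image, _matched_kernel(lam, theta))
            best = resp if best is None else np.maximum(best, resp)
        maps.append(best)
    return zprofile(np.stack(maps), "matched")


def gradient_magnitude_zprofile(image: np.ndarray, scale_set: ScaleSet) -> ZProfile:
    """Gaussian-smoothed gradient magnitude at sigma = lambda/2 per scale."""
    stack = np.stack(
        [gaussian_gradient_magnitude(image, sigma=lam / 2.0) for lam in scale_set]
    )
    return zprofile(stack, "gradient")


def vessel_confidence(
    image: np.ndarray, scale_set: ScaleSet, n_orientations: int = N_ORIENTATIONS
) -> np.ndarray:
    """Normalized agreement between the local cross-section and an ideal
    dark-bar profile, max-pooled over orientations and scales.

    Implemented as a normalized cross-correlation: the zero-mean matched
    kernel response divided by the local (support-windowed) intensity
    spread, clipped to [0,1].  Constant regions score exactly zero.
    """
    conf = np.zeros_like(image, dtype=float)
    img2 = image * image
    for lam in scale_set:
        for theta in _orientations(n_orientations):
            k = _matched_kernel(lam, theta)
            support = (k != 0).astype(float)
            nsup = support.sum()
            norm = np.linalg.norm(k)
            if norm == 0 or nsup == 0:
                continue
            num = _conv(image, k / norm)
            s1 = _conv(image, support)
            s2 = _conv(img2, support)
            ss = np.maximum(s2 - s1 * s1 / nsup, 1e-12)
            ncc = num / np.sqrt(ss)
            conf = np.maximum(conf, ncc)
    return np.clip(conf, 0.0, 1.0)


# ---------------------------------------------------------------------------
# spatial domain


def granular_zprofile(enhanced: EnhancedImage, scale_set: ScaleSet) -> ZProfile:
    """Granulometric residues of the contrast-enhanced image.

    Residue at scale lambda_k is opening(I, SE_{k-1}) - opening(I, SE_k)
    (with SE_0 the identity): the bright content living between consecutive
    size classes.  Residues are non-negative and their sum is bounded by the
    image (anti-extensivity of the opening chain).
    """
    img = enhanced.pixels
    prev = img
    maps = []
    for lam in scale_set:
        opened = opening(img, _se(lam))
        maps.append(prev - opened)
        prev = opened
    return zprofile(np.stack(maps), "granular")


# ---------------------------------------------------------------------------
# frequency domain


def _gabor_real_kernel(scale: float, theta: float) -> np.ndarray:
    """Real Gabor kernel with wavelength = scale, unit aspect ratio,
    DC-corrected so constant images respond zero.

    ``theta`` follows the same bar-direction convention as the matched
    filter (the underlying harmonic oscillates across the bar).
    """
    k = np.real(gabor_kernel(frequency=1.0 / scale, theta=theta + np.pi / 2))
    return k - k.mean()


def gabor_zprofile(
    complement: np.ndarray, scale_set: ScaleSet, n_orientations: int = N_ORIENTATIONS
) -> ZProfile:
    """Max-over-orientation real Gabor response per scale, Z-profiled.

    Applied to the complement of the enhanced image, where vessels appear
    bright, matching the positive lobe of the even Gabor kernel.
    """
    maps = []
    for lam in scale_set:
        best = None
        for theta in _orientations(n_orientations):
            resp = _conv(complement, _gabor_real_kernel(lam, theta))
            best = resp if best is None else np.maximum(best, resp)
        maps.append(best)
    return zprofile(np.stack(maps), "gabor")


# ---------------------------------------------------------------------------
# assembly and standardization


@dataclass
class FeatureStack:
    """Named per-pixel feature maps for one frame.

    maps has shape (D, H, W) with D = 21 (filter-only) or 37 (with deep
    features); names are unique and ordered; standardization holds the
    per-map (mean, std) recorded from the training set, or None before
    standardization.
    """

    maps: np.ndarray
    names: list[str]
    standardization: dict | None = None

    def __post_init__(self):
        if self.maps.shape[0] != len(self.names):
            raise ValueError("one name per map required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    @property
    def n_features(self) -> int:
        return self.maps.shape[0]

    def as_matrix(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Flatten to (N, D) over all pixels or the True pixels of mask."""
        flat = self.maps.reshape(self.n_features, -1).T
        if mask is None:
            return flat
        return flat[mask.ravel()]


def assemble_stack(
    frangi: ZProfile,
    matched: ZProfile,
    gradient: ZProfile,
    confidence: np.ndarray,
    granular: ZProfile,
    gabor: ZProfile,
    deep_maps: np.ndarray | None = None,
) -> FeatureStack:
    """Concatenate all feature maps in the canonical documented order.

    Order: frangi (4), matched (4), gradient (4), confidence (1),
    granular (4), gabor (4), then deep.01..deep.16 when provided.
    """
    named: list[tuple[str, np.ndarray]] = []
    for zp in (frangi, matched, gradient):
        named.extend(zp.maps())
    named.append(("confidence", confidence))
    for zp in (granular, gabor):
        named.extend(zp.maps())
    if deep_maps is not None:
        deep_maps = np.asarray(deep_maps)
        if deep_maps.shape[0] != N_DEEP_FEATURES:
            raise ValueError(f"expected {N_DEEP_FEATURES} deep maps")
        for i in range(deep_maps.shape[0]):
            named.append((f"deep.{i + 1:02d}", deep_maps[i]))

    shape = named[0][1].shape
    for name, arr in named:
        if arr.shape != shape:
            raise ValueError(f"shape mismatch for map {name!r}")
    return FeatureStack(
        maps=np.stack([arr for _, arr in named]),
        names=[name for name, _ in named],
    )


def fit_standardization(
    stacks: list[FeatureStack], masks: list[np.ndarray] | None = None
) -> dict:
    """Per-feature (mean, std) pooled over the training stacks.

    masks optionally restrict the pixels entering the estimate (e.g. the
    border-valid region).  Features with zero spread get std=0 recorded;
    :func:`standardize` maps them to zeros.
    """
    names = stacks[0].names
    sums = np.zeros(len(names))
    sqs = np.zeros(len(names))
    count = 0
    for i, st in enumerate(stacks):
        if st.names != names:
            raise ValueError("stacks must share the feature manifest")
        X = st.as_matrix(None if masks is None else masks[i])
        sums += X.sum(axis=0)
        sqs += (X * X).sum(axis=0)
        count += X.shape[0]
    mean = sums / count
    var = np.maximum(sqs / count - mean**2, 0.0)
    std = np.sqrt(var)
    return {name: (float(m), float(s)) for name, m, s in zip(names, mean, std)}


def standardize(stack: FeatureStack, params: dict | None = None) -> FeatureStack:
    """Standardize each map by its own (or saved training) mean/std.

    Fit mode (params=None) estimates per-map statistics from this stack;
    transform mode applies the supplied training parameters unchanged.
    Zero-spread maps standardize to all zeros with a warning.
    """
    if params is None:
        params = fit_standardization([stack])
    out = np.empty_like(stack.maps, dtype=float)
    for i, name in enumerate(stack.names):
        mu, sd = params[name]
        if sd <= 0:
            warnings.warn(f"feature {name!r} has zero spread; standardized to zeros")
            out[i] = 0.0
        else:
            out[i] = (stack.maps[i] - mu) / sd
    return FeatureStack(maps=out, names=list(stack.names), standardization=dict(params))


def extract_filter_features(frame, n_orientations: int = N_ORIENTATIONS) -> FeatureStack:
    """All 21 filter-based features from a :class:`PreprocessedFrame`."""
    img = frame.diffused
    ss = frame.scale_set
    return assemble_stack(
        frangi=frangi_zprofile(img, ss),
        matched=matched_filter_zprofile(img, ss, n_orientations),
        gradient=gradient_magnitude_zprofile(img, ss),
        confidence=vessel_confidence(img, ss, n_orientations),
        granular=granular_zprofile(frame.enhanced, ss),
        gabor=gabor_zprofile(1.0 - frame.enhanced.pixels, ss, n_orientations),
    )
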