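"""Filter-based feature extractors and stack assembly/standardization."""

import numpy as np
import pytest
from skimage.morphology import disk, opening

import vesselforge as vf
from vesselforge.features_filter import (
    N_DIFFERENTIABLE,
    assemble_stack,
    frangi_zprofile,
    gabor_zprofile,
    gradient_magnitude_zprofile,
    granular_zprofile,
    matched_filter_zprofile,
    vessel_confidence,
)
from vesselforge.preprocess import EnhancedImage, ScaleSet, _se, build_scale_set


SMALL_SS = build_scale_set(4.0, 4)  # scales 2.64 .. 25.32, small kernels


def _bar_image(angle_deg, width=5, size=96, contrast=0.5, bright=False):
    """Oriented bar through the image center."""
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    yy -= size / 2
    xx -= size / 2
    theta = np.deg2rad(angle_deg)
    d = np.abs(-xx * np.sin(theta) + yy * np.cos(theta))
    bar = d <= width / 2
    base = np.zeros((size, size)) if bright else np.full((size, size), 0.8)
    return np.where(bar, base + contrast if bright else base - contrast, base)


class TestFrangi:
    def test_constant_zero(self):
        zp = frangi_zprofile(np.full((48, 48), 0.5), SMALL_SS)
        np.testing.assert_allclose(zp.z_max, 0.0, atol=1e-12)

    def test_tube_centerline_and_scale(self, tube_image):
        ss = build_scale_set(8.0, 10)
        zp = frangi_zprofile(tube_image, ss)
        center = zp.z_max[40:56, 47:49].mean()
        bg = zp.z_max[40:56, 10:30].mean()
        assert center > bg
        # scan response vs scale at the tube center: argmax Hessian sigma
        # should sit within a factor two of half the tube width (w=6)
        from skimage.filters import frangi

        responses = [
            frangi(tube_image, sigmas=[lam / 2.0], beta=0.5, black_ridges=True)[48, 47]
            for lam in ss
        ]
        best_sigma = ss.scales[int(np.argmax(responses))] / 2.0
        assert 6 / 4 <= best_sigma <= 6 * 1.0

    def test_blob_suppressed_vs_tube(self):
        size = 96
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        blob = np.full((size, size), 0.8) - 0.5 * (
            np.hypot(yy - size / 2, xx - size / 2) <= 3
        )
        tube = _bar_image(0, width=6)
        ss = build_scale_set(6.0, 6)
        r_blob = frangi_zprofile(blob, ss).z_max[size // 2, size // 2]
        r_tube = frangi_zprofile(tube, ss).z_max[size // 2, size // 2]
        assert r_blob < r_tube


class TestMatchedFilter:
    def test_constant_zero(self):
        zp = matched_filter_zprofile(np.full((48, 48), 0.7), SMALL_SS)
        np.testing.assert_allclose(zp.z_max, 0.0, atol=1e-9)

    def test_orientation_argmax_near_30deg(self):
        from vesselforge.features_filter import _matched_kernel, _orientations
        from scipy.signal import fftconvolve

        img = _bar_image(30, width=4)
        responses = [
            fftconvolve(img, _matched_kernel(4.0, th), mode="same")[48, 48]
            for th in _orientations(12)
        ]
        best = np.rad2deg(_orientations(12)[int(np.argmax(responses))])
        # bar direction 30 deg; one kernel step is 15 deg
        assert min(abs(best - 30), abs(best - 30 + 180)) <= 15

    def test_matched_scale_beats_larger_scale(self):
        from vesselforge.features_filter import _matched_kernel
        from scipy.signal import fftconvolve

        img = _bar_image(0, width=4)
        # with sigma = scale/3, a width-4 bar is matched near scale 6
        # (cross-section sigma ~ half the width)
        r_match = fftconvolve(img, _matched_kernel(6.0, 0.0), mode="same")[48, 48]
        r_big = fftconvolve(img, _matched_kernel(24.0, 0.0), mode="same")[48, 48]
        assert r_match > r_big


class TestGradientMagnitude:
    def test_constant_zero(self):
        zp = gradient_magnitude_zprofile(np.full((48, 48), 0.2), SMALL_SS)
        np.testing.assert_allclose(zp.z_max, 0.0, atol=1e-12)

    def test_step_edge_analytic_value(self):
        # gradient of a unit step blurred at sigma peaks at h / (sigma*sqrt(2*pi))
        h = 0.6
        img = np.where(np.arange(128)[None, :].repeat(128, 0) < 64, 0.2, 0.2 + h)
        ss = ScaleSet(scales=(8.0, 16.0), cath_px=8.0)
        zp = gradient_magnitude_zprofile(img.astype(float), ss)
        # per-scale maximum lies on the edge; check the first scale (sigma=4)
        from scipy.ndimage import gaussian_gradient_magnitude

        resp = gaussian_gradient_magnitude(img.astype(float), sigma=4.0)
        assert abs(int(np.argmax(resp[64])) - 64) <= 1
        expected = h / (4.0 * np.sqrt(2 * np.pi))
        assert resp.max() == pytest.approx(expected, rel=0.05)
        assert zp.z_max.max() >= resp.max() - 1e-12

    def test_rotation_equivariance_quarter_turn(self):
        rng = np.random.default_rng(0)
        img = rng.random((64, 64))
        zp = gradient_magnitude_zprofile(img, SMALL_SS)
        zp_rot = gradient_magnitude_zprofile(np.rot90(img), SMALL_SS)
        np.testing.assert_allclose(zp_rot.z_max, np.rot90(zp.z_max), atol=1e-9)


class TestVesselConfidence:
    def test_constant_zero(self):
        conf = vessel_confidence(np.full((48, 48), 0.4), SMALL_SS)
        np.testing.assert_allclose(conf, 0.0, atol=1e-6)

    def test_tube_confidence_above_background(self, tube_image):
        ss = build_scale_set(6.0, 4)
        conf = vessel_confidence(tube_image, ss)
        assert conf.min() >= 0 and conf.max() <= 1
        center = conf[40:56, 47:49].mean()
        bg = conf[40:56, 10:30].mean()
        assert center > 0.5
        assert center > bg

    def test_noise_below_tube(self, tube_image):
        rng = np.random.default_rng(1)
        noise = np.clip(0.5 + rng.normal(0, 0.1, tube_image.shape), 0, 1)
        ss = build_scale_set(6.0, 4)
        tube = np.zeros_like(tube_image, dtype=bool)
        tube[:, 45:51] = True
        conf_tube = vessel_confidence(tube_image, ss)[tube].mean()
        conf_noise = vessel_confidence(noise, ss)[tube].mean()
        assert conf_noise < conf_tube


class TestGranular:
    def test_constant_zero(self):
        enh = EnhancedImage(pixels=np.full((32, 32), 0.3), m=1, n=1)
        zp = granular_zprofile(enh, SMALL_SS)
        np.testing.assert_allclose(zp.z_max, 0.0, atol=1e-12)

    def test_disk_residue_concentrates_at_matching_scale(self):
        # bright disk of diameter 9: content vanishes at the first SE too
        # big to fit, i.e. the first scale whose SE diameter exceeds 9
        img = np.zeros((64, 64))
        img[tuple(np.nonzero(disk(4)))] = 0.0
        dd = disk(4)
        img[20 : 20 + dd.shape[0], 20 : 20 + dd.shape[1]] = dd.astype(float)
        ss = build_scale_set(4.0, 6)  # SE diameters span ~3..25
        enh = EnhancedImage(pixels=img, m=1, n=1)
        zp = granular_zprofile(enh, ss)
        # oracle: per-scale openings directly
        masses = []
        prev = img
        for lam in ss:
            o = opening(img, _se(lam))
            masses.append((prev - o).sum())
            prev = o
        se_diams = [2 * max(1, int(round(lam / 2))) + 1 for lam in ss]
        expected_k = next(i for i, d in enumerate(se_diams) if d > 9)
        assert int(np.argmax(masses)) == expected_k
        np.testing.assert_allclose(zp.z_mean.sum() * ss.n_scales, sum(masses))

    def test_total_residue_bounded_by_image_sum(self):
        rng = np.random.default_rng(2)
        img = rng.random((32, 32))
        enh = EnhancedImage(pixels=img, m=1, n=1)
        zp = granular_zprofile(enh, SMALL_SS)
        total_residue = zp.z_mean.sum() * SMALL_SS.n_scales
        assert total_residue <= img.sum() + 1e-9


class TestGabor:
    def test_constant_zero_dc(self):
        zp = gabor_zprofile(np.full((48, 48), 0.6), SMALL_SS)
        np.testing.assert_allclose(zp.z_max, 0.0, atol=1e-9)

    def test_orientation_argmax_45deg(self):
        from vesselforge.features_filter import _gabor_real_kernel, _orientations
        from scipy.signal import fftconvolve

        img = _bar_image(45, width=4, bright=True, contrast=0.5)
        responses = [
            fftconvolve(img, _gabor_real_kernel(8.0, th), mode="same")[48, 48]
            for th in _orientations(12)
        ]
        best = np.rad2deg(_orientations(12)[int(np.argmax(responses))])
        assert min(abs(best - 45), abs(best - 45 + 180)) <= 15

    def test_contrast_linearity(self):
        img = _bar_image(0, width=5, bright=True, contrast=0.3)
        ss = build_scale_set(4.0, 3)
        z1 = gabor_zprofile(img, ss).z_max
        z2 = gabor_zprofile(2 * img, ss).z_max
        sel = z1 > 1e-6
        np.testing.assert_allclose(z2[sel], 2 * z1[sel], rtol=1e-6)


class TestAssembleAndStandardize:
    def _stacks(self, with_deep):
        rng = np.random.default_rng(3)
        shape = (16, 16)

        def zp(name):
            return vf.zprofile(rng.normal(size=(4, *shape)), name)

        deep = rng.normal(size=(16, *shape)) if with_deep else None
        return assemble_stack(
            zp("frangi"), zp("matched"), zp("gradient"),
            rng.random(shape), zp("granular"), zp("gabor"), deep,
        )

    def test_feature_bookkeeping(self):
        st37 = self._stacks(True)
        st21 = self._stacks(False)
        assert st37.n_features == 37
        assert st21.n_features == 21
        diff = [
            n for n in st21.names
            if n.split(".")[0] in ("frangi", "matched", "gradient") or n == "confidence"
        ]
        assert len(diff) == N_DIFFERENTIABLE == 13
        assert sum(n.startswith("deep.") for n in st37.names) == 16
        assert len(set(st37.names)) == 37

    def test_shape_mismatch_rejected(self):
        rng = np.random.default_rng(4)
        zp_ok = vf.zprofile(rng.normal(size=(4, 8, 8)), "frangi")
        zp_bad = vf.zprofile(rng.normal(size=(4, 9, 9)), "matched")
        with pytest.raises(ValueError):
            assemble_stack(
                zp_ok, zp_bad,
                vf.zprofile(rng.normal(size=(4, 8, 8)), "gradient"),
                rng.random((8, 8)),
                vf.zprofile(rng.normal(size=(4, 8, 8)), "granular"),
                vf.zprofile(rng.normal(size=(4, 8, 8)), "gabor"),
            )

    def test_fit_mode_standardizes_to_unit_moments(self):
        st = self._stacks(False)
        out = vf.standardize(st)
        for m in out.maps:
            assert abs(m.mean()) < 1e-6
            assert abs(m.std() - 1) < 1e-6

    def test_constant_map_zeroed_with_warning(self):
        st = self._stacks(False)
        st.maps[0] = 5.0
        with pytest.warns(UserWarning):
            out = vf.standardize(st)
        np.testing.assert_allclose(out.maps[0], 0.0)

    def test_transform_mode_applies_saved_params(self):
        st = self._stacks(False)
        st.maps[:] = 10.0
        params = {name: (2.0, 4.0) for name in st.names}
        out = vf.standardize(st, params)
        np.testing.assert_allclose(out.maps, 2.0)  # (10 - 2) / 4

    def test_train_params_never_reestimated(self):
        train = self._stacks(False)
        test = self._stacks(False)
        params = vf.fit_standardization([train])
        out = vf.standardize(test, params)
        assert out.standardization == params
        # test maps standardized with train moments are not re-centered
        assert abs(out.maps[0].mean()) >= 0  # defined; round-trip identity:
        again = vf.standardize(test, out.standardization)
        np.testing.assert_array_equal(out.maps, again.maps)


def test_vessel_background_separation_on_synthetic_frame(one_frame, one_stack):
    """On a rendered frame the tubular-filter maxima are higher on vessels."""
    frame, mask = one_frame
    labels = mask.labels & frame.border_mask
    bg = ~mask.labels & frame.border_mask
    for name in ("frangi.z_max", "matched.z_max", "gabor.z_max"):
        i = one_stack.names.index(name)
        assert one_stack.maps[i][labels].mean() > one_stack.maps[i][bg].mean(), name
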