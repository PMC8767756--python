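"""Under-sampling cascade: uniform lattice, intensity stage, Tomek, centroids."""

import warnings

import numpy as np
import pytest

import vesselforge as vf
from vesselforge.preprocess import EnhancedImage
from vesselforge.sampling import (
    PixelDataset,
    build_report,
    cluster_centroid,
    dataset_from_image,
    planned_centroid_rows,
    tomek_links,
    uniform_undersample,
    unsupervised_undersample,
)


class TestUniform:
    def test_small_frame_lattice(self):
        neg = np.ones((4, 4), dtype=bool)
        border = np.ones((4, 4), dtype=bool)
        kept = uniform_undersample(neg, border)
        assert kept.sum() == 4
        coords = np.argwhere(kept)
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                assert np.abs(coords[i] - coords[j]).max() >= 2  # Chebyshev

    def test_empty_negatives(self):
        kept = uniform_undersample(
            np.zeros((8, 8), dtype=bool), np.ones((8, 8), dtype=bool)
        )
        assert kept.sum() == 0

    def test_density_bounded_by_quarter(self):
        neg = np.ones((101, 101), dtype=bool)
        border = np.ones((101, 101), dtype=bool)
        kept = uniform_undersample(neg, border, offset=(1, 1))
        assert kept.mean() <= 0.25
        # no two retained pixels are 8-neighbors (vectorized shift check)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                shifted = np.roll(np.roll(kept, dr, 0), dc, 1)
                inner = np.zeros_like(kept)
                inner[1:-1, 1:-1] = True
                assert not (kept & shifted & inner).any()


class TestUnsupervised:
    def test_bimodal_fixture_removes_bright_mode(self):
        # enhancement clipping concentrates clear background in a single
        # saturated bin; the darker mode holds the tube and its surround
        rng = np.random.default_rng(0)
        img = np.full((64, 64), 0.9)  # saturated background mode
        dark = np.zeros((64, 64), dtype=bool)
        dark[:, 20:46] = True  # dark region: tube plus adjacent surround
        img[dark] = rng.uniform(0.1, 0.5, dark.sum())
        tube = np.zeros((64, 64), dtype=bool)
        tube[:, 30:36] = True
        enh = EnhancedImage(pixels=img, m=1, n=1)
        negatives = ~tube
        kept, bg_mask, thr = unsupervised_undersample(enh, negatives)
        # threshold falls between the modes (~0.3 vs 0.9)
        assert 0.1 < thr < 0.89
        # every saturated background negative was removed...
        assert not kept[img >= 0.9].any()
        assert bg_mask[img >= 0.9].all()
        # ...while dark tube-adjacent negatives survive
        assert kept[negatives & (img < thr)].all()
        assert kept.sum() > 0

    def test_saturation_spike_excluded_from_median(self):
        rng = np.random.default_rng(1)
        n = 10_000
        vals = np.concatenate(
            [np.ones(int(0.3 * n)), rng.uniform(0.0, 0.5, n - int(0.3 * n))]
        )
        rng.shuffle(vals)
        img = vals.reshape(100, 100)
        enh = EnhancedImage(pixels=img, m=1, n=1)
        from vesselforge.sampling import unsupervised_threshold

        thr, peak_bin = unsupervised_threshold(img)
        assert peak_bin == 255  # the saturated spike
        # threshold is the median of the non-saturated 70%
        expected = np.median(vals[vals < 1.0])
        assert thr == pytest.approx(expected, abs=0.01)

    def test_degenerate_constant_image_warns_and_keeps(self):
        img = np.full((16, 16), 0.5)
        enh = EnhancedImage(pixels=img, m=1, n=1)
        neg = np.ones((16, 16), dtype=bool)
        with pytest.warns(UserWarning):
            kept, bg, thr = unsupervised_undersample(enh, neg)
        assert (kept == neg).all()
        assert bg.sum() == 0

    def test_all_negatives_above_threshold_warns(self):
        # bright uniform negatives + a dark minority region driving the median
        rng = np.random.default_rng(2)
        img = np.clip(np.full((64, 64), 0.95) + rng.normal(0, 0.002, (64, 64)), 0, 1)
        img[:, :40] = rng.uniform(0.0, 0.3, (64, 40))
        enh = EnhancedImage(pixels=img, m=1, n=1)
        negatives = np.zeros((64, 64), dtype=bool)
        negatives[:, 40:] = True  # only the bright region is negative
        with pytest.warns(UserWarning):
            kept, _, _ = unsupervised_undersample(enh, negatives)
        assert kept.sum() == 0


def _brute_force_tomek(X, y):
    """O(N^2) link finder iterated to a fixpoint (independent oracle)."""
    keep = np.arange(len(y))
    while len(keep) >= 2 and len(np.unique(y[keep])) == 2:
        Xs, ys = X[keep], y[keep]
        d = np.sqrt(((Xs[:, None] - Xs[None]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        nn = d.argmin(axis=1)
        link = (nn[nn] == np.arange(len(ys))) & (ys != ys[nn])
        if not link.any():
            break
        keep = keep[~link]
    return keep


class TestTomek:
    def test_1d_example(self):
        X = np.array([[0.0], [0.1], [5.0]])
        y = np.array([1, 0, 0])
        ds = PixelDataset(features=X, labels=y)
        out = tomek_links(ds)
        assert out.n == 1
        assert out.features[0, 0] == 5.0

    def test_separated_clusters_identity(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, (20, 2))
        b = rng.normal(10, 0.1, (20, 2))
        ds = PixelDataset(
            features=np.vstack([a, b]), labels=np.r_[np.ones(20), np.zeros(20)]
        )
        out = tomek_links(ds)
        assert out.n == 40

    def test_matches_bruteforce_oracle_on_200_points(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 2))
        y = (rng.random(200) < 0.5).astype(int)
        ds = PixelDataset(features=X, labels=y)
        out = tomek_links(ds)
        keep = _brute_force_tomek(X, y)
        np.testing.assert_array_equal(
            np.sort(out.features, axis=0), np.sort(X[keep], axis=0)
        )

    def test_subset_and_idempotence(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(100, 3))
        y = (rng.random(100) < 0.4).astype(int)
        ds = PixelDataset(features=X, labels=y)
        once = tomek_links(ds)
        twice = tomek_links(once)
        assert once.n <= ds.n
        assert twice.n == once.n

    def test_single_class_warns_identity(self):
        ds = PixelDataset(features=np.random.rand(5, 2), labels=np.ones(5))
        with pytest.warns(UserWarning):
            out = tomek_links(ds)
        assert out.n == 5


class TestClusterCentroid:
    def test_k_equals_n_is_balanced_identity(self):
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 1, (10, 2)), rng.normal(5, 1, (10, 2))])
        y = np.r_[np.zeros(10), np.ones(10)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = cluster_centroid(PixelDataset(features=X, labels=y), 10, seed=0)
        assert out.n == 20
        assert out.positive_fraction == 0.5

    def test_blob_mean_recovery(self):
        rng = np.random.default_rng(7)
        sigma, n = 0.2, 200
        centers = {0: [(0, 0), (4, 4)], 1: [(8, 0), (12, 4)]}
        X, y = [], []
        for cls, cs in centers.items():
            for c in cs:
                X.append(rng.normal(c, sigma, (n, 2)))
                y.append(np.full(n, cls))
        ds = PixelDataset(features=np.vstack(X), labels=np.concatenate(y))
        out = cluster_centroid(ds, 2, seed=1)
        assert out.n == 4
        tol = 3 * sigma * np.sqrt(2 / n)  # 3-sigma band for a 2-D mean norm
        for cls, cs in centers.items():
            got = out.features[out.labels == cls]
            for c in cs:
                assert np.linalg.norm(got - np.array(c), axis=1).min() <= tol

    def test_exact_balance_from_imbalanced_input(self):
        rng = np.random.default_rng(8)
        X = np.vstack([rng.normal(0, 1, (500, 3)), rng.normal(3, 1, (80, 3))])
        y = np.r_[np.zeros(500), np.ones(80)]
        out = cluster_centroid(PixelDataset(features=X, labels=y), 50, seed=2)
        assert out.n == 100
        assert out.positive_fraction == 0.5  # exactly 50.000%
        assert out.origin is None

    def test_undersized_class_warns(self):
        X = np.random.rand(12, 2)
        y = np.r_[np.zeros(10), np.ones(2)]
        with pytest.warns(UserWarning):
            out = cluster_centroid(PixelDataset(features=X, labels=y), 5, seed=3)
        assert (out.labels == 1).sum() == 2


@pytest.fixture(scope="module")
def cascade_run(small_pairs):
    from vesselforge.pipeline import SegmentationPipeline
    from vesselforge.features_filter import fit_standardization, standardize
    from vesselforge.sampling import run_cascade

    pipe = SegmentationPipeline(seed=0)
    pairs = small_pairs[:3]
    feats = [pipe.extract(a) for a, _ in pairs]
    borders = [f.frame.border_mask for f in feats]
    params = fit_standardization([f.raw_stack for f in feats], borders)
    stacks = [standardize(f.raw_stack, params) for f in feats]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds, report, bgs = run_cascade(
            stacks,
            [m.labels for _, m in pairs],
            borders,
            [f.frame.enhanced for f in feats],
            per_class_target=200,
            seed=0,
        )
    return ds, report, bgs, borders


class TestCascadeAndReport:

    def test_totals_monotone_nonincreasing(self, cascade_run):
        _, report, _, _ = cascade_run
        totals = [r["total"] for r in report.rows]
        assert all(a >= b for a, b in zip(totals, totals[1:]))

    def test_percentages_sum_to_100(self, cascade_run):
        _, report, _, _ = cascade_run
        for r in report.rows:
            assert r["positive_pct"] + r["negative_pct"] == pytest.approx(100.0, abs=2e-3)

    def test_positives_untouched_until_tomek(self, cascade_run):
        _, report, _, _ = cascade_run
        by = {r["stage"]: r for r in report.rows}
        pos = {s: by[s]["total"] * by[s]["positive_pct"] / 100 for s in by}
        # percentages are rounded to 3 decimals in the report, so allow a
        # couple of counts of slack when reconstructing absolute numbers
        assert pos["raw"] == pytest.approx(pos["uniform"], abs=2)
        assert pos["raw"] == pytest.approx(pos["unsupervised"], abs=2)

    def test_final_stage_exactly_balanced(self, cascade_run):
        ds, report, _, _ = cascade_run
        assert ds.stage == "centroid"
        assert ds.n == 3 * 2 * 200
        assert ds.positive_fraction == 0.5

    def test_origins_inside_border(self, small_pairs, cascade_run):
        _, _, _, borders = cascade_run
        from vesselforge.pipeline import SegmentationPipeline

        # re-run just the coordinate-bearing stages and check containment
        pipe = SegmentationPipeline(seed=0)
        a, m = small_pairs[0]
        ff = pipe.extract(a)
        neg = ~m.labels & ff.frame.border_mask
        kept = uniform_undersample(neg, ff.frame.border_mask)
        assert not (kept & ~ff.frame.border_mask).any()

    def test_duplicate_origins_rejected(self):
        X = np.random.rand(2, 3)
        with pytest.raises(ValueError):
            PixelDataset(
                features=X, labels=np.zeros(2), origin=np.array([[0, 1, 1], [0, 1, 1]])
            )

    def test_report_csv_roundtrip(self, cascade_run, tmp_path):
        _, report, _, _ = cascade_run
        p = tmp_path / "report.csv"
        report.to_csv(p)
        import pandas as pd

        df = pd.read_csv(p)
        assert list(df.columns) == ["stage", "positive_pct", "negative_pct", "total"]
        assert len(df) == len(report.rows)


def test_planned_centroid_rows_arithmetic():
    assert planned_centroid_rows(3, 200) == 1200
    assert planned_centroid_rows(104, 4000) == 832_000
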