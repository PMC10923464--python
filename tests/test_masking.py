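"""Histogram K-means thresholds and cell-mask segmentation."""

import numpy as np
import pytest

from sodamap import (
    CellMask,
    HKParams,
    hierarchical_segment_cell_mask,
    kmeans_intensity_thresholds,
    segment_cell_mask,
)


def _exhaustive_two_class_threshold(values, n_bins=256):
    """Brute-force oracle: the histogram-bin boundary minimizing total
    within-class variance (independent of the Lloyd iteration).  With
    well-separated modes every cut through the empty gap is a minimizer,
    so the canonical representative is the midpoint of the optimal plateau.
    """
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    sse = np.full(n_bins, np.inf)
    for cut in range(1, n_bins):
        w1, w2 = counts[:cut].sum(), counts[cut:].sum()
        if w1 == 0 or w2 == 0:
            continue
        m1 = np.average(centers[:cut], weights=counts[:cut])
        m2 = np.average(centers[cut:], weights=counts[cut:])
        sse[cut] = (
            np.average((centers[:cut] - m1) ** 2, weights=counts[:cut]) * w1
            + np.average((centers[cut:] - m2) ** 2, weights=counts[cut:]) * w2
        )
    optimal = np.flatnonzero(sse <= sse.min() * (1 + 1e-12))
    return 0.5 * (edges[optimal[0]] + edges[optimal[-1]])


def _disk_image(shape=(128, 128), radius=20.0, fg=200.0, bg=10.0, noise=5.0, seed=0):
    rng = np.random.default_rng(seed)
    yy, xx = np.indices(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
    img = np.where(disk, fg, bg) + rng.normal(0.0, noise, shape)
    return np.clip(img, 0.0, None), disk


class TestThresholds:
    def test_two_valued_image_partitions_exactly(self):
        img = np.where(np.indices((20, 20))[0] < 10, 10.0, 200.0)
        (thr,) = kmeans_intensity_thresholds(img, 2)
        assert 10.0 < thr < 200.0
        assert ((img > thr) == (img == 200.0)).all()

    def test_uniform_image_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate histogram"):
            kmeans_intensity_thresholds(np.full((16, 16), 3.0), 2)

    def test_bimodal_mixture_agrees_with_exhaustive_search(self):
        rng = np.random.default_rng(7)
        vals = np.concatenate(
            [rng.normal(50.0, 5.0, 32768), rng.normal(180.0, 5.0, 32768)]
        ).clip(0.0)
        img = vals.reshape(256, 256)
        (thr,) = kmeans_intensity_thresholds(img, 2)
        assert 80.0 < thr < 150.0
        oracle = _exhaustive_two_class_threshold(vals)
        assert abs(thr - oracle) <= 2.0

    def test_affine_rescaling_moves_thresholds_covariantly(self):
        img, _ = _disk_image(seed=3)
        t0 = kmeans_intensity_thresholds(img, 3)
        t1 = kmeans_intensity_thresholds(2.5 * img + 40.0, 3)
        np.testing.assert_allclose(t1, 2.5 * t0 + 40.0, rtol=1e-9)


class TestSegmentation:
    def test_disk_iou(self):
        img, disk = _disk_image()
        mask = hierarchical_segment_cell_mask(img, HKParams(), pixel_size=100.0)
        iou = (mask.grid & disk).sum() / (mask.grid | disk).sum()
        assert iou >= 0.95

    def test_small_specks_removed_by_size_filter(self):
        img, disk = _disk_image(noise=0.0)
        for y, x in ((5, 5), (5, 120), (120, 5)):
            img[y : y + 2, x : x + 2] = 200.0
        mask = segment_cell_mask(img + np.random.default_rng(1).normal(0, 1, img.shape),
                                 HKParams(n_classes=2, min_size_px=50), pixel_size=100.0)
        for y, x in ((5, 5), (5, 120), (120, 5)):
            assert not mask.grid[y : y + 2, x : x + 2].any()
        assert mask.grid[disk].mean() > 0.9

    def test_background_only_image_raises(self):
        # pure shot-noise background: the upper intensity class is sparse
        # speckle whose components all fall below the size filter
        rng = np.random.default_rng(2)
        img = rng.poisson(1.0, (64, 64)).astype(float)
        with pytest.raises(ValueError, match="no cell found"):
            segment_cell_mask(img, HKParams(n_classes=2, min_size_px=200,
                                            dilation_px=0), pixel_size=100.0)

    def test_affine_intensity_invariance_of_mask(self):
        img, _ = _disk_image(seed=5)
        m0 = segment_cell_mask(img, HKParams(n_classes=2), pixel_size=100.0)
        m1 = segment_cell_mask(3.0 * img + 17.0, HKParams(n_classes=2), pixel_size=100.0)
        assert (m0.grid == m1.grid).all()

    def test_measure_exactness(self):
        img, _ = _disk_image()
        mask = hierarchical_segment_cell_mask(img, HKParams(), pixel_size=(40.0, 60.0))
        assert mask.measure == np.count_nonzero(mask.grid) * 40.0 * 60.0

    def test_param_validation(self):
        with pytest.raises(ValueError):
            HKParams(n_classes=1)
        with pytest.raises(ValueError):
            HKParams(n_classes=3, foreground_classes=3)
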