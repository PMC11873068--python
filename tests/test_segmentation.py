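"""Segmentation: background subtraction, nucleus labelling, Voronoi cell ROIs."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from skimage.morphology import disk, opening

from mitocn import segmentation
from mitocn.segmentation import (LabelMap, subtract_background, threshold_nuclei,
                                 voronoi_cell_rois)
from mitocn.synthgen import SynthFieldConfig, make_field


def _disk_image(shape, centers, radius, value):
    img = np.zeros(shape, np.float32)
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    for cy, cx in centers:
        img[np.hypot(yy - cy, xx - cx) <= radius] = value
    return img


class TestSubtractBackground:
    def test_uniform_image_goes_to_zero(self):
        out = subtract_background(np.full((64, 64), 37.0), 10.0, 1.0)
        assert np.allclose(out, 0.0, atol=1e-3)

    def test_small_disk_preserved_against_opening_oracle(self):
        # a bright disk smaller than the ball survives subtraction intact
        img = _disk_image((128, 128), [(64, 64)], 6, 50.0) + 10.0
        out = subtract_background(img, 15.0, 1.0)
        oracle = img - opening(img, disk(15))
        assert out.sum() == pytest.approx(oracle.sum(), rel=0.01)
        assert out.sum() == pytest.approx((img - 10.0).sum(), rel=0.01)

    def test_downsampled_path_matches_exact_ball_closely(self):
        yy, xx = np.mgrid[:160, :160]
        img = (20 + 0.05 * xx + 0.03 * yy).astype(np.float32)  # smooth shading
        img[40:50, 60:70] += 100.0
        exact = subtract_background(img, 16.0, 1.0)      # direct ball
        fast = subtract_background(img, 16.0001, 1.0)    # downsampled path
        assert np.abs(exact - fast).mean() < 0.5

    def test_degenerate_radius_rejected(self):
        with pytest.raises(ValueError):
            subtract_background(np.zeros((8, 8)), 1.0, 1.0)
        with pytest.raises(ValueError):
            subtract_background(np.zeros((8, 8)), -1.0, 1.0)


class TestThresholdNuclei:
    def test_blank_image_yields_no_labels(self):
        with pytest.warns(UserWarning):
            lm = threshold_nuclei(np.zeros((64, 64)), 10.0, pixel_size_um=1.0)
        assert lm.n_labels == 0

    def test_two_disjoint_disks_two_labels(self):
        img = _disk_image((100, 100), [(30, 30), (70, 70)], 8, 100.0)
        lm = threshold_nuclei(img, 50.0, pixel_size_um=1.0)
        assert lm.n_labels == 2

    def test_size_filter_removes_specks_and_blobs(self):
        img = _disk_image((120, 120), [(60, 60)], 10, 100.0)
        img[5, 5] = 100.0  # single-pixel speck
        lm = threshold_nuclei(img, 50.0, min_area_um2=20.0, pixel_size_um=1.0)
        assert lm.n_labels == 1

    def test_synthetic_field_counts_and_centroids_match_truth(self):
        cfg = SynthFieldConfig(field_size_px=(1536, 1536), n_cells=100, seed=13,
                               copies_per_cell_mean=1e-6)
        image, truth = make_field(cfg)
        nuc = subtract_background(image.channels["dna"], 75.0, cfg.pixel_size_um)
        lm = threshold_nuclei(nuc, 15.0, pixel_size_um=cfg.pixel_size_um)
        assert lm.n_labels == 100
        found = lm.table()[["centroid_y", "centroid_x"]].to_numpy()
        true = truth.cells[["y", "x"]].to_numpy()
        d = cdist(true, found)
        assert (d.min(axis=1) < 2.0).all()

    def test_label_count_invariant_under_joint_rescaling(self):
        img = _disk_image((100, 100), [(30, 30), (70, 70)], 8, 100.0)
        a = threshold_nuclei(img, 50.0, pixel_size_um=1.0)
        b = threshold_nuclei(img * 3.0, 150.0, pixel_size_um=1.0)
        np.testing.assert_array_equal(a.labels, b.labels)


def _brute_force_voronoi(nuclei: LabelMap, cap_px: float) -> np.ndarray:
    """O(pixels x nuclei) oracle: per-pixel nearest-nucleus-mask scan,
    equidistant pixels to the lower label id."""
    labels = nuclei.labels
    h, w = labels.shape
    pix = np.argwhere(np.ones_like(labels, bool))
    best_d = np.full(h * w, np.inf)
    best_l = np.zeros(h * w, np.int32)
    for lab in nuclei.ids:
        pts = np.argwhere(labels == lab)
        d = cdist(pix, pts).min(axis=1)
        closer = d < best_d
        best_d[closer] = d[closer]
        best_l[closer] = lab
    out = np.where(best_d <= cap_px, best_l, 0)
    return out.reshape(h, w).astype(np.int32)


class TestVoronoiCellROIs:
    def test_matches_brute_force_oracle_on_random_field(self):
        rng = np.random.default_rng(3)
        labels = np.zeros((120, 140), np.int32)
        centers = rng.integers(8, 110, size=(20, 2))
        for i, (cy, cx) in enumerate(centers, start=1):
            labels[cy - 2:cy + 3, cx - 2:cx + 3] = i
        nuclei = LabelMap(labels=labels, pixel_size_um=1.0)
        rois = voronoi_cell_rois(nuclei, dilation_px=2, max_expansion_um=40.0)
        oracle = _brute_force_voronoi(nuclei, 40.0)
        np.testing.assert_array_equal(rois.cells.labels, oracle)

    def test_bisector_between_two_point_nuclei(self):
        labels = np.zeros((50, 200), np.int32)
        labels[25, 50] = 1
        labels[25, 150] = 2
        nuclei = LabelMap(labels=labels, pixel_size_um=1.0)
        rois = voronoi_cell_rois(nuclei, dilation_px=0, max_expansion_um=1e6)
        assert rois.cells.labels[25, 90] == 1   # 40 vs 60 px
        assert rois.cells.labels[25, 110] == 2
        assert rois.cells.labels[25, 100] == 1  # exact tie -> lower label

    def test_single_nucleus_cap_radius(self):
        # cap 133 µm at 1.24 µm/px allows expansion up to 107.26 px
        labels = np.zeros((300, 300), np.int32)
        labels[150, 150] = 1
        nuclei = LabelMap(labels=labels, pixel_size_um=1.24)
        rois = voronoi_cell_rois(nuclei, dilation_px=0, max_expansion_um=133.0)
        yy, xx = np.mgrid[:300, :300]
        d = np.hypot(yy - 150, xx - 150)
        np.testing.assert_array_equal(rois.cells.labels > 0, d <= 133.0 / 1.24)

    def test_shrinking_cap_never_grows_rois(self):
        rng = np.random.default_rng(4)
        labels = np.zeros((100, 100), np.int32)
        for i, (cy, cx) in enumerate(rng.integers(10, 90, size=(8, 2)), start=1):
            labels[cy, cx] = i
        nuclei = LabelMap(labels=labels, pixel_size_um=1.0)
        big = voronoi_cell_rois(nuclei, max_expansion_um=30.0).cells.labels
        small = voronoi_cell_rois(nuclei, max_expansion_um=12.0).cells.labels
        grown = (small > 0) & (big == 0)
        assert not grown.any()
        inside = small > 0
        np.testing.assert_array_equal(small[inside], big[inside])

    def test_cytosol_excludes_dilated_nucleus_and_cells_disjoint(self):
        labels = np.zeros((80, 80), np.int32)
        labels[20:25, 20:25] = 1
        labels[60:65, 55:60] = 2
        nuclei = LabelMap(labels=labels, pixel_size_um=1.0)
        rois = voronoi_cell_rois(nuclei, dilation_px=4, max_expansion_um=20.0)
        assert not np.any((rois.cytosol.labels > 0) & (labels > 0))
        from scipy.ndimage import distance_transform_edt
        dist = distance_transform_edt(labels == 0)
        assert not np.any((rois.cytosol.labels > 0) & (dist <= 4))
        # every cell contains exactly its nucleus
        for lab in (1, 2):
            assert np.all(rois.cells.labels[labels == lab] == lab)

    def test_requires_a_nucleus(self):
        nuclei = LabelMap(labels=np.zeros((10, 10), np.int32), pixel_size_um=1.0)
        with pytest.raises(ValueError):
            voronoi_cell_rois(nuclei)
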