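"""Punctum detection, NaN masking, and per-cell photometry conservation."""

import numpy as np
import pandas as pd
import pytest

from mitocn import puncta
from mitocn.segmentation import LabelMap
from mitocn.synthgen import _add_gaussian_spot


def _cyto(shape, value=1):
    return LabelMap(labels=np.full(shape, value, np.int32), pixel_size_um=1.0)


class TestDetectPuncta:
    def test_blank_image_empty_table(self):
        out = puncta.detect_puncta(np.zeros((64, 64), np.float32), _cyto((64, 64)),
                                   peak_min=5.0)
        assert len(out) == 0

    def test_five_spots_in_one_cell(self):
        img = np.zeros((100, 100), np.float32)
        spots = [(20, 20), (20, 80), (50, 50), (80, 20), (80, 80)]
        for y, x in spots:
            _add_gaussian_spot(img, y, x, 500.0, 1.5)
        out = puncta.detect_puncta(img, _cyto((100, 100), 3), peak_min=5.0)
        assert len(out) == 5
        assert (out["cell_id"] == 3).all()
        found = set(zip(out["y"].astype(int), out["x"].astype(int)))
        assert found == set(spots)

    def test_detection_rate_on_sparse_synthetic_field(self, sparse_field,
                                                      sparse_rois):
        _cfg, _image, truth = sparse_field
        nuclei, rois, ds, raw = sparse_rois
        out = puncta.detect_puncta(ds, rois.cytosol, peak_min=4.0,
                                   photometry_image=raw)
        assert len(out) >= 0.95 * len(truth.puncta)

    def test_per_cell_sums_match_truth_within_5pct(self, sparse_field,
                                                   sparse_rois):
        _cfg, _image, truth = sparse_field
        nuclei, rois, ds, raw = sparse_rois
        # sparse field: a generous 9x9 aperture captures ~99% of each spot
        out = puncta.detect_puncta(ds, rois.cytosol, peak_min=4.0,
                                   patch_radius=4, photometry_image=raw)
        sums = puncta.sum_puncta_per_cell(out, cell_ids=nuclei.ids)
        # ground-truth per-cell sums under the same nearest-nucleus
        # assignment rule the measurement uses (a punctum can genuinely sit
        # closer to a neighbouring cell's nucleus than to its parent's)
        owner = rois.cells.labels[
            truth.puncta["y"].round().astype(int),
            truth.puncta["x"].round().astype(int)]
        truth_sum = (truth.puncta.assign(owner=owner)
                     .groupby("owner")["copies"].sum() * 100.0)
        for cid in nuclei.ids:
            assert sums[cid] == pytest.approx(
                truth_sum.get(cid, 0.0), rel=0.05)

    def test_detection_count_monotone_in_peak_min(self, sparse_rois):
        _nuclei, rois, ds, _raw = sparse_rois
        counts = [len(puncta.detect_puncta(ds, rois.cytosol, peak_min=p))
                  for p in (3.0, 5.0, 8.0, 20.0)]
        assert counts == sorted(counts, reverse=True)

    def test_plateau_tie_break_is_lexicographic(self):
        img = np.zeros((20, 20), np.float32)
        img[10, 10] = img[10, 11] = 50.0  # two-pixel plateau
        out = puncta.detect_puncta(img, _cyto((20, 20)), peak_min=5.0,
                                   local_background=False)
        assert len(out) == 1
        assert (out.loc[0, "y"], out.loc[0, "x"]) == (10, 10)


class TestMaskSubthreshold:
    def test_floor_zero_is_identity(self):
        img = np.arange(12, dtype=np.float32).reshape(3, 4)
        np.testing.assert_array_equal(puncta.mask_subthreshold(img, 0.0), img)

    def test_exclusion_arithmetic(self):
        img = np.array([[10.0] * 4, [100.0] * 4], np.float32)
        rois = _cyto((2, 4))
        masked = puncta.mask_subthreshold(img, 50.0)
        assert puncta.nan_roi_mean(masked, rois)[1] == 100.0

    def test_all_ignored_roi_reports_missing(self):
        masked = puncta.mask_subthreshold(np.full((4, 4), 5.0, np.float32), 50.0)
        assert np.isnan(puncta.nan_roi_mean(masked, _cyto((4, 4)))[1])
        assert np.isnan(puncta.nan_roi_sum(masked, _cyto((4, 4)))[1])

    def test_thresholded_area_counts_surviving_pixels(self):
        img = np.zeros((10, 10), np.float32)
        img[:5] = 80.0
        rois = LabelMap(labels=np.ones((10, 10), np.int32), pixel_size_um=1.24)
        masked = puncta.mask_subthreshold(img, 50.0)
        area = puncta.thresholded_area_per_roi(masked, rois)
        assert area[1] == pytest.approx(50 * 1.24 ** 2)

    def test_negative_floor_rejected(self):
        with pytest.raises(ValueError):
            puncta.mask_subthreshold(np.zeros((2, 2)), -1.0)


class TestSumPunctaPerCell:
    def test_simple_sum(self):
        pt = pd.DataFrame({"intensity": [100.0, 200.0], "cell_id": [3, 3]})
        sums = puncta.sum_puncta_per_cell(pt)
        assert sums[3] == 300.0

    def test_no_puncta_all_zero(self):
        pt = pd.DataFrame(columns=puncta.PUNCTA_COLUMNS)
        sums = puncta.sum_puncta_per_cell(pt, cell_ids=[1, 2, 3])
        assert (sums == 0.0).all()

    def test_conservation_is_exact(self, sparse_rois):
        nuclei, rois, ds, _raw = sparse_rois
        out = puncta.detect_puncta(ds, rois.cytosol, peak_min=4.0)
        sums = puncta.sum_puncta_per_cell(out, cell_ids=nuclei.ids)
        assigned = out.loc[out["cell_id"] > 0, "intensity"].sum()
        assert sums.sum() == pytest.approx(assigned, rel=1e-12)

    def test_unassigned_puncta_excluded(self):
        pt = pd.DataFrame({"intensity": [10.0, 20.0], "cell_id": [0, 2]})
        sums = puncta.sum_puncta_per_cell(pt, cell_ids=[1, 2])
        assert sums[1] == 0.0 and sums[2] == 20.0
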