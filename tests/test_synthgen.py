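"""Generator contracts: determinism, ground-truth conservation, distributions."""

import numpy as np
import pandas as pd
import pytest

from mitocn.synthgen import (OvercrowdingError, SynthFieldConfig, make_droplets,
                             make_field, make_growth_counts, make_ocr_trace)


class TestMakeField:
    def test_empty_field(self):
        cfg = SynthFieldConfig(n_cells=0, noise_sd=0.0, background_level=0.0,
                               seed=1)
        image, truth = make_field(cfg)
        assert len(truth.cells) == 0 and len(truth.puncta) == 0
        for ch in image.channels.values():
            assert np.all(ch == 0)

    def test_same_seed_is_bit_identical(self):
        cfg = SynthFieldConfig(n_cells=50, seed=7)
        img1, t1 = make_field(cfg)
        img2, t2 = make_field(cfg)
        for name in img1.channels:
            np.testing.assert_array_equal(img1.channels[name], img2.channels[name])
        pd.testing.assert_frame_equal(t1.cells, t2.cells)
        pd.testing.assert_frame_equal(t1.puncta, t2.puncta)

    def test_truth_copy_totals_are_conserved_exactly(self, sparse_field):
        _cfg, _img, truth = sparse_field
        per_cell = truth.puncta.groupby("cell_id")["copies"].sum()
        for _, row in truth.cells.iterrows():
            assert row["true_copies"] == per_cell.get(row["cell_id"], 0)

    def test_mean_true_copies_tracks_configured_mean(self):
        # Σ(per-punctum intensity)/q per cell averages to the configured
        # mean; dispersion 0 isolates the punctum-count calibration from
        # between-cell scatter so 2% is a ~3.5 sigma bound at 250 cells
        cfg = SynthFieldConfig(field_size_px=(2400, 2400), n_cells=250,
                               copies_per_cell_mean=400.0,
                               copies_per_cell_dispersion=0.0,
                               quantal_intensity=100.0, seed=21)
        _img, truth = make_field(cfg)
        per_cell = truth.puncta.groupby("cell_id")["intensity"].sum() / 100.0
        per_cell = per_cell.reindex(truth.cells["cell_id"], fill_value=0.0)
        assert per_cell.mean() == pytest.approx(400.0, rel=0.02)

    def test_puncta_never_inside_nuclei(self, sparse_field):
        _cfg, _img, truth = sparse_field
        cells = truth.cells.set_index("cell_id")
        for _, p in truth.puncta.iterrows():
            d = np.hypot(cells["y"] - p["y"], cells["x"] - p["x"])
            assert (d > cells["nuclear_radius_px"] + 1.0).all()

    def test_overcrowding_raises(self):
        cfg = SynthFieldConfig(field_size_px=(64, 64), n_cells=50, seed=1)
        with pytest.raises(OvercrowdingError):
            make_field(cfg)

    def test_invalid_proportions_rejected(self):
        cfg = SynthFieldConfig(ploidy_weights={"2N": 0.5, "4N": 0.4})
        with pytest.raises(ValueError):
            cfg.validate()

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = SynthFieldConfig(n_cells=9, seed=5, copies_per_cell_mean=123.0)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        back = SynthFieldConfig.from_yaml(tmp_path / "cfg.yaml")
        assert back == cfg

    def test_tiff_round_trip(self, tmp_path, sparse_field):
        _cfg, image, _truth = sparse_field
        image.to_tiff(tmp_path / "f.tiff")
        from mitocn.synthgen import FieldImage
        back = FieldImage.from_tiff(tmp_path / "f.tiff")
        assert set(back.channels) == set(image.channels)
        assert back.pixel_size_um == pytest.approx(image.pixel_size_um)
        np.testing.assert_allclose(
            back.channels["dna"],
            np.clip(image.channels["dna"], 0, 65535).astype(np.uint16))


class TestMakeDroplets:
    def test_zero_occupancy_all_negative(self):
        table = make_droplets(0.0, 0.0, 500, seed=3)
        assert (table["true_nd1_copies"] == 0).all()
        assert (table["true_actb_copies"] == 0).all()

    def test_negative_fraction_matches_poisson_void(self):
        table = make_droplets(1.0, 0.0, 100_000, seed=5)
        frac_neg = (table["true_nd1_copies"] == 0).mean()
        assert frac_neg == pytest.approx(np.exp(-1.0), abs=0.005)

    def test_double_positive_fraction_is_product_of_marginals(self):
        lam1, lam2 = 1.9467, 0.020
        table = make_droplets(lam1, lam2, 20_000, seed=9)
        expected = (1 - np.exp(-lam1)) * (1 - np.exp(-lam2))  # ~0.0170
        both = ((table["true_nd1_copies"] > 0)
                & (table["true_actb_copies"] > 0)).mean()
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(both - expected) < 3 * se

    def test_preconditions(self):
        with pytest.raises(ValueError):
            make_droplets(-0.1, 0.0, 100)
        with pytest.raises(ValueError):
            make_droplets(1.0, 1.0, 0)


class TestMakeGrowthCounts:
    def test_zero_rate_no_noise_is_constant(self):
        df = make_growth_counts(100, 0.0, 0.0, 10.0, 1.0, "none")
        assert (df["count"] == 100).all()

    def test_closed_form_final_count(self):
        df = make_growth_counts(100, 0.06931, 0.0, 72.0, 1.0, "none")
        assert df["count"].iloc[-1] == pytest.approx(100 * np.exp(0.06931 * 72),
                                                     rel=1e-9)

    def test_seeded_poisson_reproducible(self):
        a = make_growth_counts(100, 0.03, 0.0, 48.0, 0.5, "poisson", seed=4)
        b = make_growth_counts(100, 0.03, 0.0, 48.0, 0.5, "poisson", seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_confluence_truncation_flagged(self):
        df = make_growth_counts(100, 0.1, 0.0, 72.0, 1.0, "none", max_count=500)
        assert df["truncated"].any()
        assert df["count"].max() == 500


class TestMakeOCRTrace:
    def test_noise_free_step_function(self):
        trace = make_ocr_trace((100, 40, 150, 10), 3, noise_sd=0.0)
        assert trace.ocr.tolist() == [100] * 3 + [40] * 3 + [150] * 3 + [10] * 3

    def test_seeded_reproducible(self):
        a = make_ocr_trace((100, 40, 150, 10), 3, noise_sd=5.0, seed=8)
        b = make_ocr_trace((100, 40, 150, 10), 3, noise_sd=5.0, seed=8)
        np.testing.assert_array_equal(a.ocr, b.ocr)

    def test_phase_means_recovered_within_clt_bound(self):
        levels, n, sd = (100.0, 40.0, 150.0, 10.0), 12, 5.0
        trace = make_ocr_trace(levels, n, noise_sd=sd, seed=2)
        for mask, level in zip(trace.phases().values(), levels):
            assert abs(trace.ocr[mask].mean() - level) < 3 * sd / np.sqrt(n)

    def test_too_few_measurements_rejected(self):
        with pytest.raises(ValueError):
            make_ocr_trace((1, 2, 3, 4), 2)
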