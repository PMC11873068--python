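"""Ploidy gates and triple-Gaussian transfection gating."""

import numpy as np
import pandas as pd
import pytest

from mitocn import gating
from mitocn.gating import (GfpMixtureModel, PloidyGateSet,
                           auto_gates_from_g1_peak, fit_gfp_mixture,
                           fraction_high, gate_ploidy)


def _cells(intensity, area=None):
    intensity = np.asarray(intensity, float)
    if area is None:
        area = np.full(intensity.size, 150.0)
    return pd.DataFrame({"nuclear_intensity": intensity,
                         "nuclear_area_um2": area})


def _mixed_population(rng, n=2000, m=10_000.0, cv=0.08,
                      weights=(0.6, 0.3, 0.1)):
    mult = rng.choice([1.0, 2.0, 4.0], size=n, p=weights)
    vals = m * mult * (1 + cv * rng.standard_normal(n))
    return _cells(vals), mult


class TestPloidyGates:
    def test_modal_multiples_map_to_expected_classes(self):
        rng = np.random.default_rng(0)
        cells, _ = _mixed_population(rng)
        gates = auto_gates_from_g1_peak(cells)
        labeled = gate_ploidy(_cells([10_000.0, 20_000.0, 40_000.0]), gates)
        assert labeled["ploidy_class"].tolist() == ["2", "4", "8"]

    def test_agreement_with_ground_truth_at_8pct_cv(self):
        rng = np.random.default_rng(5)
        cells, mult = _mixed_population(rng, n=3000)
        gates = auto_gates_from_g1_peak(cells)
        labeled = gate_ploidy(cells, gates)
        want = pd.Series(mult).map({1.0: "2", 2.0: "4", 4.0: "8"})
        assert (labeled["ploidy_class"] == want).mean() >= 0.95

    def test_pure_2n_population_all_in_2(self):
        rng = np.random.default_rng(2)
        cells, _ = _mixed_population(rng, weights=(1.0, 0.0, 0.0))
        gates = auto_gates_from_g1_peak(cells)
        labeled = gate_ploidy(cells, gates)
        assert (labeled["ploidy_class"] == "2").mean() > 0.99

    def test_recovered_mode_within_5pct_on_equal_mixture(self):
        rng = np.random.default_rng(7)
        cells, _ = _mixed_population(rng, n=4000, weights=(0.5, 0.5, 0.0))
        gates = auto_gates_from_g1_peak(cells)
        lo, hi = gates.gates["2"]["intensity"]
        m = lo / 0.75  # recover m from the gate definition
        assert m == pytest.approx(10_000.0, rel=0.05)

    def test_gate_boundaries_scale_with_intensity(self):
        rng = np.random.default_rng(1)
        cells, _ = _mixed_population(rng)
        g1 = auto_gates_from_g1_peak(cells)
        cells2 = cells.copy()
        cells2["nuclear_intensity"] *= 3.0
        g2 = auto_gates_from_g1_peak(cells2)
        for name in g1.gates:
            np.testing.assert_allclose(
                g2.gates[name]["intensity"],
                np.asarray(g1.gates[name]["intensity"]) * 3.0, rtol=0.02)

    def test_class_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        cells, _ = _mixed_population(rng)
        gates = auto_gates_from_g1_peak(cells)
        frac = gating.class_fractions(gate_ploidy(cells, gates)["ploidy_class"])
        assert frac.sum() == pytest.approx(1.0)

    def test_overlapping_gates_rejected(self):
        with pytest.raises(ValueError):
            PloidyGateSet(gates={
                "a": {"intensity": (0, 10), "area": (0, 10)},
                "b": {"intensity": (5, 15), "area": (0, 10)}})

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            auto_gates_from_g1_peak(_cells(np.full(100, 1000.0)))

    def test_yaml_round_trip(self, tmp_path):
        rng = np.random.default_rng(1)
        cells, _ = _mixed_population(rng)
        gates = auto_gates_from_g1_peak(cells)
        gates.to_yaml(tmp_path / "g.yaml")
        back = PloidyGateSet.from_yaml(tmp_path / "g.yaml")
        assert back.gates.keys() == gates.gates.keys()


def _gfp_sample(rng, n=10_000,
                comps=((100.0, 20.0, 0.75), (500.0, 80.0, 0.15),
                       (2000.0, 300.0, 0.10))):
    which = rng.choice(len(comps), size=n, p=[c[2] for c in comps])
    mus = np.array([c[0] for c in comps])[which]
    sds = np.array([c[1] for c in comps])[which]
    return rng.normal(mus, sds)


class TestGfpMixture:
    def test_threshold_is_mu1_plus_3sd1(self, rng):
        fit = fit_gfp_mixture(_gfp_sample(rng), seed=0)
        assert fit.threshold == pytest.approx(fit.means[0] + 3 * fit.sds[0])
        assert fit.threshold == pytest.approx(160.0, abs=10.0)

    def test_transfected_fraction_recovered_within_2pp(self, rng):
        fit = fit_gfp_mixture(_gfp_sample(rng), seed=0)
        # 25% transfected mass + the 0.135% background tail beyond 3 sigma
        assert fit.transfected_fraction == pytest.approx(0.25, abs=0.02)

    def test_single_component_tail_fraction(self):
        # with only a tight background component, the mu1+3sd1 rule calls
        # exactly the 3-sigma normal tail (~0.135%) transfected
        rng = np.random.default_rng(8)
        vals = rng.normal(100.0, 20.0, 200_000)
        fit = gating.GfpMixtureFit(
            means=np.array([100.0] * 3), sds=np.array([20.0] * 3),
            weights=np.array([1 / 3] * 3), threshold=160.0,
            transfected_fraction=float(np.mean(vals > 160.0)),
            log_likelihood=0.0, n_cells=vals.size)
        assert fit.classify(vals).mean() == pytest.approx(0.00135, abs=0.0005)

    def test_affine_consistency(self, rng):
        x = _gfp_sample(rng, n=4000)
        f0 = fit_gfp_mixture(x, seed=0)
        f1 = fit_gfp_mixture(x + 500.0, seed=0)
        assert f1.threshold - 500.0 == pytest.approx(f0.threshold, abs=1e-3)

    def test_mixture_beats_single_gaussian(self, rng):
        x = _gfp_sample(rng, n=4000)
        model = GfpMixtureModel(x)
        assert model.fit(seed=0).log_likelihood >= model.null_log_likelihood()

    def test_min_cells_floor(self):
        with pytest.raises(ValueError):
            GfpMixtureModel(np.zeros(10))


class TestFractionHigh:
    def test_basic_share(self):
        assert fraction_high([0, 0, 5, 10], 1.0) == 0.5

    def test_all_below(self):
        assert fraction_high([0, 0, 0], 1.0) == 0.0

    def test_matches_configured_high_mass(self, rng):
        # background N(10, 2) vs 30% high cells at N(50, 5)
        n = 5000
        high = rng.random(n) < 0.3
        vals = np.where(high, rng.normal(50, 5, n), rng.normal(10, 2, n))
        floor = np.percentile(vals[~high], 95)
        frac = fraction_high(vals, floor)
        se = np.sqrt(0.3 * 0.7 / n)
        assert abs(frac - (0.3 + 0.7 * 0.05)) < 4 * se + 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fraction_high([], 1.0)
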