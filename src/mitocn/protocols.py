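"""Reference synthetic protocols reproducing the study's headline quantities.

Each function generates seeded synthetic data at the study's stated
conditions, runs the corresponding analysis chain end to end, and returns
the measured quantity together with the problem size.  They are the backbone
of the reproduction script (``scripts/acceptance.py``) and of the end-to-end
test suite; nothing in them is fitted to the expected answers — the numbers
come out of the generators and estimators at run time.

Protocol catalogue
------------------
``mcn_reduction``       27% mtDNA copy-number reduction recovered by the
                        full imaging pipeline (two 220-cell groups).
``transfection_rate``   ~25% transfected cells called by the triple-Gaussian
                        mu1+3*sigma1 threshold.
``ddpcr_absolute``      584 copies/cell from duplex droplets with a 6-locus
                        nuclear reference.
``ddpcr_reduction``     28% copies/cell reduction between two conditions.
``growth_doubling``     doubling times (27.3 h / 20.5 h) from noisy
                        exponential counts.
``mitosox_ploidy``      4N MitoSOX index ~2.05 through the gate->normalize
                        chain.
``tmrm_index``          control TMRM index ~0.23 from FCCP/oligomycin
                        anchors.
"""

from __future__ import annotations

import numpy as np

from . import ddpcr, gating, physiology, puncta, quantal, segmentation, synthgen
from .growth import GrowthCurve, GrowthModel
from .synthgen import SynthFieldConfig, make_field

__all__ = [
    "mcn_reduction", "transfection_rate", "ddpcr_absolute", "ddpcr_reduction",
    "growth_doubling", "mitosox_ploidy", "tmrm_index",
]

MOD = 2 ** 31


def _child(seed: int, k: int) -> int:
    return int((seed * 7919 + k * 104729 + 1) % MOD)


# ---------------------------------------------------------------------------

def _imaging_group_mcn(mean_copies: float, n_fields: int, cells_per_field: int,
                       seed: int, q: float = 100.0, sigma: float = 8.0):
    """Segment, detect and photometer one group of fields; return per-cell
    puncta sums and pooled punctum intensities (quantal fit happens later,
    per staining batch)."""
    sums = []
    intensities = []
    for i in range(n_fields):
        # 20x sampling (0.62 µm/px): nucleoids at several hundred copies/cell
        # are only resolvable as local maxima at this magnification
        cfg = SynthFieldConfig(
            field_size_px=(2048, 2048), pixel_size_um=0.62,
            n_cells=cells_per_field,
            copies_per_cell_mean=mean_copies, quantal_intensity=q,
            puncta_sigma=sigma, seed=_child(seed, i))
        image, _truth = make_field(cfg)
        px = image.pixel_size_um
        nuc = segmentation.subtract_background(image.channels["dna"], 75.0, px)
        nuclei = segmentation.threshold_nuclei(nuc, threshold=7.0,
                                               pixel_size_um=px)
        rois = segmentation.voronoi_cell_rois(nuclei)
        ds = segmentation.subtract_background(image.channels["dsdna"], 75.0, px)
        pt = puncta.detect_puncta(ds, rois.cytosol, peak_min=4.0,
                                  photometry_image=image.channels["dsdna"])
        sums.append(puncta.sum_puncta_per_cell(pt, cell_ids=nuclei.ids).to_numpy())
        intensities.append(pt.loc[pt["cell_id"] > 0, "intensity"].to_numpy())
    return np.concatenate(sums), np.concatenate(intensities)


def mcn_reduction(seed: int = 1, n_fields: int = 10, cells_per_field: int = 22,
                  ref_copies: float = 400.0, var_copies: float = 292.0) -> dict:
    """Percent reduction in mean image-estimated mCN between two groups.

    A reference group (mean 400 true copies/cell) and a variant-like group
    (mean 292, a 27% true reduction) are imaged, segmented and photometered;
    each image set gets its own quantal fit — the quantal unit is estimated
    per set of staining — which converts per-cell sums to mCN.  Returns the
    percent reduction of the variant mean relative to the reference mean.
    """
    ref_sums, ref_int = _imaging_group_mcn(
        ref_copies, n_fields, cells_per_field, _child(seed, 101))
    var_sums, var_int = _imaging_group_mcn(
        var_copies, n_fields, cells_per_field, _child(seed, 202))
    fit_ref = quantal.QuantalIntensityModel(ref_int).fit()
    fit_var = quantal.QuantalIntensityModel(var_int).fit()
    mcn_ref = quantal.estimate_mcn(ref_sums, fit_ref)
    mcn_var = quantal.estimate_mcn(var_sums, fit_var)
    ratio = float(np.mean(mcn_var) / np.mean(mcn_ref))
    return {"value": 100.0 * (1.0 - ratio),
            "n": int(len(ref_sums) + len(var_sums)),
            "mean_mcn_ref": float(np.mean(mcn_ref)),
            "mean_mcn_var": float(np.mean(mcn_var)),
            "q": fit_ref.q}


def transfection_rate(seed: int = 1, n_cells: int = 10000) -> dict:
    """Percent of cells above the fitted mu1 + 3*sigma1 GFP threshold.

    The synthetic nuclear-GFP mixture has 75% background (mu 100, sd 20),
    15% dim-transfected (500, 80) and 10% bright-transfected (2000, 300)
    mass, i.e. ~25% truly transfected cells.
    """
    rng = np.random.default_rng(_child(seed, 7))
    comps = ((100.0, 20.0, 0.75), (500.0, 80.0, 0.15), (2000.0, 300.0, 0.10))
    which = rng.choice(3, size=n_cells, p=[c[2] for c in comps])
    mus = np.array([c[0] for c in comps])[which]
    sds = np.array([c[1] for c in comps])[which]
    vals = rng.normal(mus, sds)
    fit = gating.fit_gfp_mixture(vals, seed=_child(seed, 8))
    return {"value": 100.0 * fit.transfected_fraction, "n": n_cells,
            "threshold": fit.threshold}


def ddpcr_absolute(seed: int = 1, lam_nd1: float = 1.9467,
                   lam_actb: float = 0.020, n_droplets: int = 20000,
                   loci_per_cell: float = 6.0) -> dict:
    """Absolute mtDNA copies/cell from synthetic duplex droplets."""
    table = synthgen.make_droplets(lam_nd1, lam_actb, n_droplets,
                                   seed=_child(seed, 31))
    est = ddpcr.DropletAssay(table, loci_per_cell=loci_per_cell).fit()
    return {"value": est.copies_per_cell, "n": n_droplets,
            "lambda_nd1": est.lambda_nd1, "lambda_actb": est.lambda_actb}


def ddpcr_reduction(seed: int = 1, lam_ref: float = 1.9467,
                    lam_var: float = 1.4016, lam_actb: float = 0.020,
                    n_droplets: int = 20000) -> dict:
    """Percent reduction in ddPCR copies/cell between two conditions
    sharing the nuclear-reference occupancy."""
    ref = ddpcr_absolute(_child(seed, 41), lam_nd1=lam_ref,
                         lam_actb=lam_actb, n_droplets=n_droplets)
    var = ddpcr_absolute(_child(seed, 42), lam_nd1=lam_var,
                         lam_actb=lam_actb, n_droplets=n_droplets)
    return {"value": 100.0 * (1.0 - var["value"] / ref["value"]),
            "n": 2 * n_droplets, "ref_copies": ref["value"],
            "var_copies": var["value"]}


def growth_doubling(seed: int = 1, k: float = 0.02539, n0: float = 150.0,
                    t_end_h: float = 72.0, dt_h: float = 1.0 / 3.0) -> dict:
    """Doubling time from the offset-exponential fit of a Poisson-noised curve."""
    df = synthgen.make_growth_counts(n0=n0, k=k, offset=0.0, t_end=t_end_h,
                                     dt=dt_h, noise_model="poisson",
                                     seed=_child(seed, 53))
    fit = GrowthModel(GrowthCurve.from_frame(df)).fit()
    return {"value": fit.doubling_time_h, "n": int(fit.n_points),
            "rate_per_h": fit.rate, "r_squared": fit.r_squared}


def mitosox_ploidy(seed: int = 1, n_cells: int = 600,
                   n_reference: int = 550) -> dict:
    """Mean normalized MitoSOX index of the 4N-gated population.

    A mixed-ploidy field (60/30/10% of 2N/4N/8N, nuclear-stain CV 8%) with
    nuclear dye means 95/205/264 a.u. is segmented and auto-gated on
    integrated DNA-stain intensity; dye means are normalized to a separate
    reference population generated with mean 100 a.u.  Returns the 4N group
    mean index (the 2N and 8N means ride along for context).
    """
    def measure(cfg):
        image, _ = make_field(cfg)
        px = image.pixel_size_um
        nuc = segmentation.subtract_background(image.channels["dna"], 75.0, px)
        nuclei = segmentation.threshold_nuclei(nuc, threshold=15.0,
                                               pixel_size_um=px)
        dye = segmentation.subtract_background(image.channels["dye"], 75.0, px)
        cells = nuclei.table().rename(columns={"id": "cell_id",
                                               "area_um2": "nuclear_area_um2"})
        cells["nuclear_intensity"] = cells["cell_id"].map(
            puncta.nan_roi_sum(nuc, nuclei))
        cells["dye_mean"] = cells["cell_id"].map(puncta.nan_roi_mean(dye, nuclei))
        return cells

    mixed_cfg = SynthFieldConfig(
        field_size_px=(1536, 1536), n_cells=n_cells,
        ploidy_weights={"2N": 0.6, "2S": 0.0, "4N": 0.3, "4S": 0.0, "8N": 0.1},
        copies_per_cell_mean=1e-6,  # no puncta needed for this readout
        dye_means={"2N": 95.0, "4N": 205.0, "8N": 264.0},
        seed=_child(seed, 61))
    ref_cfg = SynthFieldConfig(
        field_size_px=(1536, 1536), n_cells=n_reference,
        ploidy_weights={"2N": 1.0, "2S": 0.0, "4N": 0.0, "4S": 0.0, "8N": 0.0},
        copies_per_cell_mean=1e-6,
        dye_means={"2N": 100.0},
        seed=_child(seed, 62))

    mixed = measure(mixed_cfg)
    reference = measure(ref_cfg)
    gates = gating.auto_gates_from_g1_peak(mixed)
    mixed = gating.gate_ploidy(mixed, gates)
    ref_mean = float(reference["dye_mean"].mean())
    mixed["mitosox_index"] = physiology.normalize_mitosox(
        mixed["dye_mean"], ref_mean)
    by_class = mixed.groupby("ploidy_class")["mitosox_index"].mean()
    return {"value": float(by_class.get("4", np.nan)), "n": int(len(mixed)),
            "index_2n": float(by_class.get("2", np.nan)),
            "index_8n": float(by_class.get("8", np.nan)),
            "reference_mean": ref_mean}


def tmrm_index(seed: int = 1, n_per_condition: int = 500) -> dict:
    """Mean normalized TMRM index of a control population.

    Control cells ~ N(146, 15); anchor wells: FCCP ~ N(100, 10) (depolarized
    floor) and oligomycin ~ N(300, 25) (hyperpolarized ceiling).  The index
    is (I - mean_FCCP)/(mean_oligo - mean_FCCP) per control cell.
    """
    rng = np.random.default_rng(_child(seed, 71))
    control = rng.normal(146.0, 15.0, n_per_condition)
    fccp = rng.normal(100.0, 10.0, n_per_condition)
    oligo = rng.normal(300.0, 25.0, n_per_condition)
    norm = physiology.DyeNormalization(fccp_mean=float(fccp.mean()),
                                       oligo_mean=float(oligo.mean()))
    idx = physiology.normalize_tmrm(control, norm)
    return {"value": float(np.mean(idx)), "n": n_per_condition,
            "fccp_mean": norm.fccp_mean, "oligo_mean": norm.oligo_mean}
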