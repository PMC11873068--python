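"""End-to-end orchestration: fields in, per-cell / per-FOV / per-plate tables out.

The imaging chain is segmentation -> puncta -> quantal -> gating ->
physiology.  Per-cell records are summarized per field of view and per
plate; mCN and cell density are normalized to the mean of the reference
(wild-type-transfected) wells of the same plate and media condition, which
minimizes plate-wise variance.  Inferential statistics are not computed
here: the exported tables are analysis-ready for standard statistics tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import gating, puncta, quantal, segmentation

log = logging.getLogger("mitocn.pipeline")

__all__ = ["PlateLayout", "PipelineParams", "run_imaging_pipeline",
           "summarize_by_fov"]


@dataclass
class PlateLayout:
    """Well -> (condition, media, drug role) mapping for one plate.

    ``reference_condition`` names the normalization anchor (the wild-type
    construct); every analyzed well must be mapped.
    """

    wells: dict
    reference_condition: str = "WT"

    def condition(self, well: str) -> dict:
        try:
            return self.wells[well]
        except KeyError:
            raise KeyError(f"well {well!r} is not mapped in the plate layout")

    def validate(self, wells_in_use) -> None:
        missing = [w for w in wells_in_use if w not in self.wells]
        if missing:
            raise ValueError(f"unmapped wells: {missing}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"reference_condition": self.reference_condition,
                            "wells": self.wells}, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(wells=raw["wells"],
                   reference_condition=raw.get("reference_condition", "WT"))


@dataclass
class PipelineParams:
    """Tunable parameters of the imaging chain.

    The nuclear threshold is mandatory and chosen per staining batch (never
    auto-applied); all lengths are µm, intensities a.u.
    """

    nuclear_threshold: float
    background_radius_um: float = 75.0
    min_nuclear_area_um2: float = 20.0
    max_nuclear_area_um2: float = 2500.0
    dilation_px: int = 4
    max_expansion_um: float = 133.0
    peak_min: float = 4.0
    min_separation_px: int = 2
    patch_radius_px: int = 3
    n_quantal_components: int = 10
    min_puncta_for_fit: int = 200
    nuclear_channel: str = "dna"
    puncta_channel: str = "dsdna"
    gfp_channel: str = "gfp"
    dye_channel: str = "dye"
    gate_seed: int = 0
    extra: dict = field(default_factory=dict)


def analyze_field(image, params: PipelineParams, plate="P1", well="A1", fov=1):
    """Run segmentation + puncta measurement on one field.

    Returns (cells DataFrame, puncta DataFrame).  The quantal fit is *not*
    applied here because q must be estimated per staining batch, not per FOV.
    """
    px = image.pixel_size_um
    nuc_img = segmentation.subtract_background(
        image.channels[params.nuclear_channel], params.background_radius_um, px)
    nuclei = segmentation.threshold_nuclei(
        nuc_img, params.nuclear_threshold, params.min_nuclear_area_um2,
        params.max_nuclear_area_um2, px)
    log.info("field %s/%s/%s: %d nuclei", plate, well, fov, nuclei.n_labels)
    rois = segmentation.voronoi_cell_rois(
        nuclei, dilation_px=params.dilation_px,
        max_expansion_um=params.max_expansion_um)

    pn_img = segmentation.subtract_background(
        image.channels[params.puncta_channel], params.background_radius_um, px)
    pt = puncta.detect_puncta(
        pn_img, rois.cytosol, peak_min=params.peak_min,
        min_separation_px=params.min_separation_px,
        patch_radius=params.patch_radius_px,
        photometry_image=image.channels[params.puncta_channel])
    log.info("field %s/%s/%s: %d puncta", plate, well, fov, len(pt))

    cells = nuclei.table().rename(columns={"id": "cell_id",
                                           "area_um2": "nuclear_area_um2"})
    sums = puncta.nan_roi_sum(nuc_img, nuclei)
    cells["nuclear_intensity"] = cells["cell_id"].map(sums)
    if params.gfp_channel in image.channels:
        gfp = puncta.nan_roi_mean(image.channels[params.gfp_channel], nuclei)
        cells["gfp_mean"] = cells["cell_id"].map(gfp)
    if params.dye_channel in image.channels:
        dye = puncta.nan_roi_mean(image.channels[params.dye_channel], nuclei)
        cells["dye_mean"] = cells["cell_id"].map(dye)
    psums = puncta.sum_puncta_per_cell(pt, cell_ids=cells["cell_id"])
    cells["puncta_sum"] = cells["cell_id"].map(psums)
    cells.insert(0, "fov", fov)
    cells.insert(0, "well", well)
    cells.insert(0, "plate", plate)
    pt = pt.assign(plate=plate, well=well, fov=fov)
    return cells, pt


def run_imaging_pipeline(fields, layout: PlateLayout,
                         params: PipelineParams) -> dict:
    """Analyze a batch of fields and build cell/FOV/plate-level tables.

    ``fields`` is an iterable of dicts with keys ``image`` (a FieldImage),
    ``plate``, ``well``, ``fov``.  One quantal fit is made per plate (the
    staining batch); mCN and per-FOV cell density are normalized to the mean
    of the reference-condition wells per (plate, media).  Missing reference
    wells skip normalization with a warning while raw values are kept.

    Returns ``{"cells", "fov", "plate_summary", "quantal_fits"}``.
    """
    all_cells, all_puncta = [], []
    for fd in fields:
        cells, pt = analyze_field(fd["image"], params, plate=fd.get("plate", "P1"),
                                  well=fd.get("well", "A1"), fov=fd.get("fov", 1))
        all_cells.append(cells)
        all_puncta.append(pt)
    cells = pd.concat(all_cells, ignore_index=True)
    pnc = pd.concat(all_puncta, ignore_index=True)

    layout.validate(cells["well"].unique())
    meta = cells["well"].map(lambda w: layout.condition(w))
    cells["condition"] = [m["condition"] for m in meta]
    cells["media"] = [m.get("media", "GM") for m in meta]

    # quantal fit per plate (staining batch); mCN withheld when a fit fails
    quantal_fits = {}
    cells["mcn"] = np.nan
    for plate, grp in cells.groupby("plate"):
        batch = pnc[(pnc["plate"] == plate) & (pnc["cell_id"] > 0)]
        if len(batch) < params.min_puncta_for_fit:
            log.warning("plate %s: %d puncta < floor %d; mCN withheld",
                        plate, len(batch), params.min_puncta_for_fit)
            continue
        fit = quantal.QuantalIntensityModel(
            batch["intensity"], n_components=params.n_quantal_components,
            min_puncta=params.min_puncta_for_fit).fit()
        quantal_fits[plate] = fit
        if fit.valid:
            idx = grp.index
            cells.loc[idx, "mcn"] = cells.loc[idx, "puncta_sum"] / fit.q
        else:
            log.warning("plate %s: quantal fit invalid (%s); mCN withheld",
                        plate, "; ".join(fit.flags))

    # ploidy gates per plate when enough cells; transfection from GFP
    cells["ploidy_class"] = "ungated"
    for plate, grp in cells.groupby("plate"):
        try:
            gates = gating.auto_gates_from_g1_peak(grp)
        except ValueError as exc:
            log.warning("plate %s: ploidy gating skipped (%s)", plate, exc)
            continue
        cells.loc[grp.index, "ploidy_class"] = gates.classify(
            grp["nuclear_intensity"].to_numpy(),
            grp["nuclear_area_um2"].to_numpy()).to_numpy()
    if "gfp_mean" in cells:
        try:
            gfit = gating.fit_gfp_mixture(cells["gfp_mean"].dropna(),
                                          seed=params.gate_seed)
            cells["transfected"] = gfit.classify(cells["gfp_mean"].to_numpy())
        except ValueError as exc:
            log.warning("transfection gating skipped (%s)", exc)

    fov = summarize_by_fov(cells)

    # per-(plate, media) normalization to the reference condition
    ref = layout.reference_condition
    fov["norm_density"] = np.nan
    fov["norm_mcn"] = np.nan
    for (plate, media), grp in fov.groupby(["plate", "media"]):
        rmask = grp["condition"] == ref
        if not rmask.any():
            log.warning("plate %s media %s: no %r wells; normalization skipped",
                        plate, media, ref)
            continue
        dref = grp.loc[rmask, "n_cells"].mean()
        mref = grp.loc[rmask, "mean_mcn"].mean()
        if dref > 0:
            fov.loc[grp.index, "norm_density"] = grp["n_cells"] / dref
        if np.isfinite(mref) and mref > 0:
            fov.loc[grp.index, "norm_mcn"] = grp["mean_mcn"] / mref

    plate_summary = (
        fov.groupby(["plate", "media", "condition"])
        .agg(n_fov=("fov", "count"), n_cells=("n_cells", "sum"),
             mean_mcn=("mean_mcn", "mean"), norm_mcn=("norm_mcn", "mean"),
             norm_density=("norm_density", "mean"))
        .reset_index())
    return {"cells": cells, "puncta": pnc, "fov": fov,
            "plate_summary": plate_summary, "quantal_fits": quantal_fits}


def summarize_by_fov(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-FOV summaries: counts, means, ploidy-class fractions (sum to 1)."""
    keys = ["plate", "well", "fov"]
    rows = []
    for (plate, well, fov), grp in cells.groupby(keys):
        row = {"plate": plate, "well": well, "fov": fov,
               "condition": grp["condition"].iloc[0] if "condition" in grp else "",
               "media": grp["media"].iloc[0] if "media" in grp else "",
               "n_cells": len(grp),
               "mean_mcn": grp["mcn"].mean() if "mcn" in grp else np.nan,
               "mean_puncta_sum": grp["puncta_sum"].mean()}
        if "dye_mean" in grp:
            row["mean_dye"] = grp["dye_mean"].mean()
        if "ploidy_class" in grp:
            frac = gating.class_fractions(grp["ploidy_class"])
            row.update({f"frac_{c}": frac[c] for c in frac.index})
        rows.append(row)
    return pd.DataFrame(rows)
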