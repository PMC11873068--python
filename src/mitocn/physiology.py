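"""Dye-based physiology readouts: membrane-potential and ROS indices, mass area.

TMRM (potentiometric dye) intensities are mapped to a normalized index using
two pharmacological anchors measured on the same plate: FCCP collapses the
membrane potential (floor, index 0) and oligomycin hyperpolarizes it
(ceiling, index 1).  MitoSOX (superoxide dye, measured in nuclear ROIs at
the concentrations used here) is expressed as fold of a reference population
mean, conventionally the wild-type control diploid cells of the same plate.
Mitochondrial mass is the supra-threshold stained area per cell, counting
only pixels that survive a sub-threshold NaN mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .puncta import mask_subthreshold, thresholded_area_per_roi
from .segmentation import CellROIMap, LabelMap

__all__ = ["DyeNormalization", "normalize_tmrm", "normalize_mitosox",
           "mito_mass_area"]


@dataclass
class DyeNormalization:
    """Per-batch normalization anchors for dye indices.

    ``fccp_mean`` and ``oligo_mean`` are mean dye intensities of the FCCP-
    and oligomycin-treated control wells; ``reference_mean`` is the mean of
    the reference population for ratio normalizations.  A valid TMRM
    normalization requires oligo_mean > fccp_mean.
    """

    fccp_mean: float
    oligo_mean: float
    reference_mean: float | None = None
    batch: str = ""

    def validate_tmrm(self) -> None:
        if not (self.oligo_mean > self.fccp_mean):
            raise ValueError(
                "invalid TMRM normalization: oligomycin-well mean must exceed "
                f"FCCP-well mean (got oligo={self.oligo_mean}, fccp={self.fccp_mean})")


def normalize_tmrm(cell_values, norm: DyeNormalization):
    """Per-cell TMRM index: (I - mean_FCCP) / (mean_oligo - mean_FCCP).

    0 at full depolarization, 1 at the oligomycin ceiling; values outside
    [0, 1] are legitimate.  Exactly affine-invariant: adding a constant to
    all intensities (cells and anchor wells alike) leaves the index unchanged.
    """
    norm.validate_tmrm()
    vals = (cell_values.astype(float) if isinstance(cell_values, pd.Series)
            else np.asarray(cell_values, float))
    return (vals - norm.fccp_mean) / (norm.oligo_mean - norm.fccp_mean)


def normalize_mitosox(cell_values, reference_mean: float):
    """Per-cell MitoSOX index: value / reference mean (fold of reference)."""
    if reference_mean is None or not np.isfinite(reference_mean) or reference_mean <= 0:
        raise ValueError("reference_mean must be a finite positive number")
    vals = (cell_values.astype(float) if isinstance(cell_values, pd.Series)
            else np.asarray(cell_values, float))
    return vals / reference_mean


def mito_mass_area(image: np.ndarray, cell_rois, floor: float) -> pd.Series:
    """Thresholded mitochondrial-stain area per cell, in µm².

    Pixels below ``floor`` are NaN-masked and never count toward the area;
    the result is therefore monotone non-increasing in ``floor``.  Accepts a
    :class:`CellROIMap` (uses the cytosolic compartment) or a bare
    :class:`LabelMap`.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    rois: LabelMap = cell_rois.cytosol if isinstance(cell_rois, CellROIMap) else cell_rois
    masked = mask_subthreshold(image, floor)
    return thresholded_area_per_roi(masked, rois)
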