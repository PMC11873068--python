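"""Shared fixtures: small synthetic fields reused across test modules."""

import numpy as np
import pytest

from mitocn import segmentation
from mitocn.synthgen import SynthFieldConfig, make_field


@pytest.fixture(scope="session")
def sparse_field():
    """A small, well-resolved field: 6 cells, ~60 copies/cell, SNR >> 5."""
    cfg = SynthFieldConfig(
        field_size_px=(768, 768), pixel_size_um=0.62, n_cells=6,
        copies_per_cell_mean=40.0, puncta_placement_radius_um=60.0, seed=11)
    image, truth = make_field(cfg)
    return cfg, image, truth


@pytest.fixture(scope="session")
def sparse_rois(sparse_field):
    """Segmentation of the sparse field: (nuclei, CellROIMap, bg-subtracted dsdna)."""
    cfg, image, _truth = sparse_field
    px = image.pixel_size_um
    nuc = segmentation.subtract_background(image.channels["dna"], 75.0, px)
    nuclei = segmentation.threshold_nuclei(nuc, threshold=7.0, pixel_size_um=px)
    rois = segmentation.voronoi_cell_rois(nuclei)
    ds = segmentation.subtract_background(image.channels["dsdna"], 75.0, px)
    return nuclei, rois, ds, image.channels["dsdna"]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
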