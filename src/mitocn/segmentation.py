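"""Nuclear segmentation and Voronoi-expanded cell ROIs.

Cells in adherent culture are approximated by assigning every pixel to its
nearest nucleus (Euclidean distance to the nuclear mask, i.e. to nuclear
edges rather than centroids), capped at a maximum expansion radius.  The
cytosolic compartment excludes a small dilation ring around the nucleus so
that nuclear signal never leaks into cytosolic measurements.

Conventions: 0-based row-major pixel coordinates at pixel centres; connected
components are 8-connected; areas are reported in µm² using pixel_size².
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import block_reduce, label as cc_label, regionprops
from skimage.restoration import rolling_ball
from skimage.transform import resize

__all__ = [
    "LabelMap",
    "CellROIMap",
    "subtract_background",
    "threshold_nuclei",
    "suggest_threshold",
    "voronoi_cell_rois",
]


@dataclass
class LabelMap:
    """Integer label raster (0 = background) with acquisition metadata."""

    labels: np.ndarray
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)
    connectivity: int = 8

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def areas_um2(self) -> pd.Series:
        ids, counts = np.unique(self.labels[self.labels > 0], return_counts=True)
        return pd.Series(counts * self.pixel_size_um ** 2, index=ids, name="area_um2")

    def table(self) -> pd.DataFrame:
        """Per-ROI table: id, centroid (px), area (µm²)."""
        rows = [
            {"id": p.label,
             "centroid_y": p.centroid[0], "centroid_x": p.centroid[1],
             "area_um2": p.area * self.pixel_size_um ** 2}
            for p in regionprops(self.labels)
        ]
        return pd.DataFrame(rows, columns=["id", "centroid_y", "centroid_x", "area_um2"])

    def to_tiff(self, path) -> None:
        tifffile.imwrite(path, self.labels.astype(np.uint16))


@dataclass
class CellROIMap:
    """Nuclear, whole-cell and cytosolic label maps sharing one id space.

    Every cell ROI contains exactly its nucleus; the cytosolic ROI is the
    cell minus the ``dilation_px``-dilated nucleus, so nuclear and cytosolic
    compartments never overlap.
    """

    nuclei: LabelMap
    cells: LabelMap
    cytosol: LabelMap
    dilation_px: int
    max_expansion_um: float


def subtract_background(image: np.ndarray, radius_um: float,
                        pixel_size_um: float) -> np.ndarray:
    """Rolling-ball background subtraction (morphological, non-negative result).

    The default radius for these cells is 1.5 x the largest expected nuclear
    diameter (~50 µm), i.e. 75 µm.  For large radii the ball is rolled on a
    downscaled copy of the image and the background upsampled, which is the
    standard speed trick for smooth backgrounds and changes the result only
    at the smoothing scale of the background itself.
    """
    if radius_um <= 0:
        raise ValueError("radius_um must be > 0")
    radius_px = radius_um / pixel_size_um
    if radius_px < 2:
        raise ValueError(f"radius of {radius_px:.2f} px is degenerate (< 2 px)")
    img = np.asarray(image, np.float32)
    if radius_px <= 16:
        bg = rolling_ball(img, radius=radius_px)
    else:
        # block-median downsampling keeps small bright structures (puncta)
        # out of the coarse background estimate without the noise-floor bias
        # a block-minimum would introduce
        shrink = int(np.ceil(radius_px / 16.0))
        pad_y = (-img.shape[0]) % shrink
        pad_x = (-img.shape[1]) % shrink
        padded = np.pad(img, ((0, pad_y), (0, pad_x)), mode="edge")
        small = block_reduce(padded, (shrink, shrink), np.median)
        bg_small = rolling_ball(small, radius=radius_px / shrink)
        bg = resize(bg_small, img.shape, order=1, preserve_range=True)
        bg = np.minimum(bg, img)  # a rolled background never exceeds the image
    return np.clip(img - bg, 0.0, None).astype(np.float32)


def suggest_threshold(image: np.ndarray) -> float:
    """Otsu-based threshold suggestion.  Advisory only: segmentation never
    applies it silently; the working threshold is chosen per staining batch."""
    return float(threshold_otsu(np.asarray(image, float)))


def threshold_nuclei(image: np.ndarray, threshold: float,
                     min_area_um2: float = 20.0, max_area_um2: float = 2500.0,
                     pixel_size_um: float = 1.24) -> LabelMap:
    """Label nuclei as size-filtered 8-connected components above a threshold.

    A single intensity threshold is meant to be shared by all images acquired
    in one staining set-up.  NaN pixels never pass the threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    img = np.asarray(image, float)
    with np.errstate(invalid="ignore"):
        mask = img > threshold
    lab = cc_label(mask, connectivity=2)
    px_area = pixel_size_um ** 2
    ids, counts = np.unique(lab[lab > 0], return_counts=True)
    keep = ids[(counts * px_area >= min_area_um2) & (counts * px_area <= max_area_um2)]
    remap = np.zeros(lab.max() + 1, np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    out = remap[lab]
    if keep.size == 0:
        warnings.warn("threshold_nuclei found no nuclei", stacklevel=2)
    return LabelMap(
        labels=out.astype(np.int32), pixel_size_um=pixel_size_um,
        provenance={"channel": "dna", "threshold": float(threshold),
                    "min_area_um2": min_area_um2, "max_area_um2": max_area_um2},
        connectivity=8)


def voronoi_cell_rois(nuclei: LabelMap, dilation_px: int = 4,
                      max_expansion_um: float = 133.0) -> CellROIMap:
    """Expand nuclear ROIs to capped Voronoi cell territories.

    Each background pixel joins the nucleus whose mask is nearest in
    Euclidean distance, provided that distance does not exceed
    ``max_expansion_um``; equidistant pixels go to the lower label id.  The
    cytosolic map excludes everything within ``dilation_px`` of any nucleus.
    """
    labels = nuclei.labels
    ids = nuclei.ids
    if ids.size == 0:
        raise ValueError("voronoi_cell_rois requires at least one nucleus")
    cap_px = max_expansion_um / nuclei.pixel_size_um

    best_d = np.full(labels.shape, np.inf)
    best_l = np.zeros(labels.shape, np.int32)
    objects = ndimage.find_objects(labels)
    pad = int(np.ceil(cap_px)) + 1
    for lab in ids:  # ascending ids + strict '<' gives lower-label tie-breaks
        sl = objects[lab - 1]
        # distances beyond the expansion cap are irrelevant, so the exact
        # transform only needs a cap-padded window around each nucleus
        win = (slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0])),
               slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1])))
        d = ndimage.distance_transform_edt(labels[win] != lab)
        closer = d < best_d[win]
        bd, bl = best_d[win], best_l[win]
        bd[closer] = d[closer]
        bl[closer] = lab
        best_d[win], best_l[win] = bd, bl

    cells = np.where(best_d <= cap_px, best_l, 0).astype(np.int32)
    dist_any = ndimage.distance_transform_edt(labels == 0)
    cytosol = np.where(dist_any > dilation_px, cells, 0).astype(np.int32)

    meta = dict(nuclei.provenance)
    meta.update({"dilation_px": int(dilation_px),
                 "max_expansion_um": float(max_expansion_um)})
    mk = lambda arr: LabelMap(labels=arr, pixel_size_um=nuclei.pixel_size_um,
                              provenance=meta, connectivity=nuclei.connectivity)
    return CellROIMap(nuclei=nuclei, cells=mk(cells), cytosol=mk(cytosol),
                      dilation_px=int(dilation_px),
                      max_expansion_um=float(max_expansion_um))
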