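"""Ploidy and transfection gating.

Ploidy is classified from integrated nuclear-stain intensity versus nuclear
area (image cytometry): diploid G0/G1 cells define a modal intensity m, and
cells at ~2m / ~4m are tetraploid-or-G2/M and octoploid-or-tetraploid-G2/M
("4" and "8" deliberately conflate these, as DNA content alone cannot
separate them); the intensity gaps between consecutive G-gates are S-phase
gates.  Gates are first-class configuration (the assay is gated manually per
batch); :func:`auto_gates_from_g1_peak` exists so that synthetic pipelines
are reproducible without a human in the loop.

Transfection is called from nuclear GFP reporter intensity: the pooled
distribution is fitted with a 3-component Gaussian mixture and every cell
brighter than mu1 + 3*sigma1 of the dim (untransfected background) component
is labelled transfected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = [
    "PloidyGateSet",
    "GfpMixtureFit",
    "GfpMixtureModel",
    "fit_gfp_mixture",
    "gate_ploidy",
    "auto_gates_from_g1_peak",
    "fraction_high",
]


@dataclass
class PloidyGateSet:
    """Axis-aligned 2-D gates over (integrated intensity, nuclear area).

    ``gates`` maps class name -> {"intensity": (lo, hi), "area": (lo, hi)};
    intervals are half-open [lo, hi).  Gates must be pairwise disjoint so
    every cell maps to exactly one class, else to ``"ungated"``.
    """

    gates: dict = field(default_factory=dict)

    CLASS_ORDER = ("2", "2S", "4", "4S", "8", "ungated")

    def __post_init__(self):
        names = list(self.gates)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                ga, gb = self.gates[a], self.gates[b]
                if (self._overlap(ga["intensity"], gb["intensity"])
                        and self._overlap(ga["area"], gb["area"])):
                    raise ValueError(f"gates {a!r} and {b!r} overlap")

    @staticmethod
    def _overlap(r1, r2):
        return max(r1[0], r2[0]) < min(r1[1], r2[1])

    def classify(self, intensity, area) -> pd.Series:
        intensity = np.asarray(intensity, float)
        area = np.asarray(area, float)
        out = np.full(intensity.shape, "ungated", dtype=object)
        for name, g in self.gates.items():
            ilo, ihi = g["intensity"]
            alo, ahi = g["area"]
            hit = ((intensity >= ilo) & (intensity < ihi)
                   & (area >= alo) & (area < ahi))
            out[hit] = name
        return pd.Series(out, name="ploidy_class")

    def scaled(self, factor: float) -> "PloidyGateSet":
        """Gates after a global intensity rescale (boundaries scale linearly)."""
        return PloidyGateSet(gates={
            name: {"intensity": (g["intensity"][0] * factor,
                                 g["intensity"][1] * factor),
                   "area": tuple(g["area"])}
            for name, g in self.gates.items()})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({n: {"intensity": list(map(float, g["intensity"])),
                                "area": list(map(float, g["area"]))}
                            for n, g in self.gates.items()}, fh)

    @classmethod
    def from_yaml(cls, path) -> "PloidyGateSet":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(gates={n: {"intensity": tuple(g["intensity"]),
                              "area": tuple(g["area"])}
                          for n, g in raw.items()})


def gate_ploidy(cells: pd.DataFrame, gates: PloidyGateSet,
                intensity_col: str = "nuclear_intensity",
                area_col: str = "nuclear_area_um2") -> pd.DataFrame:
    """Label each cell record with its ploidy class (adds ``ploidy_class``)."""
    out = cells.copy()
    out["ploidy_class"] = gates.classify(
        out[intensity_col].to_numpy(), out[area_col].to_numpy()).to_numpy()
    return out


def class_fractions(labels: pd.Series) -> pd.Series:
    """Fractions per ploidy class (including 'ungated'); sums to 1."""
    frac = labels.value_counts(normalize=True)
    return frac.reindex(PloidyGateSet.CLASS_ORDER, fill_value=0.0)


def _modal_intensity(intensity: np.ndarray) -> float:
    """Mode of the intensity distribution via a Freedman-Diaconis histogram,
    refined by a second, finer pass around the coarse mode."""
    x = intensity[np.isfinite(intensity) & (intensity > 0)]
    counts, edges = np.histogram(x, bins="fd")
    if counts.size == 0 or counts.max() == 0:
        raise ValueError("no detectable intensity mode")
    i = int(np.argmax(counts))
    lo, hi = edges[max(i - 2, 0)], edges[min(i + 3, edges.size - 1)]
    sel = x[(x >= lo) & (x <= hi)]
    if sel.size >= 10:
        c2, e2 = np.histogram(sel, bins=20)
        j = int(np.argmax(c2))
        return float(0.5 * (e2[j] + e2[j + 1]))
    return float(0.5 * (edges[i] + edges[i + 1]))


def auto_gates_from_g1_peak(cells: pd.DataFrame,
                            intensity_col: str = "nuclear_intensity",
                            area_col: str = "nuclear_area_um2",
                            min_cells: int = 500,
                            area_bounds=None) -> PloidyGateSet:
    """Derive default ploidy gates from the diploid-G1 modal intensity m.

    Boxes: "2" = [0.75m, 1.25m), "4" = [1.5m, 2.5m), "8" = [3m, 5m); the
    S-phase gates fill the gaps between consecutive G-gates.  All gates share
    the same (generous) nuclear-area bounds.  Boundaries scale linearly with
    a global intensity rescale.  Requires >= ``min_cells`` cells.
    """
    if len(cells) < min_cells:
        raise ValueError(f"auto-gating needs >= {min_cells} cells, got {len(cells)}")
    m = _modal_intensity(cells[intensity_col].to_numpy(float))
    if area_bounds is None:
        areas = cells[area_col].to_numpy(float)
        area_bounds = (0.0, float(np.nanmax(areas)) * 2.0 + 1.0)
    area_bounds = tuple(area_bounds)
    return PloidyGateSet(gates={
        "2": {"intensity": (0.75 * m, 1.25 * m), "area": area_bounds},
        "2S": {"intensity": (1.25 * m, 1.5 * m), "area": area_bounds},
        "4": {"intensity": (1.5 * m, 2.5 * m), "area": area_bounds},
        "4S": {"intensity": (2.5 * m, 3.0 * m), "area": area_bounds},
        "8": {"intensity": (3.0 * m, 5.0 * m), "area": area_bounds},
    })


# ---------------------------------------------------------------------------
# transfection gating

@dataclass
class GfpMixtureFit:
    """3-component Gaussian mixture of nuclear GFP intensity, sorted by mean.

    The threshold is mu1 + 3*sigma1 of the dim background component;
    ``transfected_fraction`` is the share of the fitted sample above it.
    """

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    threshold: float
    transfected_fraction: float
    log_likelihood: float
    n_cells: int
    valid: bool = True
    flags: list = field(default_factory=list)

    def classify(self, values) -> np.ndarray:
        """Boolean transfected calls for arbitrary intensity vectors."""
        return np.asarray(values, float) > self.threshold

    def summary(self) -> str:
        rows = "\n".join(
            f"  component {i + 1}: mu={m:10.3f}  sd={s:9.3f}  w={w:.3f}"
            for i, (m, s, w) in enumerate(zip(self.means, self.sds, self.weights)))
        return (
            "Nuclear GFP triple-Gaussian fit\n"
            "===============================\n"
            f"n cells:              {self.n_cells}\n"
            f"{rows}\n"
            f"threshold mu1+3sd1:   {self.threshold:.3f}\n"
            f"transfected fraction: {self.transfected_fraction:.4f}\n"
            f"log-likelihood:       {self.log_likelihood:.2f}\n"
            f"valid:                {self.valid}"
            + (f"  ({'; '.join(self.flags)})" if self.flags else ""))


class GfpMixtureModel:
    """Mixture model of pooled nuclear GFP intensities (one batch)."""

    def __init__(self, values, n_components: int = 3, min_cells: int = 1000):
        x = np.asarray(values, float)
        x = x[np.isfinite(x)]
        if x.size < min_cells:
            raise ValueError(f"need >= {min_cells} cells, got {x.size}")
        self.values = x
        self.n_components = n_components

    def fit(self, seed: int = 0, n_init: int = 10, tol: float = 1e-8) -> GfpMixtureFit:
        """EM fit (k-means++ init, multi-restart, seeded); means sorted ascending."""
        x = self.values
        gm = GaussianMixture(n_components=self.n_components, n_init=n_init,
                             tol=tol, init_params="k-means++",
                             random_state=seed, max_iter=500)
        gm.fit(x[:, None])
        order = np.argsort(gm.means_.ravel())
        means = gm.means_.ravel()[order]
        sds = np.sqrt(gm.covariances_.ravel()[order])
        weights = gm.weights_[order]
        thr = float(means[0] + 3.0 * sds[0])
        frac = float(np.mean(x > thr))
        flags, valid = [], True
        if sds[0] <= 0:
            flags.append("degenerate first component (sigma1 <= 0)")
            valid = False
        if weights[0] < 0.2:
            flags.append("first component weight < 0.2")
            valid = False
        ll = float(gm.score(x[:, None]) * x.size)
        return GfpMixtureFit(means=means, sds=sds, weights=weights,
                             threshold=thr, transfected_fraction=frac,
                             log_likelihood=ll, n_cells=x.size,
                             valid=valid, flags=flags)

    def null_log_likelihood(self) -> float:
        """Log-likelihood of the best single-Gaussian fit (nesting sanity)."""
        x = self.values
        mu, sd = x.mean(), x.std()
        return float(norm.logpdf(x, mu, max(sd, 1e-12)).sum())


def fit_gfp_mixture(nuclear_gfp, min_cells: int = 1000, seed: int = 0,
                    **fit_kw) -> GfpMixtureFit:
    """Convenience wrapper: build :class:`GfpMixtureModel` and fit it."""
    return GfpMixtureModel(nuclear_gfp, min_cells=min_cells).fit(seed=seed, **fit_kw)


def fraction_high(values, floor: float) -> float:
    """Share of cells with value strictly above ``floor`` (e.g. 'high' ROS cells)."""
    if floor < 0:
        raise ValueError("floor must be >= 0")
    x = np.asarray(values, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("fraction_high of an empty sample is undefined")
    return float(np.mean(x > floor))
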