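"""Duplex droplet digital PCR quantification of absolute mtDNA copy number.

A duplex EvaGreen reaction partitions the sample into ~20,000 droplets; the
2-D intensity plot shows four populations (empty, mitochondrial-target-only,
nuclear-reference-only, double-positive).  Each target's mean occupancy
(copies/droplet) follows from the Poisson void probability,
lambda = -ln(fraction negative), and the absolute mtDNA copies per cell is
the ratio of the mitochondrial concentration to the per-cell-equivalent
nuclear-reference concentration:

    copies_per_cell = lambda_mito / (lambda_ref / loci_per_cell)

``loci_per_cell`` defaults to 6 — the nuclear reference primers amplify
three loci per haploid genome and the cells are taken as diploid.  This
factor scales the result 2x, so it is a prominent, explicit parameter.
Droplet volumes cancel in the ratio, so no copies/µL output is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["DropletAssay", "ConcentrationEstimate", "classify_droplets",
           "poisson_concentration", "copies_per_cell"]

CLASSES = ("negative", "ND1-only", "ACTB-only", "double")


def _two_means_split(values: np.ndarray, max_iter: int = 100):
    """Deterministic 1-D 2-means: returns (threshold, separation score).

    Initialized at the extremes; the threshold is the midpoint between the
    converged cluster means (the valley of a well-separated bimodal sample).
    The separation score is (m2 - m1) / (s1 + s2).
    """
    lo, hi = float(values.min()), float(values.max())
    c1, c2 = lo, hi
    for _ in range(max_iter):
        mid = 0.5 * (c1 + c2)
        left = values[values <= mid]
        right = values[values > mid]
        if left.size == 0 or right.size == 0:
            break
        n1, n2 = float(left.mean()), float(right.mean())
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    mid = 0.5 * (c1 + c2)
    left = values[values <= mid]
    right = values[values > mid]
    spread = (left.std() if left.size else 0.0) + (right.std() if right.size else 0.0)
    sep = (c2 - c1) / spread if spread > 0 else np.inf
    return mid, sep


def _has_valley(values: np.ndarray, split: float, depth: float = 0.7) -> bool:
    """True when the smoothed intensity histogram dips at the split point,
    i.e. the channel really is bimodal rather than a single cloud."""
    counts, edges = np.histogram(values, bins=100)
    sm = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    idx = int(np.clip(np.searchsorted(edges, split) - 1, 0, sm.size - 1))
    d_lo = sm[:idx].max() if idx > 0 else 0.0
    d_hi = sm[idx + 1:].max() if idx + 1 < sm.size else 0.0
    if d_lo == 0.0 or d_hi == 0.0:
        return False
    return sm[idx] < depth * min(d_lo, d_hi)


def classify_droplets(table: pd.DataFrame, gates="auto",
                      min_droplets_auto: int = 1000,
                      min_separation: float = 3.0) -> pd.DataFrame:
    """Quadrant-gate droplets into the four duplex populations.

    ``gates`` is either "auto" (per-channel two-cluster valley split) or a
    ``(channel1_threshold, channel2_threshold)`` pair.  Labels are written to
    a ``droplet_class`` column; re-gating already-gated tables is idempotent.
    In auto mode a channel whose clusters are not separated by at least
    ``min_separation`` pooled standard deviations is flagged in
    ``table.attrs["gating_flags"]`` (a saturated or all-negative channel is
    unimodal by construction and is not flagged).
    """
    out = table.copy()
    flags = []
    if gates == "auto":
        if len(out) < min_droplets_auto:
            raise ValueError(
                f"auto gating needs >= {min_droplets_auto} droplets, got {len(out)}")
        thr = []
        for ch in ("channel1", "channel2"):
            v = out[ch].to_numpy(float)
            t, sep = _two_means_split(v)
            if not _has_valley(v, t):
                # unimodal channel: a lone cloud cannot be told positive from
                # negative without anchors; gate above it (all-negative call)
                t = float(v.mean() + 5.0 * v.std() + 1.0)
                flags.append(f"{ch}: not bimodal; gated as all-negative")
            elif sep < min_separation:
                flags.append(f"{ch}: clusters poorly separated (score {sep:.2f})")
            thr.append(t)
        t1, t2 = thr
    else:
        t1, t2 = gates
    pos1 = out["channel1"].to_numpy(float) > t1
    pos2 = out["channel2"].to_numpy(float) > t2
    cls = np.where(pos1 & pos2, "double",
                   np.where(pos1, "ND1-only",
                            np.where(pos2, "ACTB-only", "negative")))
    out["droplet_class"] = cls
    out.attrs["gates"] = (float(t1), float(t2))
    out.attrs["gating_flags"] = flags
    return out


def poisson_concentration(n_negative_for_target: int, n_total: int):
    """Mean copies/droplet from the Poisson void probability.

    lambda = -ln(n_negative / n_total).  With zero negative droplets the
    assay is saturated and only a lower bound -ln(1/n_total) can be
    reported; a warning is raised and the bound returned.
    """
    if n_total <= 0:
        raise ValueError("n_total must be > 0")
    if not 0 <= n_negative_for_target <= n_total:
        raise ValueError("n_negative must lie in [0, n_total]")
    if n_negative_for_target == 0:
        warnings.warn(
            "no negative droplets: assay saturated, returning the lower "
            "bound -ln(1/n_total)", stacklevel=2)
        return float(np.log(n_total))
    return float(-np.log(n_negative_for_target / n_total))


def copies_per_cell(lambda_nd1: float, lambda_actb: float,
                    loci_per_cell: float = 6.0) -> float:
    """Absolute mtDNA copies per cell from the two target concentrations."""
    if lambda_actb <= 0:
        raise ValueError("lambda_actb must be > 0 (no cell-equivalent denominator)")
    if loci_per_cell < 1:
        raise ValueError("loci_per_cell must be >= 1")
    return float(lambda_nd1 / (lambda_actb / loci_per_cell))


@dataclass
class ConcentrationEstimate:
    """Poisson-corrected concentrations and the per-cell copy number.

    Confidence intervals are propagated from the binomial uncertainty of the
    negative fraction for each target.
    """

    lambda_nd1: float
    lambda_actb: float
    n_droplets: int
    loci_per_cell: float
    copies_per_cell: float
    lambda_nd1_ci: tuple
    lambda_actb_ci: tuple
    flags: list = field(default_factory=list)

    def summary(self) -> str:
        return (
            "ddPCR concentration estimate\n"
            "============================\n"
            f"droplets:            {self.n_droplets}\n"
            f"lambda ND1:          {self.lambda_nd1:.4f} copies/droplet "
            f"(95% CI {self.lambda_nd1_ci[0]:.4f}-{self.lambda_nd1_ci[1]:.4f})\n"
            f"lambda ACTB:         {self.lambda_actb:.4f} copies/droplet "
            f"(95% CI {self.lambda_actb_ci[0]:.4f}-{self.lambda_actb_ci[1]:.4f})\n"
            f"reference loci/cell: {self.loci_per_cell:g}\n"
            f"mtDNA copies/cell:   {self.copies_per_cell:.1f}"
            + (f"\nflags: {'; '.join(self.flags)}" if self.flags else ""))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "lambda_nd1": self.lambda_nd1, "lambda_actb": self.lambda_actb,
            "n_droplets": self.n_droplets, "loci_per_cell": self.loci_per_cell,
            "copies_per_cell": self.copies_per_cell,
        }])


def _lambda_ci(n_neg: int, n_total: int, z: float = 1.96) -> tuple:
    p = max(n_neg, 1) / n_total
    se = np.sqrt(p * (1 - p) / n_total)
    hi_p = min(p + z * se, 1.0)
    lo_p = max(p - z * se, 1.0 / n_total)
    return (float(-np.log(hi_p)), float(-np.log(lo_p)))


class DropletAssay:
    """Duplex ddPCR assay model over a per-droplet two-channel table.

    Statsmodels-style: construct from the droplet table, ``fit()`` returns a
    :class:`ConcentrationEstimate`.  The table needs ``channel1`` (mito
    target) and ``channel2`` (nuclear reference) columns; a QX200-style
    amplitude CSV (``Ch1 Amplitude``/``Ch2 Amplitude``) is accepted too.
    """

    def __init__(self, table: pd.DataFrame, loci_per_cell: float = 6.0):
        table = table.rename(columns={
            "Ch1 Amplitude": "channel1", "Ch2 Amplitude": "channel2"})
        if not {"channel1", "channel2"} <= set(table.columns):
            raise ValueError("droplet table needs channel1/channel2 columns")
        self.table = table
        self.loci_per_cell = float(loci_per_cell)

    @classmethod
    def from_csv(cls, path, **kw) -> "DropletAssay":
        return cls(pd.read_csv(path), **kw)

    def plot(self, ax=None):
        """2-D droplet intensity plot coloured by class (requires fit())."""
        import matplotlib.pyplot as plt

        if not hasattr(self, "gated_"):
            raise RuntimeError("call fit() before plot()")
        if ax is None:
            _fig, ax = plt.subplots()
        colors = {"negative": "grey", "ND1-only": "C0",
                  "ACTB-only": "C2", "double": "C1"}
        for cls, col in colors.items():
            sub = self.gated_[self.gated_["droplet_class"] == cls]
            ax.plot(sub["channel1"], sub["channel2"], ".", ms=2, color=col,
                    label=f"{cls} ({len(sub)})")
        ax.set_xlabel("channel 1 amplitude (mitochondrial target)")
        ax.set_ylabel("channel 2 amplitude (nuclear reference)")
        ax.legend(markerscale=4)
        return ax

    def fit(self, gates="auto") -> ConcentrationEstimate:
        gated = classify_droplets(self.table, gates=gates)
        self.gated_ = gated
        cls = gated["droplet_class"]
        n = len(gated)
        neg1 = int(((cls == "negative") | (cls == "ACTB-only")).sum())
        neg2 = int(((cls == "negative") | (cls == "ND1-only")).sum())
        flags = list(gated.attrs.get("gating_flags", []))
        lam1 = poisson_concentration(neg1, n)
        lam2 = poisson_concentration(neg2, n)
        if neg1 == 0:
            flags.append("ND1 saturated: lambda_nd1 is a lower bound")
        if neg2 == 0:
            flags.append("ACTB saturated: lambda_actb is a lower bound")
        cpc = copies_per_cell(lam1, lam2, self.loci_per_cell) if lam2 > 0 else np.nan
        if lam2 == 0:
            flags.append("lambda_actb = 0: copies/cell undefined")
        return ConcentrationEstimate(
            lambda_nd1=lam1, lambda_actb=lam2, n_droplets=n,
            loci_per_cell=self.loci_per_cell, copies_per_cell=cpc,
            lambda_nd1_ci=_lambda_ci(neg1, n), lambda_actb_ci=_lambda_ci(neg2, n),
            flags=flags)
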