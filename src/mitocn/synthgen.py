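"""Seeded synthetic data carrying the statistical structure the analysis assumes.

This module emulates the four data streams of a high-content mitochondrial
DNA copy-number (mCN) study on cultured smooth-muscle-like cells:

* multi-channel fluorescence fields: a nuclear DNA stain whose integrated
  intensity scales with genome copies (mixed-ploidy populations), anti-dsDNA
  puncta whose integrated intensities are integer multiples of a quantal
  single-copy nucleoid intensity ``q`` plus Gaussian noise, a nuclear GFP
  transfection reporter drawn from a 3-component mixture, and a physiology
  dye channel (TMRM/MitoSOX-like) with per-ploidy means;
* duplex ddPCR droplet tables with independent Poisson occupancy per target
  and well-separated intensity clusters;
* exponential growth-count time series with Poisson count noise;
* Mito-Stress-Test oxygen-consumption traces with four drug phases.

Every generator records ground truth so recovery tests can compare estimates
against the numbers that were actually simulated.  A single master seed
drives deterministic child streams; identical (config, seed) pairs produce
bit-identical output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "PLOIDY_CLASSES",
    "PLOIDY_GENOME_COPIES",
    "SynthFieldConfig",
    "GroundTruth",
    "FieldImage",
    "OvercrowdingError",
    "make_field",
    "draw_gfp_intensities",
    "make_droplets",
    "make_growth_counts",
    "make_ocr_trace",
    "OCRTrace",
]

#: Ploidy classes tracked by the generator and the gating stage.  "S" classes
#: are S-phase populations with intermediate (replicating) DNA content.
PLOIDY_CLASSES = ("2N", "2S", "4N", "4S", "8N")

#: Nuclear genome copies per ploidy class (S-phase cells mid-replication).
PLOIDY_GENOME_COPIES = {"2N": 2.0, "2S": 3.0, "4N": 4.0, "4S": 6.0, "8N": 8.0}


class OvercrowdingError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap within the retry budget."""


def _default_ploidy_weights() -> dict:
    return {"2N": 0.55, "2S": 0.08, "4N": 0.25, "4S": 0.04, "8N": 0.08}


def _default_nuclear_radii() -> dict:
    # area proportional to genome copies: r = r2 * sqrt(copies / 2)
    r2 = 9.0
    return {c: r2 * math.sqrt(PLOIDY_GENOME_COPIES[c] / 2.0) for c in PLOIDY_CLASSES}


def _default_copy_weights() -> tuple:
    # geometric with mode at copy number 1: most puncta are single-copy nucleoids
    ratio = 0.45
    w = np.array([ratio ** k for k in range(10)])
    w /= w.sum()
    return tuple(float(x) for x in w)


def _default_gfp_params() -> tuple:
    # (mean, sd, weight): background, dim-transfected, bright-transfected
    return ((100.0, 20.0, 0.75), (500.0, 80.0, 0.15), (2000.0, 300.0, 0.10))


def _default_dye_means() -> dict:
    # nuclear MitoSOX-like means by base ploidy (a.u.)
    return {"2N": 95.0, "2S": 95.0, "4N": 205.0, "4S": 205.0, "8N": 264.0}


@dataclass
class SynthFieldConfig:
    """Parameters of one synthetic field of view.

    Intensities are in arbitrary units (a.u.), lengths in µm, and the
    rendered rasters are float arrays on a 16-bit-like scale.
    """

    field_size_px: tuple = (1024, 1024)
    pixel_size_um: float = 1.24
    n_cells: int = 100
    ploidy_weights: Mapping[str, float] = field(default_factory=_default_ploidy_weights)
    nuclear_radius_um: Mapping[str, float] = field(default_factory=lambda: {
        c: r * 1.24 for c, r in _default_nuclear_radii().items()
    })
    nuclear_intensity_per_genome: float = 5000.0
    nuclear_cv: float = 0.08
    quantal_intensity: float = 100.0
    copies_per_cell_mean: float = 400.0
    copies_per_cell_dispersion: float = 0.15
    puncta_copy_weights: Sequence[float] = field(default_factory=_default_copy_weights)
    puncta_sigma: float = 8.0
    psf_sigma_px: float = 1.5
    puncta_placement_radius_um: float = 110.0
    transfected_fraction: float = 0.25
    gfp_component_params: Sequence = field(default_factory=_default_gfp_params)
    dye_means: Mapping[str, float] = field(default_factory=_default_dye_means)
    dye_cv: float = 0.10
    background_level: float = 20.0
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        pw = np.array([self.ploidy_weights.get(c, 0.0) for c in PLOIDY_CLASSES], float)
        if abs(pw.sum() - 1.0) > 1e-9:
            raise ValueError(f"ploidy_weights must sum to 1, got {pw.sum()!r}")
        if (pw < 0).any():
            raise ValueError("ploidy_weights must be non-negative")
        cw = np.asarray(self.puncta_copy_weights, float)
        if abs(cw.sum() - 1.0) > 1e-9:
            raise ValueError(f"puncta_copy_weights must sum to 1, got {cw.sum()!r}")
        if (cw < 0).any():
            raise ValueError("puncta_copy_weights must be non-negative")
        for name in ("pixel_size_um", "nuclear_intensity_per_genome",
                     "quantal_intensity", "psf_sigma_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must lie in [0, 1]")
        for cls in PLOIDY_CLASSES:
            if self.nuclear_radius_um.get(cls, 1.0) <= 0:
                raise ValueError("nuclear radii must be > 0")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["field_size_px"] = list(d["field_size_px"])
        d["ploidy_weights"] = dict(d["ploidy_weights"])
        d["nuclear_radius_um"] = dict(d["nuclear_radius_um"])
        d["dye_means"] = dict(d["dye_means"])
        d["puncta_copy_weights"] = [float(x) for x in d["puncta_copy_weights"]]
        d["gfp_component_params"] = [list(p) for p in d["gfp_component_params"]]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthFieldConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["field_size_px"] = tuple(d["field_size_px"])
        d["puncta_copy_weights"] = tuple(d["puncta_copy_weights"])
        d["gfp_component_params"] = tuple(tuple(p) for p in d["gfp_component_params"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-object truth for a generated field.

    ``cells`` has one row per cell (ploidy, genome copies, transfection flag,
    true mtDNA copy count, GFP and dye draws); ``puncta`` has one row per
    rendered punctum (owner cell, centroid, copy number, noiseless-free
    rendered intensity).  The per-cell ``true_copies`` equals the sum of its
    puncta ``copies`` exactly.
    """

    cells: pd.DataFrame
    puncta: pd.DataFrame

    def to_csv(self, cells_path, puncta_path) -> None:
        self.cells.to_csv(cells_path, index=False)
        self.puncta.to_csv(puncta_path, index=False)


@dataclass
class FieldImage:
    """One field of view: named channel rasters plus acquisition metadata."""

    channels: dict
    pixel_size_um: float
    bit_depth: int = 16
    truth: GroundTruth | None = None

    def to_tiff(self, path) -> None:
        """Write a multi-page 16-bit TIFF, one page per channel (sorted names)."""
        names = sorted(self.channels)
        stack = np.stack(
            [np.clip(self.channels[n], 0, 2 ** self.bit_depth - 1).astype(np.uint16)
             for n in names]
        )
        tifffile.imwrite(path, stack, photometric="minisblack", metadata={
            "axes": "CYX",
            "channel_names": names,
            "pixel_size_um": self.pixel_size_um,
        })

    @classmethod
    def from_tiff(cls, path, channel_names=None, pixel_size_um=None) -> "FieldImage":
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        if stack.ndim == 2:
            stack = stack[None]
        names = channel_names or meta.get("channel_names") or [
            f"ch{i}" for i in range(stack.shape[0])
        ]
        px = pixel_size_um or meta.get("pixel_size_um") or 1.0
        return cls(
            channels={n: stack[i].astype(np.float32) for i, n in enumerate(names)},
            pixel_size_um=float(px),
        )


# ---------------------------------------------------------------------------
# rendering helpers

def _add_gaussian_spot(img: np.ndarray, y: float, x: float, total: float,
                       sigma: float) -> None:
    """Add an isotropic Gaussian spot with the given integrated intensity in place."""
    r = max(2, int(math.ceil(4 * sigma)))
    yy0, yy1 = int(round(y)) - r, int(round(y)) + r + 1
    xx0, xx1 = int(round(x)) - r, int(round(x)) + r + 1
    ys = np.arange(max(yy0, 0), min(yy1, img.shape[0]))
    xs = np.arange(max(xx0, 0), min(xx1, img.shape[1]))
    if ys.size == 0 or xs.size == 0:
        return
    gy = np.exp(-0.5 * ((ys - y) / sigma) ** 2)
    gx = np.exp(-0.5 * ((xs - x) / sigma) ** 2)
    kern = np.outer(gy, gx)
    kern *= total / (2 * math.pi * sigma * sigma)
    img[ys[0]:ys[-1] + 1, xs[0]:xs[-1] + 1] += kern


def _add_disk(img: np.ndarray, y: float, x: float, radius: float,
              total: float) -> None:
    """Add an anti-aliased disk carrying the given integrated intensity in place."""
    r = int(math.ceil(radius)) + 2
    ys = np.arange(max(int(y) - r, 0), min(int(y) + r + 1, img.shape[0]))
    xs = np.arange(max(int(x) - r, 0), min(int(x) + r + 1, img.shape[1]))
    if ys.size == 0 or xs.size == 0:
        return
    dist = np.hypot(ys[:, None] - y, xs[None, :] - x)
    w = np.clip(radius + 0.5 - dist, 0.0, 1.0)
    s = w.sum()
    if s > 0:
        img[ys[0]:ys[-1] + 1, xs[0]:xs[-1] + 1] += w * (total / s)


def _fill_disk(img: np.ndarray, y: float, x: float, radius: float,
               value: float) -> None:
    """Set pixels inside a disk to ``value`` (hard mask, additive) in place."""
    r = int(math.ceil(radius)) + 1
    ys = np.arange(max(int(y) - r, 0), min(int(y) + r + 1, img.shape[0]))
    xs = np.arange(max(int(x) - r, 0), min(int(x) + r + 1, img.shape[1]))
    if ys.size == 0 or xs.size == 0:
        return
    dist = np.hypot(ys[:, None] - y, xs[None, :] - x)
    sub = img[ys[0]:ys[-1] + 1, xs[0]:xs[-1] + 1]
    sub[dist <= radius] += value


def _place_nuclei(rng, shape, radii_px, margin=2.0, max_tries_per_cell=400):
    """Rejection-sample non-overlapping nucleus centres; raise on overcrowding."""
    h, w = shape
    centres = []
    placed_r = []
    for i, r in enumerate(radii_px):
        ok = False
        for _ in range(max_tries_per_cell):
            y = rng.uniform(r + 1, h - r - 1)
            x = rng.uniform(r + 1, w - r - 1)
            if all((y - cy) ** 2 + (x - cx) ** 2 >= (r + cr + margin) ** 2
                   for (cy, cx), cr in zip(centres, placed_r)):
                ok = True
                break
        if not ok:
            raise OvercrowdingError(
                f"could not place nucleus {i + 1}/{len(radii_px)} after "
                f"{max_tries_per_cell} tries; reduce n_cells or enlarge the field"
            )
        centres.append((y, x))
        placed_r.append(r)
    return centres


def draw_gfp_intensities(config: SynthFieldConfig, n: int, rng) -> tuple:
    """Draw per-cell nuclear GFP means and transfection flags.

    Untransfected cells come from the first (background) component; transfected
    cells from the second/third components with their relative weights.
    Returns ``(gfp_values, transfected_flags)``.
    """
    (m1, s1, _w1), (m2, s2, w2), (m3, s3, w3) = config.gfp_component_params
    flags = rng.random(n) < config.transfected_fraction
    vals = rng.normal(m1, s1, size=n)
    if flags.any():
        hi = rng.random(flags.sum()) < (w3 / (w2 + w3))
        tv = np.where(hi, rng.normal(m3, s3, size=flags.sum()),
                      rng.normal(m2, s2, size=flags.sum()))
        vals[flags] = tv
    return np.clip(vals, 0.0, None), flags


def make_field(config: SynthFieldConfig) -> tuple:
    """Render one synthetic field and its ground truth.

    Channels: ``dna`` (nuclear stain), ``dsdna`` (cytosolic nucleoid puncta),
    ``gfp`` (nuclear transfection reporter), ``dye`` (nuclear physiology dye).
    Nuclei are anti-aliased disks whose integrated intensity is proportional to
    genome copies (with ``nuclear_cv`` lognormal-free multiplicative scatter);
    puncta are Gaussian spots of integrated intensity ``k*q + N(0, σ√k)``
    placed in the cytosol, never inside a nucleus (the nuclear stain is not
    visible inside mitochondria, and vice versa).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.field_size_px
    shape = (int(h), int(w))
    px = config.pixel_size_um

    channels = {name: np.zeros(shape, np.float32)
                for name in ("dna", "dsdna", "gfp", "dye")}

    n = config.n_cells
    classes = np.array(PLOIDY_CLASSES)
    pw = np.array([config.ploidy_weights.get(c, 0.0) for c in PLOIDY_CLASSES])
    ploidy = rng.choice(classes, size=n, p=pw / pw.sum()) if n else np.array([], str)
    radii_px = np.array([config.nuclear_radius_um[c] / px for c in ploidy])
    centres = _place_nuclei(rng, shape, radii_px) if n else []

    genome = np.array([PLOIDY_GENOME_COPIES[c] for c in ploidy])
    nuc_total = (genome * config.nuclear_intensity_per_genome
                 * (1.0 + config.nuclear_cv * rng.standard_normal(n)))
    gfp_vals, transfected = draw_gfp_intensities(config, n, rng)
    base = {"2S": "2N", "4S": "4N"}
    dye_mu = np.array([config.dye_means.get(c, config.dye_means.get(base.get(c, c), 0.0))
                       for c in ploidy]) if n else np.array([])
    dye_vals = np.clip(dye_mu * (1.0 + config.dye_cv * rng.standard_normal(n)), 0, None)

    # expected copies per cell: mean with extra-Poisson between-cell dispersion
    disp = config.copies_per_cell_dispersion
    cell_mu = config.copies_per_cell_mean * np.clip(
        1.0 + disp * rng.standard_normal(n), 0.05, None)
    copy_w = np.asarray(config.puncta_copy_weights, float)
    copy_w = copy_w / copy_w.sum()
    kvals = np.arange(1, copy_w.size + 1)
    mean_copy = float((kvals * copy_w).sum())

    # occupancy mask of all nuclei, for cytosolic punctum placement
    nuc_mask_u8 = np.zeros(shape, np.uint8)
    for (cy, cx), r in zip(centres, radii_px):
        _fill_disk(nuc_mask_u8, cy, cx, r, 1)
    nuc_mask = nuc_mask_u8 > 0

    cell_rows = []
    punct_rows = []
    place_r = config.puncta_placement_radius_um / px
    q = config.quantal_intensity
    for i in range(n):
        cy, cx = centres[i]
        n_punct = rng.poisson(cell_mu[i] / mean_copy)
        copies = rng.choice(kvals, size=n_punct, p=copy_w) if n_punct else np.array([], int)
        intens = copies * q + config.puncta_sigma * np.sqrt(copies) * rng.standard_normal(n_punct)
        intens = np.clip(intens, 0.05 * q, None)
        for k, inten in zip(copies, intens):
            for _ in range(200):
                ang = rng.uniform(0, 2 * math.pi)
                rad = (radii_px[i] + 2.0) + (place_r - radii_px[i] - 2.0) * math.sqrt(rng.random())
                py, pxx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                iy, ix = int(round(py)), int(round(pxx))
                if 0 <= iy < shape[0] and 0 <= ix < shape[1] and not nuc_mask[iy, ix]:
                    break
            else:  # pragma: no cover - placement virtually never exhausts retries
                continue
            _add_gaussian_spot(channels["dsdna"], py, pxx, float(inten),
                               config.psf_sigma_px)
            punct_rows.append((i + 1, py, pxx, int(k), float(inten)))

        _add_disk(channels["dna"], cy, cx, radii_px[i], float(nuc_total[i]))
        _fill_disk(channels["gfp"], cy, cx, radii_px[i], float(gfp_vals[i]))
        _fill_disk(channels["dye"], cy, cx, radii_px[i], float(dye_vals[i]))

        cell_rows.append({
            "cell_id": i + 1, "y": cy, "x": cx, "ploidy": ploidy[i],
            "genome_copies": genome[i], "nuclear_radius_px": radii_px[i],
            "nuclear_total_intensity": nuc_total[i],
            "transfected": bool(transfected[i]),
            "gfp_value": gfp_vals[i], "dye_value": dye_vals[i],
        })

    puncta_df = pd.DataFrame(
        punct_rows, columns=["cell_id", "y", "x", "copies", "intensity"])
    cells_df = pd.DataFrame(cell_rows, columns=[
        "cell_id", "y", "x", "ploidy", "genome_copies", "nuclear_radius_px",
        "nuclear_total_intensity", "transfected", "gfp_value", "dye_value"])
    if len(cells_df):
        tc = puncta_df.groupby("cell_id")["copies"].sum()
        cells_df["true_copies"] = cells_df["cell_id"].map(tc).fillna(0).astype(int)
        npx = puncta_df.groupby("cell_id").size()
        cells_df["n_puncta"] = cells_df["cell_id"].map(npx).fillna(0).astype(int)
    else:
        cells_df["true_copies"] = pd.Series([], dtype=int)
        cells_df["n_puncta"] = pd.Series([], dtype=int)

    for name, img in channels.items():
        img += config.background_level
        img += config.noise_sd * rng.standard_normal(shape).astype(np.float32)
        np.clip(img, 0, None, out=img)

    truth = GroundTruth(cells=cells_df, puncta=puncta_df)
    return FieldImage(channels=channels, pixel_size_um=px, truth=truth), truth


# ---------------------------------------------------------------------------
# droplets

def make_droplets(lambda_nd1: float, lambda_actb: float, n_droplets: int,
                  intensity_model: Mapping | None = None,
                  seed: int = 0) -> pd.DataFrame:
    """Simulate duplex ddPCR droplets with independent Poisson occupancy.

    Channel 1 reports the mitochondrial target (ND1), channel 2 the nuclear
    reference (ACTB); occupied and empty droplets form well-separated
    intensity clusters, yielding the four populations of a duplex EvaGreen
    assay.  True occupancies are recorded per droplet.
    """
    if lambda_nd1 < 0 or lambda_actb < 0:
        raise ValueError("occupancies must be >= 0")
    if n_droplets < 1:
        raise ValueError("n_droplets must be >= 1")
    model = {"neg_mean": 1000.0, "neg_sd": 60.0,
             "pos_mean_ch1": 5000.0, "pos_mean_ch2": 6000.0, "pos_sd": 150.0}
    if intensity_model:
        model.update(intensity_model)
    rng = np.random.default_rng(seed)
    occ1 = rng.poisson(lambda_nd1, n_droplets)
    occ2 = rng.poisson(lambda_actb, n_droplets)
    ch1 = np.where(occ1 > 0,
                   rng.normal(model["pos_mean_ch1"], model["pos_sd"], n_droplets),
                   rng.normal(model["neg_mean"], model["neg_sd"], n_droplets))
    ch2 = np.where(occ2 > 0,
                   rng.normal(model["pos_mean_ch2"], model["pos_sd"], n_droplets),
                   rng.normal(model["neg_mean"], model["neg_sd"], n_droplets))
    return pd.DataFrame({
        "channel1": ch1, "channel2": ch2,
        "true_nd1_copies": occ1, "true_actb_copies": occ2,
    })


# ---------------------------------------------------------------------------
# growth

def make_growth_counts(n0: float, k: float, offset: float = 0.0,
                       t_end: float = 72.0, dt: float = 1.0 / 3.0,
                       noise_model: str = "poisson", seed: int = 0,
                       max_count: float | None = None) -> pd.DataFrame:
    """Exponential growth-count series: count = offset + n0·e^{k t} plus noise.

    Times are in hours.  ``noise_model`` is ``"poisson"`` (counts drawn from
    Poisson with the expected value as mean), ``"none"`` or ``"gaussian"``
    (sd = sqrt(expected)).  Counts exceeding ``max_count`` (confluence) are
    truncated and flagged in the ``truncated`` column.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if t_end < dt:
        raise ValueError("t_end must be >= dt")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + dt / 2, dt)
    expected = offset + n0 * np.exp(k * t)
    if noise_model == "poisson":
        count = rng.poisson(np.clip(expected, 0, None)).astype(float)
    elif noise_model == "gaussian":
        count = expected + rng.standard_normal(t.size) * np.sqrt(np.clip(expected, 0, None))
    elif noise_model == "none":
        count = expected.copy()
    else:
        raise ValueError(f"unknown noise_model {noise_model!r}")
    truncated = np.zeros(t.size, bool)
    if max_count is not None:
        truncated = count > max_count
        count = np.minimum(count, max_count)
    return pd.DataFrame({"time_h": t, "count": count, "truncated": truncated})


# ---------------------------------------------------------------------------
# OCR traces

@dataclass
class OCRTrace:
    """A Mito-Stress-Test oxygen-consumption trace.

    ``time_min``/``ocr`` are the measurements; the injection times mark the
    additions of oligomycin, FCCP and rotenone/antimycin-A, splitting the
    trace into basal / post-oligo / post-FCCP / post-rot-AA phases.
    """

    time_min: np.ndarray
    ocr: np.ndarray
    t_oligo: float
    t_fccp: float
    t_rot_aa: float
    n_cells: int | None = None

    def phases(self) -> dict:
        t = self.time_min
        return {
            "basal": t < self.t_oligo,
            "oligo": (t >= self.t_oligo) & (t < self.t_fccp),
            "fccp": (t >= self.t_fccp) & (t < self.t_rot_aa),
            "rot_aa": t >= self.t_rot_aa,
        }

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_min": self.time_min, "ocr": self.ocr}).to_csv(
            path, index=False)


def make_ocr_trace(levels: Sequence[float], n_measurements_per_phase: int = 3,
                   noise_sd: float = 0.0, seed: int = 0,
                   dt_min: float = 3.0) -> OCRTrace:
    """Stepwise OCR trace with one mean level per drug phase.

    ``levels`` are the (basal, post-oligomycin, post-FCCP, post-rot/AA) phase
    means in pmol O2/min/well; each phase contributes
    ``n_measurements_per_phase`` points at ``dt_min``-minute increments.
    """
    if len(levels) != 4:
        raise ValueError("levels must have 4 entries (basal, oligo, FCCP, rot/AA)")
    if n_measurements_per_phase < 3:
        raise ValueError("need >= 3 measurements per phase")
    rng = np.random.default_rng(seed)
    npp = n_measurements_per_phase
    t = np.arange(4 * npp) * dt_min
    ocr = np.repeat(np.asarray(levels, float), npp)
    if noise_sd > 0:
        ocr = ocr + noise_sd * rng.standard_normal(t.size)
    return OCRTrace(time_min=t, ocr=ocr,
                    t_oligo=t[npp] - dt_min / 2,
                    t_fccp=t[2 * npp] - dt_min / 2,
                    t_rot_aa=t[3 * npp] - dt_min / 2)
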