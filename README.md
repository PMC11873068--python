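# mitocn

Single-cell quantification of mitochondrial DNA copy number (mCN) and its
physiological companions, for high-content imaging studies of cultured
cells (vascular smooth muscle lines, HeLa, and similar).

Mitochondrial DNA is packaged in nucleoids that carry small integer numbers
of genome copies, with single-copy nucleoids the most abundant.  In an
anti-dsDNA immunofluorescence image the integrated intensities of cytosolic
puncta are therefore *quantized*: a k-copy nucleoid measures `k·q + N(0, σ√k)`
for a quantal unit intensity `q`.  `mitocn` estimates `q` by fitting the
pooled punctum-intensity distribution of a staining batch with a
10-component Gaussian mixture whose means are constrained to `k·q`
(`k = 1..10`, first component the most abundant), and converts each cell's
summed punctum intensity `S` to an absolute copy number

    mCN = S / q̂

Everything around that estimate is included:

* **segmentation** — rolling-ball background subtraction, threshold-based
  nuclear labelling, and capped Voronoi expansion of nuclei into cell
  territories (distance to nuclear *edges*, 133 µm cap, exact against a
  brute-force oracle);
* **puncta** — local-maximum detection with deterministic tie-breaks and
  fixed-aperture photometry with a sigma-clipped annulus background;
* **quantal** — the constrained mixture fit (`QuantalIntensityModel` →
  `QuantalFit`) and mCN conversion;
* **gating** — DNA-content ploidy gates (2N/2S/4N/4S/8N) from integrated
  nuclear-stain intensity, and transfection calls from nuclear GFP via a
  triple-Gaussian fit thresholded at μ₁+3σ₁ (`GfpMixtureModel`);
* **ddpcr** — duplex droplet digital PCR: quadrant gating of the four
  droplet populations, Poisson correction λ = −ln(negative fraction), and
  absolute copies/cell against a multi-locus nuclear reference
  (`DropletAssay` → `ConcentrationEstimate`);
* **physiology** — TMRM membrane-potential index anchored on FCCP/oligomycin
  wells, MitoSOX ROS index as fold of a reference population, thresholded
  mitochondrial-mass area;
* **growth** — 3-parameter exponential fits of nuclear-count time series
  (`GrowthModel` → `GrowthFit`), doubling times ln 2/k, relative growth and
  curve rebasing for conditioned-media protocols;
* **seahorse** — Mito-Stress-Test respiration metrics from OCR traces,
  normalized per cell;
* **synthgen** — seeded generators for every data stream (multi-channel
  fields with full ground truth, droplet tables, growth counts, OCR traces);
* **pipeline** — plate-layout-aware orchestration with per-plate
  reference normalization, plus a `mitocn` command-line interface.

See `docs/methods.md` for the models, assumptions, and numerical choices.

## Worked example

Generate a synthetic field, segment it, and estimate per-cell mCN:

```python
import numpy as np
from mitocn import segmentation, puncta
from mitocn.quantal import QuantalIntensityModel, estimate_mcn
from mitocn.synthgen import SynthFieldConfig, make_field

cfg = SynthFieldConfig(field_size_px=(2048, 2048), pixel_size_um=0.62,
                       n_cells=22, copies_per_cell_mean=400.0,
                       quantal_intensity=100.0, seed=3)
image, truth = make_field(cfg)

px = image.pixel_size_um
dna = segmentation.subtract_background(image.channels["dna"], 75.0, px)
nuclei = segmentation.threshold_nuclei(dna, threshold=7.0, pixel_size_um=px)
rois = segmentation.voronoi_cell_rois(nuclei)          # 4 px dilation, 133 µm cap

ds = segmentation.subtract_background(image.channels["dsdna"], 75.0, px)
pt = puncta.detect_puncta(ds, rois.cytosol, peak_min=4.0,
                          photometry_image=image.channels["dsdna"])
sums = puncta.sum_puncta_per_cell(pt, cell_ids=nuclei.ids)

fit = QuantalIntensityModel(pt.loc[pt.cell_id > 0, "intensity"]).fit()
print(fit.summary())
mcn = estimate_mcn(sums, fit)
print(f"mean mCN: {mcn.mean():.1f}  (true: {truth.cells.true_copies.mean():.1f})")
```

Output:

```
Quantal nucleoid intensity fit
==================================
method:        histogram
n puncta:      4845
q (a.u.):      91.23
sigma (a.u.):  14.16
residual norm: 17.79
valid:         True
weights: w1=0.510, w2=0.259, w3=0.115, w4=0.061, w5=0.032, w6=0.013, w7=0.004, w8=0.003, w9=0.001, w10=0.001
mean mCN: 421.1  (true: 431.3)
```

The fitted unit `q̂ ≈ 91` is the measured single-copy intensity (the
generator's 100 a.u. times the finite photometric aperture), the weights
recover the generator's geometric copy-number mix with single-copy
nucleoids dominant, and the population mean mCN lands within a few percent
of the simulated truth — `q` cancels the photometric gain, so mCN is
invariant to global intensity rescaling.

The same chains are scriptable from the shell:

```bash
mitocn synth --n-cells 22 --seed 3 --out field/
mitocn mcn field/field.tiff --threshold 7
mitocn run-all --seed 1
```

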