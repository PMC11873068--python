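# Methods

`mitocn` implements the quantitative core of a single-cell mitochondrial DNA
copy-number (mCN) assay on cultured cells, together with the companion
measurements such a study runs alongside it: absolute quantification by
duplex droplet digital PCR, DNA-content ploidy gating, nuclear-GFP
transfection gating, TMRM/MitoSOX dye indices, growth-kinetics fits, and
Mito-Stress-Test respiration metrics.  Because no public raw dataset exists
for this assay class, every analysis stream has a seeded synthetic generator
that reproduces the statistical structure the estimators assume, with full
ground truth, and the package's headline numbers are parameter-recovery
results on those generators.

## Image-based quantal mCN estimation

**Model.**  mtDNA is packaged in nucleoids carrying small integer numbers of
genome copies, with single-copy nucleoids the most abundant species.  An
anti-dsDNA immunofluorescence image of the cytosol therefore shows puncta
whose integrated intensities are quantized: a k-copy nucleoid measures

    I = k·q + ε,   ε ~ N(0, σ²k),   k = 1..K (K = 10 by default)

where q is the quantal (single-copy) intensity in arbitrary units.  The
variance grows linearly in k (σ_k = σ√k) because copy contributions add
independently.  Pooling all puncta of one staining batch, the intensity
distribution is a K-component Gaussian mixture with means constrained to
integer multiples of q; the identifying assumption is that the first
component carries the largest weight.  Per-cell mCN is the cell's summed
punctum intensity divided by q̂ — real-valued, not rounded.  Any constant
photometric gain (aperture capture fraction, microscope gain) cancels in
this ratio, which is why the estimate is invariant to global intensity
rescaling.

**Fitting.**  The default fit minimizes weighted least squares between the
binned model (component mass integrated over Freedman–Diaconis bins,
weights 1/√count) and the observed histogram.  For fixed (q, σ) the optimal
non-negative component amplitudes are a non-negative least-squares solve;
(q, σ/q) are then optimized in log space by Nelder–Mead from 20 log-spaced
q starts between the 5th intensity percentile and the histogram mode.  Two
identifiability guards matter in practice and are enforced as soft bounds:
q ∈ [0.6, 1.7]×mode (excludes the q→q/2 alias, which fits the data equally
well with all odd-component weights zero) and σ/q ∈ [0.02, 0.35] (a larger
spread makes the quantal structure unresolvable and lets one broad
component soak up the histogram).  The histogram is extended with empty
bins up to K·q + 4σ√K so that the observed absence of counts pins down the
amplitudes of components beyond the data range.  A fit is flagged invalid —
and mCN conversion refuses it — when the first component is not the most
abundant.  A raw-sample EM fit with the same mean constraint
(`method="em"`) exists as a cross-check; closed-form updates are
q ← Σrₖx/Σrₖk and σ² ← mean of rₖ(x−kq)²/k.

**Segmentation.**  Nuclei are thresholded (one manual intensity threshold
per staining batch; an Otsu suggestion is available but never silently
applied), 8-connected, size-filtered, after rolling-ball background
subtraction with radius 1.5× the largest expected nuclear diameter (~50 µm
for these cells, so 75 µm).  For radii above 16 px the ball rolls on a
block-median-downsampled copy and the background is upsampled; block median
(not mean) keeps puncta out of the background estimate, and (not minimum)
avoids biasing the background to the noise floor's lower envelope.  Cell
territories are capped Voronoi regions: each pixel joins the nucleus whose
*mask* (not centroid) is nearest in Euclidean distance, within a 133 µm
expansion cap; equidistant pixels go to the lower label id — the
implementation computes per-label distance transforms over cap-padded
windows and is tested for exact equality against an O(pixels×nuclei)
brute-force scan.  The cytosolic compartment excludes a 4-px dilation of
every nucleus.  Pixel coordinates are 0-based row-major at pixel centres;
areas use pixel_size² (default 1.24 µm/px).

**Punctum detection and photometry.**  Puncta are local maxima (Chebyshev
separation 2 px, deterministic lexicographic plateau tie-break) above a
per-batch peak threshold inside cytosolic ROIs, found on the
background-flattened image.  Integrated intensity uses fixed-aperture
photometry *on the raw image*: the sum over a (2r+1)² patch (r = 3 default)
minus patch-area × an iteratively 3σ-clipped mean of a surrounding annulus
ring.  Fixed patches keep the intensity scale unit-additive (a 2-copy
nucleoid measures twice a 1-copy one), which watershed-support photometry
would not guarantee.  The annulus term is essential at realistic nucleoid
densities (hundreds per cell): the diffuse floor of unresolved neighbours
otherwise inflates per-cell sums and q̂ by different factors and biases
absolute mCN by >10%.  Measuring on the raw image rather than the
background-subtracted one avoids two subtle artifacts of global
subtraction: the clipped-at-zero noise floor (whose mean exceeds its
median) and local dips the coarse background estimate can carve around
bright spots.  At the default study density the measured single-punctum
response is ≥0.99× truth; unresolvably close pairs merge into a
double-intensity punctum, which the quantal model absorbs as a k=2 event —
total flux, and hence mCN, is approximately conserved.

**Normalization.**  mCN and cell density are normalized to the mean of the
reference (wild-type-construct) wells per plate and media condition, which
removes plate-wise staining and seeding variance; the operation is plain
division and is idempotent once the reference is 1.

## Ploidy and transfection gating

DNA-content gating uses integrated nuclear-stain intensity versus nuclear
area.  Gates are axis-aligned boxes, first-class configuration (the assay
is gated manually per batch); for reproducible synthetic runs
`auto_gates_from_g1_peak` locates the diploid-G1 modal intensity m
(histogram mode, refined by a finer second pass) and sets
2N ≡ [0.75m, 1.25m), 4N ≡ [1.5m, 2.5m), 8N ≡ [3m, 5m), with the S-phase
gates filling the gaps.  The "4" and "8" classes deliberately conflate
diploid G2/M with tetraploid G0/G1 (and tetraploid G2/M with octoploid
G0/G1): DNA content alone cannot separate them.

Transfection is called from nuclear GFP reporter intensity.  A 3-component
Gaussian mixture (EM, k-means++ init, 10 restarts, tol 1e-8, seeded;
components sorted by mean) is fitted to the pooled distribution, and every
cell above μ₁ + 3σ₁ of the dim background component is transfected.  The
rule is affine-consistent (shifting all intensities shifts the threshold
identically) and degenerates gracefully: with only a background component
it calls the ~0.135% normal tail.

## Duplex ddPCR absolute quantification

A duplex EvaGreen reaction partitions the sample into ~20,000 droplets,
producing four intensity populations (empty, mitochondrial-target-only,
nuclear-reference-only, double-positive).  Droplets are quadrant-gated by
two channel thresholds — manual, or automatic via a deterministic 1-D
two-means split per channel with a histogram-valley bimodality check
(a unimodal channel is gated above its cloud and flagged; a bimodal channel
whose clusters separate by fewer than 3 pooled SDs is flagged as poorly
separated).  Each target's occupancy follows from the Poisson void
probability λ = −ln(fraction negative), with binomial CIs propagated
through the log; zero negative droplets yields a lower bound with a
warning, never a silent number.  Absolute copies per cell is
λ_mito/(λ_ref/loci_per_cell) with loci_per_cell = 6 by default (the nuclear
reference primers amplify three loci per haploid genome; diploid cells).
This factor scales the result 2× and is therefore a prominent parameter.
Droplet volumes cancel in the ratio.

## Dye physiology indices

TMRM index: (I − mean_FCCP)/(mean_oligo − mean_FCCP) per cell, using the
FCCP-treated (depolarized floor) and oligomycin-treated (hyperpolarized
ceiling) control wells of the same plate as anchors; exactly
affine-invariant, may legitimately leave [0, 1]; requires
oligo_mean > fccp_mean.  MitoSOX index: value / reference-population mean
(wild-type control diploid cells of the plate), measured in nuclear ROIs —
at the micromolar dye concentrations used in this assay class the signal
localizes to the nucleus.  Mitochondrial mass: supra-threshold stained area
per cell in µm², on a 32-bit sub-threshold NaN mask so ignored pixels never
count toward any statistic (an all-masked ROI reports missing, not zero).

## Growth kinetics

Per-frame nuclear counts are fitted with count(t) = c + a·e^{kt}; doubling
time is ln 2/k.  The printed form of the model names two parameters; the
third is implemented as an additive offset, the most common 3-parameter
exponential, absorbing a non-dividing or mis-segmented baseline (a
2-parameter pure exponential is available and demonstrably biased when a
true offset exists).  Counts are Poisson, so the default fit is weighted
least squares with σᵢ = √countᵢ, and the parameters are constrained a > 0,
c ≥ 0: a baseline population cannot be negative, and the unconstrained fit
occasionally trades a spurious negative offset against a badly biased rate
(observed ~3σ doubling-time excursions).  The rate initializes from a
log-linear regression of the series tail.  k ≤ 0 flags the doubling time
undefined rather than reporting a negative time.  Identifiability limit:
when the window spans less than ~2-fold growth (k ≈ 0.01/h over 72 h) the
offset is weakly identified and the pure model is the appropriate
estimator; the recovery suite reflects this.  End-point comparisons use
relative growth (final/first count); conditioned-media curves are rebased
at the media-change time (the rebased exponential keeps its rate).

## Mito-Stress-Test metrics

From a four-phase OCR trace (basal, +oligomycin, +FCCP,
+rotenone/antimycin-A; ≥3 measurements per phase at ~3-min increments),
with vendor-convention point rules: non-mitochondrial = mean of the final
phase; basal = last basal point − non-mito; ATP-linked = last basal − min
post-oligo; proton leak = min post-oligo − non-mito; maximal = max
post-FCCP − non-mito.  basal = ATP-linked + proton-leak holds exactly by
construction.  A sub-basal FCCP response (seen in some smooth-muscle lines)
is flagged, not fatal.  Per-cell normalization divides every metric by the
imaged nuclear count of the well.

## Synthetic data: what it emulates, what it does not

One master seed drives every stream; identical (config, seed) pairs are
bit-identical.  Fields render nuclei as anti-aliased disks whose integrated
stain intensity is proportional to genome copies (2/3/4/6/8 for
2N/2S/4N/4S/8N, 8% CV — chosen so ploidy gates are separable but
non-trivial), puncta as Gaussian spots (PSF σ = 1.5 px) of intensity
k·q + N(0, σ√k) placed in the cytosol and never inside nuclei, nuclear GFP
from a 3-component mixture with a 25% transfected fraction, and a nuclear
dye channel with per-ploidy means.  Per-punctum copy numbers are geometric
over 1..10 with mode 1 (mean ≈ 1.8 copies); per-cell expected copies get a
15% between-cell dispersion; ground-truth per-punctum copies sum exactly to
each cell's true copy count.  Droplets draw independent Poisson occupancies
per target with well-separated Normal intensity clusters; growth counts are
offset + n0·e^{kt} with Poisson noise; OCR traces are step functions plus
Gaussian noise.  Additive Gaussian read noise (σ = 1 a.u. on a ~20 a.u.
background) is the default noise model, chosen for analytic tractability.

Not emulated: optical aberrations and shading, autofluorescence texture,
cell shape (territories are Voronoi by construction, so the segmentation's
geometric assumption is exactly true in synthetic data), ddPCR "rain"
(partial-amplitude droplets), transfection biology, or any diffusible-factor
kinetics — effect sizes are injected as generator parameters.  Passing
recovery tests therefore demonstrates correctness of the estimators under
the model's assumptions, not robustness to real-microscope artifacts.

## Reference protocol sizes and numerical choices

The reproduction protocols (`mitocn.protocols`, driven by
`scripts/acceptance.py`) use: two groups of 10 fields × 22 cells (220
cells/group) at 0.62 µm/px (20× sampling, where several hundred nucleoids
per cell remain resolvable) for the 27% mCN-reduction recovery; 10,000
cells for transfection gating; 20,000 droplets per condition at occupancies
1.9467/0.020 (and 1.4016 for the reduced condition) for ddPCR; 72 h and
46 h curves at 20-min sampling for the 27.3 h and 20.5 h doubling times; a
600-cell mixed-ploidy field (60/30/10% of 2N/4N/8N) plus a 550-cell
reference field for the MitoSOX ploidy index; 500 cells per condition for
the TMRM index.  With 20,000 droplets and λ_ref = 0.020, the binomial SE of
the reference concentration is ~5% of its value — the dominant uncertainty
of the absolute ddPCR number.

Other numerical conventions: NNLS for mixture amplitudes; Nelder–Mead on
log-parameters (scale equivariance to float precision); `curve_fit`
trust-region with analytic-free Jacobian for growth; iterative 3σ-clipped
annulus means for photometry floors; all label maps int32; degenerate
inputs (constant intensities, empty fields, all-masked ROIs, zero-count
anchors) either short-circuit to the exact answer or raise with a message
naming the violated precondition.
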