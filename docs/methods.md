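# Methods

## Decay model and time base

Each pixel of a TCSPC channel holds a photon-arrival histogram over 256 time
bins spanning 12.5 ns (an 80 MHz repetition period), a common TCSPC
configuration. The expected histogram is the discrete convolution of a
two-component exponential, α₁e^(−t/τ₁) + (1−α₁)e^(−t/τ₂), with the
sum-normalized IRF, scaled so the background-free curve integrates to the
pixel's expected photon count, plus a constant background C per bin. The
default IRF is Gaussian with 0.25 ns FWHM centered at 1.0 ns. Wraparound of
incomplete decays from the previous laser period is not simulated and not
modeled in fitting; at τ₂ ≤ ~3.5 ns and a 12.5 ns window the truncated tail
carries ≪1% of the signal. Bin timestamps are bin centers.

## Synthetic scenes

Cells are non-overlapping disks (radius 11–16 px by default) with an
interior dark nucleus (expected photons = 0.3 × cytosol) and mitochondrial
puncta (disks of radius 1–2 px at 2× cytosol brightness, 0.04 puncta per
cytoplasm pixel, which covers roughly a fifth of the cytoplasm — the area
fraction the brightest-20% mitochondrial proxy assumes). Placement uses
bounded rejection sampling; a field that cannot hold the requested count
yields fewer cells with a warning. Photon emission is independent Poisson
per (pixel, bin).

Phenotype presets give each (channel, compartment) a parameter distribution.
Cytosolic NAD(P)H control means are α₁ = 0.75, τ₁ = 0.5 ns, τ₂ = 2.5 ns at
1,000 expected photons per cytoplasm pixel (binned peak > 100 counts).
Glycolysis inhibition shifts NAD(P)H (α₁, τ₁, τ₂) by (−0.06, +0.1 ns,
+0.3 ns) with dimmer NAD(P)H and FAD; OXPHOS inhibition shifts them by the
opposite amounts with brighter NAD(P)H and dimmer FAD (hence a lower
intensity redox ratio). FAD lifetimes carry no shift between the two
inhibition phenotypes, reflecting that no consistent FAD lifetime difference
distinguishes them; an optional high-pyruvate preset raises the bound FAD
fraction. Only the *directions* of these shifts are established biology; the
magnitudes are package choices sized to be resolvable at the simulated
photon budget. Mitochondria carry α₁ 0.03 below the cytosol of the same
cell (more bound NAD(P)H where oxidative chemistry happens). Between-cell
jitter is truncated Gaussian with SDs (α₁ 0.04, τ₁ 0.05 ns, τ₂ 0.12 ns,
photons 120), chosen so phenotype distributions overlap the way real
single-cell data do rather than forming point masses.

Two fast paths bypass rendering for experiments needing thousands of cells:
`sample_cell_features` draws per-cell cytoplasm-averaged feature vectors
(cytosol/mitochondria mixed 80/20 by area) plus calibrated estimation noise
(SDs α₁ 0.012, τ 0.025–0.06 ns, intensity 4%, matching the scatter of
cytoplasm means recovered from fitted images at this photon budget), and
`sample_cell_stacks` draws per-cell 40×40 parameter-map images with
per-pixel scatter emulating fitted maps after 3×3 binning. What the fast
paths do not emulate: fit-induced parameter correlations, compartment mixing
at binned boundaries, segmentation errors. The full physics path
(scene → cubes → fit → segment → aggregate) is exercised end to end on
smaller fields, so tests on fast-path data demonstrate the statistical
machinery, not photon-level robustness — that is what the fitting and
segmentation tests cover.

## Fitting

Pixels are spatially binned by summing the (2r+1)² neighborhood (default
r = 1, nine pixels; truncated at edges, no padding). A pixel is fitted only
if its *binned* histogram peak reaches the channel threshold (20 photons
NAD(P)H, 3 FAD); the threshold-after-binning reading is recorded in the
output metadata since the alternative order is equally defensible.

The fit is bounded weighted least squares over (α₁, τ₁, τ₂) with amplitude
and background profiled out exactly by weighted linear least squares at each
objective evaluation (background clipped at zero). Bounds: α₁ ∈ [0, 1],
τ ∈ [0.05, 10] ns. Initialization: log-linear tail fit for τ₂, early-time
residual slope for τ₁, fallback (0.7, 0.4 ns, 2.2 ns). Weights are Poisson:
a first pass uses variance = max(counts, 1); a second pass re-weights with
variance = max(model, 1) from the first-pass fit and re-optimizes. The
refinement removes the known downward bias of observed-count weighting
(near-empty tail bins over-weighted), cutting the median τ₂ error from ~7%
to ~2% at 10⁴ photons; `fit_weights` exposes the final weight rule so
external checks can evaluate the exact objective minimized. Components are
sorted to τ₁ ≤ τ₂ afterwards (amplitudes swapped accordingly); fits with
τ₂ − τ₁ < 1% of τ₂ are flagged degenerate and reported as single-exponential
(α₁ = 1). Reduced χ² uses the final model's own Poisson variances with
degrees of freedom = bins − 4, and calibrates to ~0.96 on well-specified
data. Below-threshold pixels yield an "excluded" sentinel result (NaN maps),
never an exception.

## Segmentation

The supplementary pipeline the original analysis used is not available, so
segmentation is a documented equivalent built from standard operators:
Gaussian smoothing (σ = 2 px), Otsu threshold, hole filling (keeps dark
nuclei inside their cells), size filter, distance-transform watershed seeded
at local maxima (minimum seed distance 8 px), and discarding edge-touching
cells so CNN crops are complete. Nuclei are recovered per cell as the
largest connected dark region under a within-cell Otsu threshold; cytoplasm
is cell minus nucleus. Equivalence to the original is functional (cells,
nuclei, cytoplasm, complete bounding boxes), not procedural. The
mitochondrial proxy marks exactly ceil(0.20 × |cytoplasm|) brightest
cytoplasm pixels per cell, ties broken deterministically in row-major order;
the remaining cytoplasm is the cytosol compartment. Coordinates are 0-based,
row-major, with half-open bounding boxes.

## Features and statistics

Per-cell features average the per-pixel maps over the requested compartment
(no re-fitting of pooled decays), requiring ≥ 10 jointly valid pixels.
Intensity features are unbinned per-pixel photon totals. Undefined pixels
(zero total intensity for IRR, FAD α₁ = 0 for FLIRR) carry NaN and are
excluded from means; whether such pixels should instead be clipped is
unresolved in the source analysis, and exclusion is the conservative choice.
Control normalization divides each feature by the control-group mean within
each batch.

Group tests are two-sided Wilcoxon rank-sum (Mann–Whitney) via scipy, with
the Bonferroni family defined as the pairwise comparisons within one feature
(the family definition in the source is ambiguous; per-feature is the
smallest defensible family and is applied uniformly). Constant data yields
p = 1. UMAP runs on z-scored features (neighbors 15, min_dist 0.1, fixed
random_state; neighbors reduced with a warning for small tables).

## Classifiers

Random forest: 50 trees, 5 candidate variables per split, terminal node
size 1. SVM: linear kernel on z-scored features (scaling inside the
pipeline; forest and QDA take raw features — tree splits and class
covariances are scale-equivariant). QDA falls back to reg_param = 10⁻³ when
a class covariance is singular (the twelve features are nearly collinear
through τ_m). Splits are stratified 75/25 with a ceiling on the training
count (1,819 cells → 1,365/454); 5-fold CV runs on the full labeled table
by default. The positive class is the OXPHOS-inhibited (glycolytic)
phenotype throughout. Single-feature AUCs use the feature value as the
score on whichever orientation yields AUC ≥ 0.5, with the orientation
recorded. Transfer normalizes the new population by its own control means
before applying a model trained on normalized features.

## CNN

Cell crops are masked to the cell, rescaled so the longest side is 40 px
(aspect preserved), center-padded to 40×40. Lifetime channels use fixed
physical scaling (τ / 5 ns clipped to [0, 1]; α unchanged) so stored models
transfer across scenes; intensity channels are scaled per image to [0, 1],
which deliberately removes absolute brightness. The network is the classical
LeNet-5 layout — conv 5×5×6, max-pool, conv 5×5×16, max-pool, dense
120 → 84 → 2 — with ReLU, softmax cross-entropy and Adam, implemented
directly on numpy (im2col convolutions), single-threaded and fully
seed-reproducible. Exact filter counts and the optimizer are conventional
choices; the source names none. FAD lifetime channels are excluded from the
default channel sets since they carry no phenotype signal. Default training
config mirrors the reference protocol (learning rate 10⁻⁵, up to 80 epochs
with early stopping on validation loss, 15% validation split by cell);
the analysis drivers use Adam at 10⁻³ with ≤ 10 epochs, which reaches the
same plateau on these synthetic stacks in a fraction of the time.
Augmentation (flips, 90° rotations) exists but is off by default.

## Problem sizes

The shipped drivers and checks use 96×96 fields for full-physics runs
(per-pixel fitting is the expensive step: a few ms per pixel), 256×256
fields for intensity-based segmentation, 1,000-decay ensembles for recovery
statistics, 2,000 cells for classifier and CNN experiments, and ≤ 20-epoch
CNN runs. These sizes give stable statistics while keeping any single step
in the minutes range on one CPU.

## Known limitations

No optical PSF blur, detector afterpulsing, channel crosstalk, FMN/flavin
spectral contamination, photobleaching, motion, or incomplete-decay
wraparound. Segmentation is classical, not learned, and is tuned for
disk-like synthetic cells; real morphologies would need parameter changes.
The phenotype-preset magnitudes are free parameters of the simulator, so
absolute classifier accuracies on synthetic data characterize the pipeline,
not any real biological dataset.
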