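# flimpheno

Label-free metabolic phenotyping of single cells from two-channel
NAD(P)H / FAD fluorescence-lifetime (TCSPC) images.

Cellular metabolism — whether a cell leans on glycolysis or on oxidative
phosphorylation (OXPHOS) — can be read out without labels from the
autofluorescence of two metabolic coenzymes: NAD(P)H and FAD. Both exist
free and protein-bound, and the two states have distinct fluorescence
lifetimes. Time-correlated single-photon counting (TCSPC) microscopy records
a photon-arrival histogram per pixel; fitting it with a two-component decay
through the instrument response function (IRF),

```
I(t) = [ α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂) ] ⊛ IRF + C ,   α₁ + α₂ = 1 ,
```

resolves the bound/free fractions (α₁, α₂) and lifetimes (τ₁ ≤ τ₂). From
these, per cell, the package computes twelve features: the intensity redox
ratio IRR = FAD/(FAD + NAD(P)H), the lifetime redox ratio
FLIRR = NAD(P)H α₂ / FAD α₁, and per channel the mean lifetime
τ_m = α₁τ₁ + α₂τ₂, τ₁, τ₂, α₁ and intensity. Glycolytic and oxidative cells
shift these features in opposite directions (glycolysis inhibition lowers
the free NAD(P)H fraction α₁ and lengthens τ₁, τ₂, τ_m; OXPHOS inhibition
does the reverse), so feature-based classifiers (random forest, linear SVM,
QDA) and a LeNet CNN on per-cell lifetime-component images can predict the
metabolic phenotype of each cell.

The package is organized as an analysis over synthetic data with known
ground truth:

- `flimpheno.synth` — compartmentalized cell scenes (dark nuclei, bright
  mitochondrial puncta), phenotype presets, IRF-convolved decays, Poisson
  photon noise; plus phenotype-level fast paths for classifier-scale
  experiments.
- `flimpheno.fitting` — 3×3 spatial binning, peak-count thresholds
  (20 photons NAD(P)H / 3 FAD), bounded weighted least squares through the
  IRF, reduced χ².
- `flimpheno.segmentation` — watershed cell segmentation from NAD(P)H
  intensity, nucleus/cytoplasm split, brightest-20% mitochondrial proxy mask.
- `flimpheno.features` — derived maps and the twelve per-cell features;
  control normalization.
- `flimpheno.stats` — pairwise Wilcoxon rank-sum tests with Bonferroni
  correction; seeded UMAP.
- `flimpheno.classify` — RFT (50 trees) / linear SVM / QDA, ROC/AUC,
  5-fold CV, feature ranking, control-normalized transfer.
- `flimpheno.cnn` — 40×40 per-cell image stacks and a numpy LeNet trained
  with cross-entropy.
- `flimpheno.pipeline` / `flimpheno.cli` — one-config orchestration and the
  `flimpheno` command-line interface.

## Worked example

The numbered drivers under `analysis/` run the study end to end and write
their tables under `results/`:

```
$ python analysis/01_simulate_scene.py
placed 6 cells (3 glycolysis-inhibited, 3 OXPHOS-inhibited)
mean photons per cell pixel: NADH 1071, FAD 426

$ python analysis/02_fit_decays.py
nadh: 27.1% of pixels fitted, mean reduced chi2 0.977
  alpha1 recovery bias vs truth: +0.0006
fad: 27.2% of pixels fitted, mean reduced chi2 0.962

$ python analysis/03_segment_features.py
segmented 6 cells; 6/6 matched at IoU >= 0.7
                      nadh_a1  nadh_tm  redox_ratio
glycolysis_inhibited    0.689    1.306        0.377
oxphos_inhibited        0.793    0.780        0.242
```

Glycolysis-inhibited cells show the lower free NAD(P)H fraction (α₁ 0.689
vs 0.793) and the longer mean lifetime (τ_m 1.31 ns vs 0.78 ns) — the
directions the phenotype presets encode. Only pixels whose binned decay
peak clears the photon threshold are fitted, hence the ~27% valid fraction
on a sparsely populated field. Continuing:

```
$ python analysis/05_classifiers.py
2000 cells -> 1500 train / 500 test
RFT: accuracy 1.000, AUC 1.000, precision 1.000, recall 1.000, 5-fold CV 1.000
...
label-permutation 5-fold CV accuracy: 0.502 (chance control)

$ python analysis/06_transfer.py
raw model on shifted population: accuracy 0.510
control-normalized model:        accuracy 1.000

$ python analysis/07_cnn.py
nadh_all: test accuracy 1.000, AUC 1.000, ... (7 epochs)
nadh_intensity: test accuracy 0.460, AUC 0.483, ... (5 epochs)
```

At the presets' separation the feature classifiers saturate; the permutation
control confirms the pipeline carries no label leakage. Transfer to a
baseline-shifted "cell type B" collapses without control normalization and
is restored by it, and the CNN ordering (all NAD(P)H lifetime components ≫
per-image-normalized intensity alone) shows the phenotype signal lives in
the lifetime maps, not in morphology.

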