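# specmap

Cross-sample analysis of spatially resolved Fourier-transform infrared
(FTIR) microspectroscopy data: quality control and preprocessing of
per-pixel absorbance spectra, eigen-spectra PCA, graph-based clustering,
band quantification with secondary-structure estimation, and spatial
reconstruction of results in acquisition layout.

## Who it is for

µFTIR imaging (scanning-mode or focal-plane-array) yields thousands of
absorbance spectra A(ν̃) per tissue section, each spectrum a chemical
fingerprint over wavenumbers ν̃ ≈ 950–3700 cm⁻¹.  Histological profiling
with this data — distinguishing protein-, lipid- or nucleic-acid-rich
regions, comparing disease cases against controls — needs a reproducible,
scriptable pipeline that can treat many samples jointly.  specmap is a
batch-oriented Python library (plus a thin `specmap` CLI) for exactly
that: no interactive steps, every stage seeded and logged, every artifact
a delimited-text file that reproduces bitwise on rerun.

## What it computes

- **QC.** A pixel is *empty* if its mean absorbance over the amide I
  window (1600–1700 cm⁻¹ by default) falls below a threshold; it is a
  *scatter* outlier if the least-squares baseline slope over the silent
  region (1800–2600 cm⁻¹) exceeds a threshold or the spectrum is mostly
  negative.  Excluded positions are saved for later repopulation.
- **Preprocessing.** Closed-interval excision of the atmospheric CO₂ band
  (2300–2400 cm⁻¹); vector normalization x ↦ x/‖x‖₂; Savitzky–Golay
  second derivative d²A/dν̃² (window 9, order 3), which annihilates
  constant and linear baseline drift.
- **PCA.** Mean-centered decomposition A = μ + S·Eᵀ with unit-norm,
  mutually orthogonal eigen-spectra E, scores S and explained-variance
  ratios; deterministic sign convention.
- **Clustering.** k-nearest-neighbor graph (Euclidean, on the PCA scores,
  union-symmetrized, unweighted) partitioned by the Leiden algorithm at a
  tunable resolution (default 0.5, tuned to tissue-region granularity);
  optional seeded UMAP embedding for visualization only.
- **Quantification.** Trapezoidal band areas ∫ A dν̃ over a window,
  optionally above the linear chord joining the window endpoints;
  peak-shift-aware window recentering; per-cluster mean spectra;
  secondary-structure fractions from amide I sub-band areas (α-helix
  1648–1660, β-sheet 1620–1640 ∪ 1670–1695, turns 1660–1670, other
  1640–1648 cm⁻¹; clamped at zero and normalized to sum to one — no curve
  fitting or spectral decomposition).
- **Spatial maps.** Per-pixel scalars or cluster labels repopulated to
  their original grid positions (excluded pixels as a missing marker) and
  rasterized as ny × nx images, written as PNG plus an exact text sidecar.
- **Synthetic scenes.** A ground-truthed generator (three-region tissue
  phantom with Gaussian bands, baselines, CO₂, noise, holes and scatter
  artifacts) so the entire pipeline is testable without any downloads.

## Worked example

Scripts under `examples/` run one capability each.  The core loop
(`examples/03_pca_clustering.py`) on the default synthetic scene prints:

```
explained variance ratio (top 5): [0.6789 0.1921 0.0068 0.0064 0.0062]
cumulative variance after 2 components: 0.8709
clusters found: 3 (ground truth: 3 regions)
adjusted Rand index vs ground truth: 1.000
cluster sizes (largest first): [336, 335, 313]
```

Two principal components carry 87% of the variance — they separate the
three tissue classes — and Leiden clustering on the scores recovers the
generative regions exactly (ARI 1.0).  The end-to-end run
(`examples/06_full_pipeline.py`, also `specmap run --config run.yaml`)
analyzes a 2-case/2-control synthetic study and prints:

```
mean beta-sheet fraction by group:
case       0.271
control    0.212
```

i.e. the β-sheet-shifted amide I signature built into the case samples is
recovered as a higher estimated β-sheet fraction.

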