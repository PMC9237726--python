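# Methods

This note documents the models, parameter choices and numerical decisions
behind specmap, and what the synthetic-scene tests do and do not
demonstrate about real data.

## Data model

A `SpectralMap` is a dense `n_pixels x n_wavenumbers` absorbance matrix
with a strictly ascending wavenumber axis (cm^-1).  Instruments commonly
export descending axes; these are reversed once at the I/O boundary so
that integration and differentiation never need to reason about axis
direction.  Joint analysis of several samples requires identical axes to
within 1e-6 cm^-1 absolute; the package never resamples silently, because
interpolation would change band areas and derivative magnitudes.
Acquisition geometry is carried separately as `(nx, ny)` plus a declared
raster order (default: row-major, origin top-left, x fastest; a
column-major order is available for instruments that scan the other way).

## Quality control

The two per-pixel detectors operationalize "no sample" and "scattering
artifact" with cheap, transparent statistics:

- **Empty**: mean absorbance in `empty_window` (default 1600-1700 cm^-1,
  amide I) below `empty_threshold` (default 0.1 absorbance).  All
  biological material absorbs at amide I, so a low windowed mean is a
  robust no-sample indicator.  The threshold is an absorbance, not a
  quantile, so it transfers across samples of similar thickness.
- **Scatter**: absolute least-squares slope of the spectrum over
  `scatter_silent_window` (default 1800-2600 cm^-1, where tissue is
  nearly transparent) above `scatter_slope_threshold` (default 1e-3
  absorbance/cm^-1), OR fraction of negative absorbance channels above
  `scatter_negative_fraction_threshold` (default 0.6).  The negative
  fraction default is deliberately above 0.5: a noise-only (hole)
  spectrum fluctuates around zero and sits near 50% negative channels,
  and holes are the empty detector's responsibility; 0.6 flags spectra
  that are systematically negative (e.g. failed background correction)
  without double-flagging holes.

Full extended-multiplicative/resonant-Mie scattering correction is out of
scope by design: pixels with scattering evidence are excluded, not
corrected.  Detectors never modify data; they return masks over the
original pixel order with per-pixel reason codes, and masks compose by
logical AND (first mask's reason wins on pixels both exclude —
an arbitrary but deterministic tie-break).

## Spectral preprocessing

Order is fixed: QC -> CO2 excision -> vector normalization -> second
derivative.  Normalization runs only on retained spectra (a zero-norm
spectrum is an error, not a silent NaN); CO2 excision precedes the
derivative and clustering so atmospheric variation cannot enter either.

- **CO2 excision** removes the closed interval 2300-2400 cm^-1 by
  default (atmospheric asymmetric stretch, centered near 2349 cm^-1).
- **Vector normalization** scales rows to unit Euclidean norm — the
  standard meaning of the term in IR spectroscopy — removing
  pathlength/concentration scaling.
- **Second derivative** uses a Savitzky-Golay filter (default window 9
  points, polynomial order 3, derivative scaled by spacing^-2, so units
  are absorbance*cm^2).  SG filters of order >= 2 are exact on
  quadratics, hence the filter annihilates affine baselines exactly (to
  rounding), which is the point of the transform.  Edges are filled by
  evaluating the local polynomial fit at the edge points, so the axis is
  never truncated.  Because CO2 excision leaves a gap in an otherwise
  uniform axis, the filter is applied independently to each maximal
  contiguous run of uniform spacing (uniform within 1e-6 relative); each
  run must be at least one filter window long.  A genuinely non-uniform
  (e.g. jittered) axis is rejected with a spacing error.

## PCA

Spectra are mean-centered (no variance scaling — wavenumber channels
share units, and scaling would inflate noise channels) and decomposed by
a full SVD.  Eigen-spectra are unit-norm rows; the sign convention —
largest-magnitude entry of each eigen-spectrum positive — makes output
reproducible across eigensolvers.  Tests verify the implementation
against an independent explicit-covariance `eigh` oracle.

## Clustering

Clustering operates on PCA scores (default 15 components), not raw
spectra: the graph is a k-nearest-neighbor graph (default k = 15,
Euclidean) symmetrized by the union of directed edges and left
unweighted — the simplest fully deterministic construction.  Leiden
community detection (RB-configuration modularity) partitions it at a
given resolution with a given seed; labels are relabeled descending by
cluster size with first-occurrence tie-break, so output is stable across
runs and solvers.

**Default resolution = 0.5.**  The RB-configuration null model has a
resolution limit: at gamma = 1.0 on a graph with m edges, communities
much larger than ~sqrt(2m) nodes are split even when they are perfectly
separated in score space (the intra-community cut is cheaper than the
degree-product penalty).  For typical focal-plane-array tiles (~10^3
pixels, regions of several hundred pixels) that granularity
over-partitions spatially coherent tissue classes, so the package
defaults to a coarser resolution appropriate for tissue-region discovery;
raising it probes finer substructure.  This was verified empirically on
the synthetic scene: gamma = 1.0 reproducibly cuts ~330-pixel regions
into 2-3 slices, while gamma in [0.05, 0.5] recovers the generative
regions exactly.

The optional 2-D embedding (seeded UMAP on the scores) is decorative by
contract: it never feeds clustering, and tests assert nothing about its
coordinates beyond determinism.

## Quantification

Band areas use the trapezoid rule on the native axis grid over the closed
window; `baseline="linear_endpoints"` first subtracts the chord joining
the two window-endpoint absorbances (a local linear baseline).  Window
recentering (`adjust_window`) finds the argmax of the map-mean spectrum
within `nominal_center +/- search_radius`; using the map mean rather than
per-pixel argmax keeps the estimand identical across pixels.  Ties break
toward the nominal center, then toward the lower wavenumber; windows that
would overrun the axis are clipped with a provenance entry.

Secondary-structure fractions are computed from amide I sub-band areas
without any curve fitting or band deconvolution: the spectrum is
baseline-corrected once over the full amide window (default 1600-1700
cm^-1, endpoint chord), each class's literature wavenumber ranges
(alpha-helix 1648-1660; beta-sheet 1620-1640 and 1670-1695; turns
1660-1670; other 1640-1648 cm^-1) are integrated, negative areas are
clamped to zero, and the class areas are normalized to fractions summing
to one.  The assignment table is fully configurable.  These fractions are
a transparent, reproducible summary of amide I shape — invariant to
overall spectrum scaling — not a calibrated structural assay; band-range
assignments vary across the literature, adjacent ranges share overlapping
band tails, and published regression-based estimators are not reproduced
here.  Pixels with zero total clamped area get missing-valued fractions
and are flagged in the provenance log.

## Spatial reconstruction

`repopulate` and `to_grid` are pure index bookkeeping: retained values
are copied bitwise into their original positions, excluded positions hold
a missing marker (NaN for scalars, -1 for labels), and the flat vector is
reshaped by the declared raster order.  PNG renderings reserve a color
for missing pixels outside the scalar colormap / categorical palette; the
delimited-text sidecar (missing as "NA") is the machine-checkable record.

## Synthetic scenes

The generator emulates what matters to the pipeline's contracts: three
spatially contiguous tissue classes (protein-rich, lipid-rich with CH2
stretches and an ester carbonyl, nucleic-acid-rich with phosphate bands —
every class carries amide I/II, as all tissue contains protein), Gaussian
absorption bands, mild per-pixel affine baselines (offset 0.01-0.06
absorbance, slope within +/-2e-5 absorbance/cm^-1), a variable
atmospheric CO2 band (amplitude 0-0.15), i.i.d. Gaussian channel noise
(sd 0.005 absorbance, typical of a well-averaged FPA measurement), ~2%
noise-only hole pixels and ~2% scatter pixels with a steep rising
baseline (1.5e-3 to 3e-3 absorbance/cm^-1, anchored at the axis start).
The default axis is 950-3100 cm^-1 at 2 cm^-1 spacing — fingerprint plus
CH-stretch regions at a tractable size.  Rendering is seeded and bitwise
reproducible.

What it does **not** emulate: Mie/resonant-Mie lineshape distortion
(scatter is a baseline ramp, not a physical scattering model), instrument
line-shape and apodization effects, water-vapor rotational structure,
spatially correlated noise, focus drift, or partial-volume mixing at
region borders.  Passing the recovery tests therefore demonstrates that
the pipeline's bookkeeping, transforms and clustering behave as specified
under realistic signal-to-noise — not that the QC thresholds or structure
assignments are validated against measured tissue.

The case/control sample-set generator gives case samples a
beta-sheet-shifted protein signature (amide I moved toward 1648 cm^-1
plus a 1628 cm^-1 component), a simplified stand-in for
protein-misfolding pathology used to exercise multi-sample joint
analysis.

## Determinism and numerics

Every stochastic component (scene generation, Leiden, UMAP) takes an
explicit seed; the pipeline writes all artifacts as delimited text with
shortest-round-trip float formatting, and re-running an identical
configuration reproduces them byte for byte.  Axis comparisons use 1e-6
cm^-1 absolute tolerance; unit-norm checks 1e-10; PCA oracle agreement
1e-8.  Degenerate inputs (zero-norm spectra, empty windows, mismatched
grids) raise typed errors rather than propagating NaNs.

## Problem sizes

The test suite and acceptance script run on 32 x 32 scenes (1024 pixels,
1076 wavenumbers) for recovery checks and 12 x 12 or 16 x 16 scenes for
end-to-end determinism — sizes chosen so the full suite exercises every
stage, including clustering, in well under a minute per check while
keeping region sizes (several hundred pixels) representative of real FPA
tiles.
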