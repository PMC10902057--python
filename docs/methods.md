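# Methods

## Scope and model of the data

`lipidseg` implements the computational half of a lipid imaging mass
spectrometry (LIMS) workflow for focal demyelinating spinal-cord lesions:
negative-ion MALDI-Orbitrap rastering at 10 µm/pixel over 12-µm coronal
sections, m/z 550–1000, followed by spectral reduction, correlation-driven
divisive segmentation, region-fingerprint statistics and [M−H]⁻ lipid
annotation.  Because no raw sections are distributed, every stage is
exercised against a synthetic datacube generator with exact ground truth.

## Synthetic sections

**Phantom.**  The cord cross-section is an ellipse on a background raster;
a ventral horizontal band inside it is grey matter, the remainder white
matter; the lesion is an ellipse (core) wrapped in a ring (peri-lesion)
placed dorsally.  Geometry is parametric rather than anatomically traced so
the label raster is exact and regenerable.  The default raster is 48×48
pixels — a deliberate desk-scale reduction of a real section (~150 px
across at 10 µm/pixel); all geometry scales with the raster.

**Region templates.**  Each region carries a relative-abundance vector over
41 species in nine classes (PC, PC-E, PE, PE-E, PI, PS, PG, SM, sulfatide),
summing to 1.  The white-matter template is myelin-rich (27% sulfatide);
peri-lesion and core templates are produced by multiplicative per-class
factors with species-level overrides encoding the reported directional
changes of demyelination at 14 days post injection: PC and PE up toward the
core, PC ethers down, sulfatides and PS down, SM up, PI 38:4 (the main
arachidonic-acid store) strongly up together with other putative
AA-containing PIs, PE-ether remodelling (36:2e/40:6e down, 38:6e/38:7e/40:7e
up) and PE 36:5e peaking in the peri-lesion.  Grey matter is PI-rich and
poor in myelin lipids.  Factor magnitudes (typically 1.4–3.2×) match the
visual scale of the published per-species changes.  An `effect_scale`
parameter interpolates all factors toward 1 (0 collapses every region onto
white matter), used for effect-size monotonicity checks.

**Noise model.**  Peaks are Gaussian in m/z with constant FWHM
(700/60000 ≈ 0.0117 Da, resolving power ≈60,000 at m/z 700; a constant-FWHM
simplification of an FT analyser whose resolution varies with m/z).
Per-pixel latents: a mean-one log-normal total-signal factor (default CV
0.20), a rigid Normal(0, 3 ppm) mass drift, plus mean-one log-normal
amplitude noise per pixel-peak (CV 0.15), an additive baseline (1e-4 in
template units) and optional Poisson count noise (off by default).  The
cohort generator adds per-section log-normal template jitter (CV 0.10,
inter-animal variability) and lesion geometry jitter.  Nine sections by
default, one per animal of the emulated study.  All latents are returned
for recovery tests.  No per-pixel noise statistics were published for the
real data; these defaults are plausible Orbitrap-MSI values, exposed in the
noise configuration.

The m/z axis is sparse: windows of ~4 ppm-spaced samples around each
species, each window centred exactly on the species m/z.  This keeps a
48×48 cube under 30 MB and makes the noiseless limit exact: with all
dispersions at zero, the apex sample of every peak equals the template
abundance, so the preprocessing chain must reproduce templates to float
precision, not merely approximately.

**What the simulator does not emulate** — and hence what passing tests do
not show about real data: matrix and ablation inhomogeneity, isotope
envelopes and adduct heterogeneity, chemical background structure,
resolution varying with m/z, spatially correlated noise, partial-volume
mixing at region borders, and anatomical geometry.  Results on the phantom
demonstrate correctness of the algorithms under the stated noise model, not
instrument-level realism.

## Preprocessing

Order: align → TIC-normalize → average → pick peaks → reduce.

*Alignment* (method unstated in the source workflow) is a per-pixel rigid
ppm shift maximizing cross-correlation with the cohort mean spectrum,
scanned on a 0.5 ppm grid within ±10 ppm (configurable), refined by
parabolic interpolation, two passes with the reference recomputed after the
first.  Resampling uses cubic splines: linear interpolation on a few-ppm
grid scallops the objective and biases estimates by a sizeable fraction of
the grid step.  All-zero pixels get shift 0 and a flag; estimates at the
search bound are flagged saturated.  Injected ±6 ppm drifts are recovered
within ±1 ppm (worst case ≈0.5 ppm); estimated-vs-true correlation exceeds
0.95 up to 10 ppm drift SD.

*TIC normalization* scales each pixel's summed sampled intensity to 1;
all-zero pixels are flagged, never raised on.

*Tissue masking*: pixels with TIC below 5% of the median TIC are excluded
(a `quantile` mode is also provided).  A fixed low quantile cannot work
when the background fraction is large and unknown, as on the phantom
(~40% background); the relative rule is scale-free and exact here because
background pixels carry only baseline.

*Peak picking* operates on the average spectrum only: strict local maxima
of a 3-point moving-average-smoothed trace whose raw apex intensity is at
least 0.5% of the raw base peak (both thresholds configurable).

*Reduction* takes, per pixel and per peak, the maximum intensity within
±5 ppm of the peak centre; overlapping windows are cut at midpoints
(nearest-centre rule) with a logged warning.

## DHC-RC segmentation

Pixels are fingerprint rows of the reduced matrix; similarity is Pearson
correlation, computed as dot products of row-standardized fingerprints so
group statistics need no pairwise matrix.  Segmentation is divisive: the
leaf with the lowest mean within-segment correlation (singletons count as
perfectly coherent) is bipartitioned until the requested count (five
initially; four at re-segmentation of the lesion-matching segments, both
published choices).

A bipartition is grown by two competing walkers seeded at a minimally
correlated pixel pair; at each step the walker whose best candidate has the
highest mean correlation to its current region claims that pixel.  The
"variable number of walkers" of the original description is realized as
restarts: the global minimum-correlation pair plus up to five further seed
pairs drawn (deterministically per split seed) from the bottom 1% of
pairwise correlations; the bipartition maximizing *mean within-group minus
mean between-group correlation* is kept.  Segments of ≤12 pixels are split
by exact enumeration of all bipartitions of that same objective — feasible
there and free of heuristic error; the walker itself is verified against
exhaustive search on block-structured instances.  Above 20,000 pixels seed
search falls back to a subsample (assignment is always exact); ties
everywhere resolve to the lowest pixel index.  Spatial connectivity is not
enforced: spatially coherent lesion segments are an outcome, not a
constraint.  The original rank-compete mechanics are only verbally
specified; every choice above sits behind `WalkerConfig` so alternatives
are pluggable.

Colours: the two segments with minimal mean-fingerprint correlation take
values 0 and 1; every other segment sits at d_a/(d_a+d_b) where d_x is its
correlation distance (1−r) to extreme x — proximity in colour means
similarity of fingerprint.  Exact ties are separated by a stable
id-ordered nudge so colours are unique.

On ten default-noise phantoms the 5-way map isolates the core analogue at
median purity 1.0, 4-way re-segmentation recovers the peri-lesion ring at
median F1 ≈ 0.87, and the full reconstruction reaches median adjusted Rand
index ≈ 0.99 against ground truth.

## Statistics

Fingerprints are means over a region's pixels of the annotated species
columns, renormalized to sum 1 — one observation per (section, region);
pixels are never used as replicates.  Comparisons use Welch's two-sided
t-test (safer than Student under unequal variances; a flag restores the
pooled test) with stars exactly as printed in the source figure caption:
\* p<0.05, ** p<0.01, *** p<0.0001.  The unusual *** threshold is kept as
printed, overridable in `STAR_THRESHOLDS`.  No multiple-testing correction
is applied to the stars; a Benjamini–Hochberg column is emitted alongside.
PCA is mean-centred (unit-variance optional) via SVD with the sign of each
component fixed so its largest-magnitude loading is positive; constant
columns are dropped with a warning.  Classification is a 500-tree random
forest (sqrt-features per split, fixed seed) evaluated strictly
out-of-fold, by default leave-one-section-out; metrics derive from the
pooled confusion matrix, specificity one-vs-rest.  The published 46%/15%
PCA variance fractions are a property of the real sections and are not
reproduced; the synthetic analogue instead verifies the PC1 gradient
(strict centroid ordering white matter → peri-lesion → core, sign
invariant) and the perfect random-forest classification.  The permutation
null uses stratified 3-fold CV with a smaller forest — the null is
scheme-independent in expectation and this keeps 100 permutations cheap.

## Annotation

The bundled library (52 species, CSV shipped with the package) covers the
nine classes with formulas derived from documented backbone compositions:
diacyl phosphatidic acid C(c+3)H(2c−2d+5)O8P plus class head groups
(choline +C5H11N, ethanolamine +C2H5N, glycerol +C3H6O2, serine +C3H5NO2,
inositol +C6H10O5); ether variants −O+2H; SM C(c+5)H(2c−2d+13)N2O6P;
sulfatide C(c+6)H(2c−2d+11)NO11S.  [M−H]⁻ = monoisotopic mass − proton.
All bundled masses sit ≥40 ppm apart, so simulated species round-trip
uniquely at the 5 ppm default tolerance (an assumption consistent with
60,000 resolving power; no tolerance was published).  Matching reports all
candidates within tolerance sorted by |ppm|.  PS matches are flagged when a
PI of the same sum composition exists: the PI in-source fragment (loss of
anhydroinositol, 162.0528 Da, vs the serine head, 87.0320 Da) lands exactly
on the PS [M−H]⁻ m/z, so PS annotations warrant caution.  Only the [M−H]⁻
adduct is bundled (negative mode has few adducts); the adduct argument is
the extension point.  Annotations are m/z-only; no MS/MS confirmation.

## Pipeline and problem sizes

The orchestrated run is: simulate (or ingest imzML) → preprocess → 5-way
segmentation → select lesion-matching segments → 4-way re-segmentation →
fingerprints → statistics → annotation, with a manifest (config,
provenance, seeds, stage wall-times) sufficient for exact re-runs.  In
synthetic mode lesion segments are selected by ground-truth overlap — the
stand-in for the IHC-guided expert choice, which cannot be inferred from
MSI alone; in real-data mode the ids must be user-supplied.  Default
problem sizes — 48×48 rasters, nine sections, ten repeat seeds for
segmentation benchmarks — are the package's desk-scale study conditions;
a nine-section run completes in well under a minute per stage on one core.

## Known limitations

Constant-FWHM peaks and a sparse m/z axis are idealizations; alignment
assumes a rigid ppm shift per pixel (no nonlinear calibration drift);
segmentation quality on real sections with partial-volume mixing will be
lower than on the phantom; PS/PI and other isobaric ambiguities are
flagged, not resolved; class assignment of ether species from nominal
composition alone cannot distinguish plasmanyl from plasmenyl isomers.
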