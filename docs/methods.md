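# Methods

## The question the package answers

Radiomic features are scalar descriptors computed from the voxels inside a
region of interest (ROI).  A feature is *unique* to its ROI when its value
from the tumor is distinguishable from the value the identical ROI shape
produces elsewhere in the same image set; a feature whose values are
interchangeable across tissues carries no tumor-specific information and
should be dropped from radiomic models.  `featuniq` mechanizes the
screening procedure: translocate the tumor ROI rigidly into four other
tissue regions (adipose, heart, lung beyond the nodule, muscle), extract
the same 123 features from all five placements, and classify each feature
from two statistics —

- **CV** (coefficient of variation), per patient across the five tissue
  values: `CV = 100 · s / |x̄|` with the sample (n−1) standard deviation.
  `CV < 10%` means the feature barely moves between tissues.
- **CCC** (Lin's concordance correlation coefficient), per patient between
  the tumor series and each tissue series:
  `CCC = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)` with biased (n) moments.
  `CCC > 0.85` means the tumor and tissue values agree strongly.

Aggregation rules (defaults in `DecisionConfig`): a feature is
**CV-nonunique** in a cohort when at least 50% of its patients have
CV < 10%; a (feature, tissue pair) **fails** when at least 50% of patients
have CCC > 0.85, and a feature is **CCC-nonunique** when it fails in ≥ 2 of
the four tumor/tissue pairs; a feature is **nonunique overall** when it is
CV-nonunique in every cohort *and* CCC-nonunique in every cohort.

### The inclusive fraction rule

The patient-fraction comparison is inclusive (`count ≥ 0.5·n`).  This is a
deliberate reading: with two cohorts of 14 and 18 patients, several
features sit exactly at half (9/18), and only the inclusive rule makes the
replayed published counts internally consistent (29 CV-nonunique features
in the larger cohort require the 9/18 entries to qualify).  The strict
rule (`count > 0.5·n`) remains available via
`DecisionConfig(inclusive_fraction=False)`.

## Replay of the published counts

The decision engine is exercised against the per-feature failure counts
printed for two NSCLC cohorts (GE, n = 14; Siemens, n = 18), packaged as
CSVs under `featuniq/data/`.  Features absent from those tables have count
zero.  The replay recomputes — it does not quote — the headline numbers:
12 and 29 CV-nonunique features (9.8% / 23.6% of the bank), 18 and 16
CCC-nonunique features (14.6% / 13.0%), an 11-feature cross-cohort CCC
overlap, and a combined set of 9 features (7.3%): seven
gradient-orientation-histogram statistics plus the 3D GLCM features IDMN
and IDN.  The CCC fixtures enter the engine at the regions-failed level
(the per-patient CCC values behind them were not published), so the replay
exercises the ≥ 2-pair rule and the combination rule, not the
patient-fraction rule, which the CV fixtures cover.

## Feature bank (123 features)

| category | n | variant axis |
|---|---|---|
| IntensityDirect | 34 | deciles for Percentile / PercentileArea / Quantile |
| IntensityHistogram | 9 | deciles for Percentile |
| IntensityHistGaussFit | 6 | — |
| GLCM 2D / 3D | 22 + 22 | 4 in-plane / 13 unique 3D directions, distance 1 |
| GrayRunLength2D | 11 | 4 in-plane directions |
| NeighborIntensityDiff 2D / 3D | 5 + 5 | — |
| GradientOrientHistogram | 9 | deciles for Percentile / PercentileArea / Quantile |

Conventions that the feature names alone do not pin down, fixed here once:

- **Quantization**: 64 equal-width levels over the ROI's own min–max HU,
  separately per ROI (constant ROIs map to level 1).  N_g enters IDMN/IDN
  explicitly, so the choice is material and recorded in provenance.
- **Entropies** in bits (log₂), `0·log 0 = 0`.
- **Kurtosis** non-excess (normal = 3); MeanAbsoluteDeviation about the
  mean, MedianAbsoluteDeviation about the median, both unscaled.
- **GLCM**: symmetric accumulation, distance 1; 2D matrices use in-plane
  offsets so pair counts pool across slices before normalization.
  `IDN = Σ p/(1 + |i−j|/N_g)`, `IDMN = Σ p/(1 + (i−j)²/N_g²)`; the
  unnormalized counterparts (`InverseDiff`, `InverseDiffMoment`) keep the
  raw difference.  Termwise, IDN ≥ InverseDiff and IDMN ≥ InverseDiffMoment
  for any matrix — the order invariant the tests assert — and at N_g = 64
  the normalized pair crowds toward 1 on every tissue
  (`analysis/03_normalization_mechanism.py` tabulates the effect).
- **Run lengths**: maximal constant-level runs restricted to in-mask
  voxels; a mask gap terminates a run; RunPercentage divides by the ROI
  voxel count.
- **NGTDM**: 8 in-plane neighbours (2D) or 26 (3D), in-mask only;
  Coarseness's denominator is guarded by ε = 1e−6, capping it at 1e6 on
  perfectly homogeneous ROIs.
- **Local statistics** (LocalEntropy/LocalRange/LocalStd): 3×3×1 in-plane
  window restricted to in-mask voxels — the smallest nontrivial window,
  chosen so 4 mm nodules still yield meaningful neighbourhoods.
- **Gauss fit**: least-squares fit of 1–3 Gaussians to the 64-bin
  histogram, deterministic quantile-segment initialisation, BIC model
  selection; the dominant (largest-area) component is reported; a moment
  fit is the flagged fallback.  HistArea = total count × bin width, which
  depends only on the ROI size and intensity range — with an identical
  translocated ROI it is expected to be CV-nonunique, and
  `DecisionConfig(exclude_hist_area=True)` can drop it as a same-shape
  artifact.
- **Gradient orientation**: per-slice central-difference gradients at
  in-mask voxels; orientation angles in (−180°, 180°] enter a
  magnitude-weighted 36-bin histogram; the nine features are descriptive
  statistics of that weighted distribution.  An all-zero gradient field
  (constant ROI) yields the degenerate convention "all statistics 0".
  Because orientation statistics are largely invariant to tissue identity
  for stationary textures, this family is the natural nonunique block.
- **Undefined values** (single-voxel ROIs, empty co-occurrence matrices)
  are carried as NaN and skipped pairwise by CV/CCC, never coerced to 0.

The 34 IntensityDirect members beyond the twenty that any external listing
fixes are reconstructed from the IBEX naming lineage plus the cardinality
constraint and are flagged `reconstructed=True` in the registry.  The
variant-expanded total of this bank is 534 values; no claim is attached to
any particular expansion count.

### CCC grouping

Directional and decile-based features get an individual CCC across their
matched variant values (e.g. the 13 direction values of a 3D GLCM feature,
tumor vs tissue).  Single-valued features receive the category-level CCC
computed across the scalar features of their category, assigned to every
member — so scalar categories succeed or fail as blocks, which is exactly
the block-failure pattern visible in the published CCC table (the six
Gauss-fit features fail together).  The alternative everything-per-category
mode is exposed as `ccc_table(..., mode="category")`.  Category-level CCC
is computed on raw feature values; features of large magnitude dominate
that statistic, a documented consequence of not rescaling.

For CV, a multi-variant feature is summarised per region by its variant
mean before the five-region CV is taken.

## Synthetic phantoms

`phantom_synth` renders deterministic CT-like volumes so the entire
pipeline runs without patient data.  Geometry is a slab layout: four
axial-plane bands along y (muscle 0–22%, adipose 22–44%, heart 44–66%,
lung 66–100%), constant along z, with a spherical nodule centred in the
lung band.  Each band is thick enough to host the translocated nodule ROI
in-plane.  Texture is zero-mean Gaussian white noise smoothed by a
Gaussian kernel (correlation length in voxels), rescaled to the requested
standard deviation; the regional noise mean is subtracted so every
tissue's voxel mean equals its specified attenuation exactly.  Defaults:
lung −800 HU (σ 60), adipose −100 (σ 20), heart +40 (σ 25), muscle +50
(σ 25), nodule +20 (σ 40), correlation lengths 1.0–1.5 voxels — textbook
attenuation means with noise magnitudes typical of thoracic CT.  A
mean-centred radial intensity ramp (−30 HU centre-to-rim) makes
gradient-orientation features non-degenerate.

What the phantom does **not** emulate: anatomy, partial-volume effects,
reconstruction-kernel correlation structure, beam hardening, dose
modulation, or any scanner difference between cohorts (both synthetic
cohorts draw from the same spec, differing only by seed).  Published
texture statistics per tissue do not exist, so the noise parameters are
plausible settings, not calibrated values.  Consequently a passing phantom
run demonstrates that the machinery is correct — shape-conserving
placement, complete extraction, bit-exact reproducibility — not that the
phantom reproduces the published per-feature verdicts; the published
counts are validated through the replay path instead.  It is still
scientifically reassuring that on phantoms the combined nonunique set is
dominated by gradient-orientation statistics, the same family the real
cohorts flag.

## ROI translocation

Valid offsets are those for which every translated foreground voxel lands
inside the target tissue label; they are found exactly (FFT
cross-correlation of the target indicator with the ROI kernel, thresholded
at the ROI voxel count).  In-plane offsets (Δz = 0) are preferred; only
when none exists does the search widen to |Δz| = 1, 2, … and stop at the
nearest feasible slice shift — the least-biased mechanization of "choose an
appropriate z-location".  Among the winning tier one offset is drawn
uniformly at random under a per-(seed, tissue) generator, because the
placement is meant to be random, not nearest.  Overlap between different
non-tumor placements is permitted (only tissue containment is enforced);
placements are logged with offset, fallback flag and seed.  Rigid
translation guarantees the voxel count and the multiset of internal
relative coordinates are conserved, which the pipeline asserts on every
placement.

## Determinism and problem sizes

Every random draw descends from a master seed: per-patient phantom seeds
via `SeedSequence([master, cohort, index])` (kept below 2³¹), placement
draws via `default_rng([seed, tissue_label])`.  Reruns with the same
config and seed are bit-identical on all CSV outputs, which the tests
compare byte for byte.  The shipped study configuration uses two cohorts
of five phantoms on a 24×80×80 grid with a 10 mm nodule — small enough to
run interactively, large enough that all texture families are
non-degenerate (≈ 500 ROI voxels, five tissues, 40 placements).

## Known limitations

- The exact IBEX variant enumeration (its 1739 expanded values) is not
  reproduced; the registry's variant axes are the package's own, stated
  above.
- Category-level CCC on raw values is scale-dominated (no rescaling is
  applied, matching the procedure being mechanized).
- The Gauss-fit component count is a BIC decision on a least-squares fit,
  not a mixture-model likelihood; it is deterministic but can differ from
  an EM fit on ambiguous histograms.
- DICOM reading handles single-series directories only; RT-STRUCT
  contours are out of scope (masks are the exchange format).
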