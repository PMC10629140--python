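# Methods

## Problem and pipeline

Given per-subject paired volumes — one real CT and one or more synthetic
CTs on an identical grid, with one shared set of binary ROI masks — the
pipeline quantifies (1) voxel-level image quality inside each ROI and
(2) the reproducibility of radiomic features between real and synthetic
images across the cohort. No registration or resampling is performed:
geometric alignment is an upstream responsibility, and every case is
validated for grid agreement before any computation.

## Image-quality metrics

MAE, RMSE, SSIM and PSNR are computed over mask voxels on raw HU. Working
in HU (rather than on [−1, 1]-rescaled intensities, for which a
`minmax_normalize` helper exists) keeps MAE/RMSE in physically meaningful
units.

Two constants are not universal for CT and are therefore explicit
configuration, resolved once per subject and recorded in every output
record:

* **PSNR peak** (`psnr_max`, default `"auto"`): the real image's dynamic
  range over the body mask. PSNR = 10·log₁₀(peak²/MSE); identical images
  return a documented +∞ sentinel. Reported PSNR magnitudes are only
  comparable across runs that share a peak convention.
* **SSIM** uses a Gaussian-weighted 7³ window (σ = 1.5, K₁ = 0.01,
  K₂ = 0.03, data range `"auto"` as above) via scikit-image's
  `structural_similarity`; the ROI value is the mean of the SSIM map over
  mask voxels, with the map computed on the mask bounding box padded by the
  window half-width. ROIs whose bounding box is smaller than the window in
  any axis fall back to a single global window over mask voxels and are
  flagged in the record.

## Radiomic feature bank (837 features)

* **Discretization**: fixed bin width (default 25 HU) anchored at the
  masked minimum, `level(x) = floor((x − min)/w) + 1`, top bin closed.
  This makes every discretization-based feature exactly invariant to adding
  a constant to the image. An alternative `width-aligned` anchor snaps bin
  edges to multiples of the width (the convention of some extraction
  tools, which aligns bins across images at the cost of arbitrary-shift
  invariance); it exists for cross-tool comparison and is off by default.
* **First order (18)**: energy, total energy (voxel-volume scaled),
  entropy and uniformity (on the discretized histogram), min/max/range,
  percentiles and IQR, mean/median, MAD and robust MAD (10–90 percentile
  band), RMS, skewness, kurtosis, variance — population (1/n) moments.
  Skewness/kurtosis of a constant region return a 0 sentinel; robust MAD
  of an empty percentile band returns 0.
* **Texture (75)**: GLCM (24), GLRLM (16), GLSZM (16), GLDM (14),
  NGTDM (5). GLCM and GLRLM are built per direction over the 13 unique
  3-D offsets at distance 1 and features are averaged over directions;
  GLCM matrices are symmetrized (counts + transpose). GLSZM zones, GLDM
  dependence neighbourhoods (α = 0; dependence size = 1 + equal-level
  neighbours, so an isolated voxel has size 1) and NGTDM neighbourhoods
  use 26-connectivity. Degenerate denominators return documented
  sentinels: 0 for correlation/IMC-type features, 10⁶ for NGTDM coarseness
  of a flat region. No resegmentation or outlier clipping is applied
  inside the mask. Matrix construction is validated against independent
  brute-force enumeration on small volumes (see tests).
* **Wavelet (744 = 93 × 8)**: one-level stationary (undecimated) 3-D
  transform with the `coif1` basis; each of the 8 L/H sub-bands stays on
  the input grid so the ROI mask applies unchanged (odd axes are
  edge-padded by one voxel and cropped back). The decomposition is
  computed once per volume and shared by all ROIs of that volume.
  Sub-band discretization reuses the same bin width on each sub-band's own
  masked range, since sub-band intensities are not HU. Letters are ordered
  (slice, row, column).
* Feature names are `{filter}_{family}_{Feature}`; the vector always has
  exactly 837 entries — failed features become flagged sentinels, never
  silent drops. Shape features are deliberately absent: identical contours
  on real and synthetic images make them constant within a pair.

## Concordance analysis

Lin's CCC with 1/n moment estimators is the agreement measure; a
bias-corrected (n/(n−1)) variant exists but is off by default, keeping the
classic concordance definition. Both-constant pairs are 1.0 when equal,
0.0 (flagged degenerate) when not. Levels: excellent ≥ 0.9 > good ≥ 0.75 >
moderate ≥ 0.5 > poor, boundaries inclusive upward.

Cross-model overlap of excellent/good sets reports Jaccard **and** the
intersection as a fraction of each model's own set, because "proportion of
overlapping features" is denominator-ambiguous; all three are emitted.
MAE-vs-mean-CCC correlation across ROIs reports both Pearson and Spearman
(the appropriate choice depends on linearity one cannot assume with ≤ 7 ROI
points). Paired t-tests (two-sided, df = n − 1) compare models per
(ROI, metric) across subjects and per (ROI, category) across features;
zero-variance differences raise a documented degenerate-test error, and no
multiple-testing correction is applied (noted in output provenance).

## Synthetic cohort generator

The generator emulates the statistical structure the analysis needs, not
anatomy: an ellipsoidal soft-tissue body (≈40 HU) with a bone shell
(≈700 HU) in air (−1000 HU), smooth intra-tissue texture (SD 25 HU),
acquisition noise (SD 10 HU), and six ellipsoidal ROIs. The tumor ROI is
partitioned by quantiles of a smooth random field into ≈8 % air, 63 % soft
tissue and 29 % bone, so it is heterogeneous the way a nasopharyngeal
tumor volume is. Default grid 64³ at 1.5 mm — desk scale; all geometry is
spec-driven.

Inter-subject variability (HU means jittered with SD 30 HU, bone 3× that;
ROI centers/radii jittered with SD 1.5 voxels) is essential: CCC is
undefined on a cohort of identical subjects.

Degradations are parametric stand-ins for synthesis-model error, applied
as blur → multiplicative bone remap (bone classified at 150 HU on the
pre-degradation image) → additive noise inside the body → optional
boundary artifact (a scaled gradient-magnitude map, emulating residual
source-modality edges). The two stock styles were fixed once as the
package's study conditions: `smoothnet` (blur 1.2 mm, noise 15 HU, bone
×0.85 attenuation) over-smooths — its body MAE lands near the
~90–130 HU scale typical of published MRI-to-CT synthesis — while
`cyclesim` (blur 0.5 mm, noise 30 HU, bone ×0.92, boundary artifact on) is
sharper but noisier. Seeding: per-subject, per-operator
`SeedSequence(master_seed, spawn_key=(subject, op))` substreams, so adding
a subject never perturbs earlier subjects.

What the generator does **not** emulate: real anatomy and tissue
boundaries, scanner artifacts, registration error, and the spatial error
correlations of actual network outputs. Passing tests therefore
demonstrate the correctness and calibration of the *measurement pipeline*
(counts, identities, analytic recoveries, monotone responses), not any
claim about how specific synthesis networks perform on patients.

## Numerical and design choices

* All arrays are (slice, row, column); masks are strictly binary (any
  nonzero voxel is foreground).
* ROI computations crop to the mask bounding box first (margin 8 voxels
  when wavelet features are required, else 1); crops never change
  mask-restricted statistics.
* Problem sizes in the analysis scripts and acceptance script (8 subjects
  at 64³; 6 subjects for the degradation sweep; 50 × 2000 draws for CCC
  recovery) were chosen as the smallest cohorts at which the measured
  quantities are stable across seeds.
* The curated-subset report takes a plain-text feature list as user input;
  the list shipped under `analysis/data/` is a synthetic stand-in and is
  labelled as such.

## Known limitations

* PSNR/SSIM magnitudes depend on the configurable peak/data-range
  constants; compare only within a convention.
* With small cohorts (n < 10) the per-feature CCC estimate is noisy; level
  percentages are stable in aggregate but individual features can change
  class between seeds.
* The stationary wavelet transform is periodic at volume boundaries; when
  a precomputed full-volume decomposition is compared with a per-ROI-crop
  decomposition, sub-band voxels near the crop edge differ slightly
  (original-image features are unaffected).
* GLSZM zone labelling runs one connected-component pass per gray level,
  which dominates runtime for very large, high-dynamic-range ROIs (e.g. a
  whole-body mask); texture ROIs in the shipped analyses are organ-scale.
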