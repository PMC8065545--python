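# Methods

`radpipe` implements a complete radiomic analysis of multiparametric
prostate MRI (T2-weighted images and apparent-diffusion-coefficient maps)
aimed at non-invasive markers of tumour aggressiveness: Gleason grade
group (GGG, dichotomized at >= 4+3), extracapsular extension (ECE) and
pathological nodal stage (pN). Because suitable patient images cannot be
redistributed, the pipeline ships with a synthetic lesion-phantom
generator that reproduces the statistical structure the analysis relies
on; every stage is exercised end-to-end on those phantoms.

## Pipeline

1. **ADC maps.** Diffusion-weighted pairs at b = 50 and 800 s/mm^2 are
   inverted under the monoexponential model `S(b) = S0 exp(-b ADC)`:
   `ADC = ln(S_low/S_high) / (b_high - b_low)` (mm^2/s). Voxels with a
   non-positive signal (noise floor) map to ADC 0 and are counted in a
   warning rather than aborting the run. Bias-field correction is treated
   as upstream preprocessing and is not re-implemented; inputs are assumed
   corrected (the phantom generator emits bias-free volumes).
2. **T2w standardization.** Whole-volume affine rescaling of intensities
   onto 0–600 (min -> 0, max -> 600). Plain min/max is used, not
   percentile-clipped min/max; the map is strictly monotone, and with
   fixed-bin-number discretization downstream (see below) the texture
   features are unaffected by this choice — only first-order intensity
   statistics see it.
3. **Volume filter.** Only lesions whose ADC-mask volume strictly exceeds
   0.7 cc enter the analysis (a lesion of exactly 0.7 cc is excluded;
   boundary cases are logged). Rationale: below ~4 voxels per direction
   texture matrices stop being meaningful on the coarser ADC grid.
4. **Feature extraction (93 features).** Per (image, mask): resampling to
   isotropic spacing, with the target set to the smallest in-plane spacing
   (the coarse slice axis is upsampled; tri-linear interpolation for
   intensities, nearest-neighbour for masks); Collewet VOI
   re-segmentation (retain intensities within mean +/- 3 sample SD,
   single pass, no iteration); fixed-bin-number discretization to 64 gray
   levels with the maximum clamped into bin 64. Families:
   - 14 morphological: mesh volume, voxel volume, surface area,
     surface/volume ratio, sphericity, maximum 3D diameter, three maximum
     2D diameters, major/minor/least axis lengths, elongation, flatness.
     (Compactness 1/2 and spherical disproportion are monotone functions
     of sphericity and are the members trimmed to reach 14.) Surface
     meshes come from marching cubes on a lightly smoothed (sigma = 1
     voxel) mask — the raw 0/1 mesh overstates a ball's surface by ~8% —
     with a fallback to the raw mesh when smoothing degenerates on sparse
     masks. Elongation `sqrt(l2/l1)` and flatness `sqrt(l3/l1)` come from
     the PCA eigenvalues `l1 >= l2 >= l3` of in-mask physical coordinates;
     a fully degenerate (single-voxel) cloud is defined isotropic
     (elongation = flatness = 1).
   - 18 first-order: energy, total energy, entropy (bits, on the 64-bin
     histogram), min, 10th/90th percentile, max, mean, median, IQR, range,
     MAD, robust MAD, RMS, skewness, kurtosis (not excess), variance
     (population), uniformity. Skewness/kurtosis of a constant VOI are
     defined 0.
   - 61 textural: GLCM (24), GLRLM (16), GLSZM (16), NGTDM (5) — the
     unique standard partition consistent with 14 + 18 + 61 = 93. GLCM and
     GLRLM use the 13 unique 3D offsets at Chebyshev distance 1, with
     per-direction features averaged; GLSZM zones and NGTDM neighbourhoods
     use 26-connectivity; only in-mask voxels enter any matrix. Degenerate
     fallbacks: GLCM correlation/MCC of a single-level VOI = 1, NGTDM
     busyness/strength/contrast = 0 when their denominators vanish,
     coarseness capped at 1e6. The GLCM `Idmn`/`Idn` normalizer `Ng` is
     the number of occupied gray levels. Filtered (wavelet/LoG) feature
     banks are out of scope by design.
5. **Stability rank.** Each feature is measured on the same patient
   subset under two readers' masks and tested with a tie-corrected
   Friedman rank test (chi-square reference, k-1 df). A feature is stable
   iff p > 0.05 strictly; the rank orders by descending p with ties broken
   by canonical name. With k = 2 readers the Friedman test reduces to a
   sign test and the chi-square p is anti-conservative at small n (worst
   case ~0.25 below the exact permutation p at n = 8, mid-range); it never
   over-states stability and orders features exactly as the exact test, so
   the rank is unaffected. The general-k implementation is kept for reuse
   and matches the reference library implementation exactly for k >= 3.
   The stability subset size is a config knob (default 20 patients).
6. **Redundancy pruning.** Pearson correlation across patients among the
   stable features; |r| > 0.8 defines edges, connected components are the
   clusters (deterministic and parameter-free), and each cluster is
   represented by its highest coefficient-of-variation member (sample
   SD / |mean|; ties and zero-mean infinities resolved by name order;
   constant columns correlate with nothing by definition). Connected
   components do not guarantee representatives of different clusters stay
   below the threshold (transitivity can fail); the guaranteed property —
   every pruned feature is highly correlated with a member of its own
   cluster — is the one tested.
7. **Cluster association.** Heavily skewed (|skewness| > 2, a config
   knob; the original criterion "extreme values" is not quantitative)
   nonnegative features are log2-transformed with zeros replaced by the
   column's smallest positive value; all features z-scored; agglomerative
   clustering (Euclidean distance, complete linkage — the heatmap-tool
   default — overridable) cut at exactly k = 2 groups. Group association
   with GGG/ECE/pN uses two-sided Fisher exact tests on 2x2 tables; pNx
   (unassessable nodes) patients are excluded from the nodal table only.
8. **Signatures.** Per modality, the non-redundant representatives within
   the first 10 stable features form S_TOP-T2w and S_TOP-ADC (redundancy
   is reduced *within* the top-10 set, so representatives always lie in
   it); S_TOP is their union; S_ADCmean is the single mean-ADC feature;
   S_TOP+ADCmean appends it. Class imbalance is handled by undersampling:
   10 random balanced subsets, each keeping all minority-class patients
   plus an equal-size majority draw. Within each subset an RBF-kernel SVM
   (C = 1, kernel width 1/(d * feature variance); no tuning) is scored by
   stratified 5-fold cross-validation with fold-wise standardization fit
   on training folds; metrics pool over folds, summaries
   (mean/SD/min/max) over the 10 subsets, and ROC/AUC from decision
   scores pooled across subsets. **Caveat:** how performance is estimated
   within each balanced subset is genuinely open — resubstitution would
   inflate every metric; cross-validation is the conservative choice made
   here and is the main free methodological decision in the package.
   Sensitivity counts the positive class (high GGG / ECE present /
   pN >= 1). TZ-only classification is not run (too few TZ lesions by
   construction).

## Synthetic cohort

Each patient carries one ellipsoidal index lesion (random axis ratios at
a fixed equivalent-sphere radius) on an anisotropic grid, default
(0.6, 0.6, 3.0) mm — fine in-plane, coarse slices, so isotropic
resampling is genuinely exercised. Lesion interiors hold a Gaussian
random field (white noise smoothed to a class-specific correlation
length, the kernel FWHM in mm) shifted to a class-specific mean;
backgrounds are uniform plus noise (no anatomy — only the VOI is
analyzed). Defaults encode the aggressiveness signal: mean ADC 0.85e-3
mm^2/s (high GGG) vs 1.25e-3 (low) against 1.6e-3 benign background,
correlation lengths 5 mm (high, coarser) vs 2 mm (low), and analogous
T2w means; these are typical clinical magnitudes. The DWI pair is the
exact monoexponential forward model of the ADC field before noise, so
`compute_adc` recovers the generating field to floating-point precision
in the noise-free setting. Reader 1's masks are the true ellipsoid;
reader 2 is a bounded random boundary perturbation (smooth random field
applied to the signed distance, saturating at the magnitude, default
1 mm), retried until Dice >= 0.6 — a repository choice, since no
quantitative inter-reader disagreement figure was available; reader 2 is
deliberately *not* an independent segmentation model. Labels follow the
analyzed-cohort prevalences (high GGG 71%, ECE 61%, pN>=1 21%, pNx 16%,
PZ 69%/TZ 26%/both 5%); ECE and pN are drawn conditionally on the class
with a positive association (strength 0.15, clipped to preserve
marginals) so that those endpoints carry indirect signal; zone and pNx
are class-independent. By default 40/102 of lesions are drawn below the
0.7 cc cut-off, mirroring the enrolled-to-analyzed attrition.

What the phantoms do **not** emulate: prostate anatomy, endorectal-coil
bias fields, Rician noise statistics, motion, independent per-modality
segmentations, multifocal disease, or any coupling between lesion shape
and class. Passing tests therefore demonstrate that the pipeline's
machinery is correct and recovers injected effects — not that the
clinical effect sizes or the reported cohort-level p-values generalize.

## Numerical choices and problem sizes

- Determinism: one config seed fans out to stages by fixed offsets; rerun
  with the same config is bit-identical for all CSV/JSON outputs.
- FBN discretization: `level = min(64, floor(64 (x - min)/(max - min)) + 1)`;
  a constant VOI maps to level 1 everywhere.
- Degenerate inputs raise structured errors (constant T2w volume, empty
  post-resampling VOI, < 4 patients for clustering) or take defined
  fallbacks listed above.
- Tests and the acceptance script run cohorts on a "compact" phantom
  preset (48 x 48 x 14 grid, (0.7, 0.7, 2.8) mm spacing, lesions 6–8.5 mm
  equivalent radius) chosen so a full 102-patient pipeline completes in
  well under a minute; the statistical structure is identical to the
  default preset. Texture-oracle checks run on random VOIs up to 6^3
  voxels with up to 4 gray levels against pure-Python enumeration.
- Known limitations: the chi-square Friedman p at k = 2 (above); Fisher
  tests are conditionally exact and hence conservative at small n; the
  pooled-ROC construction concatenates decision scores across subsets,
  which assumes comparable score scales between subsets (fold-wise
  standardization keeps them close); complete-linkage two-group cuts can
  isolate outlier patients on cohorts with extreme feature dispersion.
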