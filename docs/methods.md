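# Methods

## Overview

`hepatex` re-implements, as a reusable and fully tested pipeline, a CT
radiomics analysis of the liver in acute alcohol-associated hepatitis
(AAH): a 178-dimensional texture signature is extracted from a single
masked axial liver slice per subject, a recursive-feature-elimination
random forest (RFE-RF) selects the texture subset that best separates AAH
from trauma controls, and each selected texture feature is then related
to 13 clinical predictors through an elastic net followed by a debiased
univariate refit with Benjamini-Hochberg FDR control.  Because no patient
images are distributed with the original study, the package ships a
synthetic phantom cohort generator that reproduces the statistical
structure the analysis relies on, with full ground truth, so that every
stage can be validated end to end.

## Texture signature

The unit of analysis is a `MaskedImage`: a 2D grayscale grid (arbitrary
HU-like units, treated as given — no windowing or rescaling) plus a
same-shape binary region of interest.  Pairs, runs, zones and LBP centers
never cross the mask boundary.

**Discretization.**  Masked intensities are binned equal-width into nine
integer levels 0–8 over the region's min–max range:
`level(x) = min(8, floor(9 (x − min)/(max − min)))`; a constant region
maps to level 0.  Nine levels is the literal reading of "values between
zero and eight"; `n_levels` is a config key so eight-level discretization
is one flag away.

**Families and counts.**  The 178-name manifest is
13 first-order + 21 GLCM × 4 directions + 11 GLRLM × 4 directions +
11 GLSZM + 26 LBP bins.  The per-family lists follow the feature families
of the classic R `radiomics` texture package, which yields exactly this
total and contains every feature name the study reports (e.g. "0 GLNU",
"45 RLN", "45 short run emphasis", "135 cluster tendency",
"Size zone variability", "LBM 0"–"LBM 25").

Conventions pinned for reproducibility:

* coordinates row-major, origin top-left; direction offsets
  0°→(0,1), 45°→(−1,1), 90°→(−1,0), 135°→(−1,−1); a 90° image rotation
  therefore swaps the 0↔90 and 45↔135 feature blocks exactly (a property
  test).
* GLCM: distance 1, symmetric accumulation (transpose added), normalized
  to probabilities.  Haralick-style formulas as documented in
  `texture.glcm_features`; `inverse variance` sums `p(i,j)/(i−j)²` off
  the diagonal.
* GLRLM: maximal collinear constant-level runs, broken by the mask and
  image edge; every masked pixel lies in exactly one run per direction
  (conservation is asserted: Σ j·R(i,j) = n_pixels).
* GLSZM: maximal 8-connected constant-level zones, computed once
  (a size-zone matrix has no direction); Σ s·S(i,s) = n_pixels.
* Gray-level weighting in low/high-intensity emphases uses `level + 1`,
  because the level range includes 0 and the standard formulas divide by
  the squared level.
* First-order statistics are computed on the discretized levels (the
  study discretized "before analysis"); `first_order_on_raw` flips this.
  Skewness/kurtosis use population moments, kurtosis is Pearson
  (non-excess).
* LBP: rotation-invariant uniform patterns, P = 24 circular neighbours,
  radius 3, bilinear interpolation (scikit-image), computed on **raw**
  intensities; P + 2 = 26 bins explain the published "LBM 0 … LBM 25"
  labels.  Centers whose sampling circle leaves the image are skipped.
* Undefined values (no valid pixel pair in a direction, zero variance)
  are NaN, never silently zero; downstream stages drop NaN columns with a
  logged warning.

Numerical note: LBP rotation invariance is exact only up to interpolation
ties.  On smooth images with integer plateaus the interpolated neighbour
can equal the center exactly, and a one-ulp difference in interpolation
weights after rotation flips the `>=` threshold for a handful of pixels;
histograms of rotated smooth phantoms therefore agree to ~1e-3, while
generic images agree to better than 1e-6.

## Classification (RFE-RF)

The cohort is split stratified into training and held-out test subjects
(`test_size` accepts a fraction or an explicit count, honouring both the
"20 % left out" description and the 52/17 split the study reports for 69
subjects).  On the training part, repeated stratified k-fold resampling
(10×10 by default) drives the eliminator: within each resample, features
are ranked by random-forest impurity importance on the resample's
training part (permutation importance by flag), the forest is refit at
each candidate subset size, and held-out accuracy is recorded.  The
candidate grid defaults to {1–15, 20, 25, 30, 40, 50, 75, 100, 178} —
dense near the low sizes where such cohorts typically peak.  The chosen
size is the smallest whose mean CV accuracy lies within one standard
error of the maximum (`one_se=False` gives the exact argmax).  The final
forest (500 trees by default, √p features per split) is refit on all
training data at the chosen size and evaluated on the held-out subjects;
AAH is the positive class, and sensitivity/specificity/PPV/NPV with a
zero denominator are NaN.

## Clinical association

For each selected texture feature the 13 predictors (age, race, sex, WBC,
BUN, creatinine, total bilirubin, albumin, AST, ALT, platelet count,
MELD, cirrhosis) enter an elastic net with the texture feature as
outcome.  Categoricals are one-hot encoded against the largest category
as reference; all design columns are standardized internally, so the
coefficient magnitudes are comparable and the "top predictor" (largest
absolute standardized coefficient at the cross-validated optimum,
one-hot columns attributed to their parent) is invariant to affine
rescaling of any predictor.  The grid covers mixing parameters
l1_ratio ∈ {0.1, …, 1.0} and a 50-point automatic penalty path, selected
by 10-fold cross-validated RMSE; the reported `elastic_rmse` is the CV
RMSE at the optimum.  If every coefficient is shrunk to zero the record
carries the `"none"` sentinel and is excluded from the FDR family.

Debiasing: the winning predictor alone is refit by ordinary least squares
with intercept; the slope (texture units per predictor unit) and the
two-sided t-test p-value are reported.  P-values across the testable
family are adjusted by the Benjamini-Hochberg step-up
(`adj_(k) = min_{m≥k} p_(m)·n/m`, capped at 1), implemented directly and
cross-checked exactly against both a brute-force O(n²) evaluation of the
definition and `statsmodels.multipletests`.

## Synthetic phantom cohort

A phantom slice is an elliptical "liver" region (default 128×128 image,
semi-axes 48×38 px) filled with `base_intensity` (120) plus a stationary
Gaussian random field — white noise smoothed by a Gaussian kernel of
scale `correlation_length` and rescaled to `contrast_sd` (12) — with a
Poisson number (mean 3) of darker elliptical inclusions standing in for
vessels.  Intensities are rounded to integers and clipped to the 16-bit
PNG range.

The single latent bridge between image and labs is the heterogeneity
`h = 1/correlation_length + noise`: rougher livers have larger h.  Per
subject, the correlation length is the class base (3 px for controls,
multiplied by `class_effect` for AAH; smaller means rougher) jittered
log-normally (log-SD 0.2).  Each laboratory value is log-linear in
centred h around its class median with correlated noise:
`lab = median_class · exp(slope·(h − h̄_class) + ε)`,
ε multivariate normal with common SD 0.15 and pairwise correlation 0.3
(emulating the multicollinearity of real chemistries), truncated at
physiologic floors.  Class medians for AST (32.5/153 U/L), ALT
(28/48 U/L) and total bilirubin (0.5/12.0 mg/dL) follow the published
cohort; the remaining labs use values typical of trauma controls versus
moderate-severe AAH (WBC 7/12.5, BUN 12/18, creatinine 0.9/1.0, albumin
4.2/2.8, platelets 250/150, MELD 7/24).  Demographics (age ≈ 44 ± 10,
sex ratios, race mix, cirrhosis prevalence 5 %/45 %) are sampled
per class.  Default link slopes give AST the strongest (negative)
dependence on h (−8 per unit h on the log scale), with weaker positive
links for WBC, bilirubin and BUN.

What the generator does **not** emulate: liver anatomy, CT physics (noise
spectra, beam hardening, slice selection), segmentation error, and any
dependence of texture on demographics.  Passing tests therefore show that
the pipeline recovers planted statistical structure of this form — not
that the published clinical findings replicate on real CT data.

### Study conditions used by the acceptance checks

* **Power run**: 30 AAH / 30 controls, `class_effect = 0.35` (a strong
  texture shift, chosen so the two classes are nearly separable),
  default phantoms, stratified 75/25 split, RFE-RF with 10×10 CV,
  50-tree forests and the 12-point size grid
  {1,2,3,5,8,10,15,23,30,50,100,178}.  Forest size and grid density are
  reduced from the library defaults to keep a desk-scale runtime; the
  selection behaviour is unchanged.
* **Null run**: `class_effect = 1` and no lab links, same cohort size.
  A single 60-subject null cohort can carry accidental class separation
  (with 178 features the best spurious feature reaches ~0.65 CV accuracy
  on an unlucky draw), so the null CV accuracy is averaged over three
  independent cohorts; 3 CV repeats and 30-tree forests suffice here.
* **Association run**: 34 AAH / 35 controls with `class_effect = 1` and a
  single strong negative AST link (`{"ast": −8}`).  Holding the class
  texture shift at 1 isolates the within-cohort AST↔h link: with
  `class_effect < 1` the AAH class has both a higher AST median and
  rougher texture, a between-class confound of the opposite sign that is
  not the property under test.  Recovery is scored over the four
  directional RLN features across 10 seeds.

## Reproducibility

Every stochastic component takes an explicit seed; per-subject,
per-resample and per-model seeds are spawned from `numpy.SeedSequence`,
so identical seeds give bit-identical cohorts, splits, rankings and
reports.  `run-all` writes a `run_metadata.json` with the package
version, the full configuration and its hash.  Feature CSVs are written
with `%.17g` and read with round-trip float parsing, so write→read is
exact.

## Known limitations

* The 178-name manifest reconstructs an enumeration the original report
  never prints; individual formula conventions (e.g. the base of
  entropy logarithms, 1-based intensity weights) follow common radiomics
  practice and are pinned by tests, but other software may differ in
  detail.
* Whether the original discretization used 8 or 9 levels is ambiguous
  ("between zero and eight"); 9 is the default here.
* GLSZM is computed once, not per direction, although the original text
  sweeps "each direction" over all families.
* The elastic-net RMSE is cross-validated; the original column of the
  same name is assumed, not known, to be cross-validated.
* Published headline numbers (82.4 % test accuracy, 23 selected
  features, Table-style coefficients) depend on 69 undistributed patient
  scans and are not reproduction targets; the synthetic checks validate
  mechanism, determinism and statistical calibration instead.
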