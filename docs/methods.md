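# Methods

## Model and assumptions

The analysis targets a two-arm randomized trial with right-censored
overall survival. All survival modelling is Cox proportional hazards,
`h(t|x) = h0(t) exp(βᵀx)`, fitted by Newton–Raphson maximization of the
partial likelihood with the Efron tie correction (Breslow available via
`ties="breslow"`); convergence is declared when the coefficient update
falls below 1e-8 in sup-norm, and monotone likelihoods (perfect risk
separation) raise instead of silently returning huge coefficients.
Hazard-ratio confidence intervals are Wald 95% intervals
`exp(β ± 1.96·SE)`. The two-group log-rank test uses the standard
hypergeometric variance at each distinct event time. Kaplan–Meier
medians are the first time the product-limit curve drops to ≤ 0.5, with
95% CIs obtained by inverting the log(−log) confidence band; an upper
limit the band never reaches is reported as non-estimable (`N.E`).
Proportional hazards are checked by correlating scaled Schoenfeld
residuals against event time (identity transform) with the
Grambsch–Therneau score test per covariate and globally; under
proportional hazards its rejection rate matches the nominal α in
simulation, and it has essentially full power against a sign-flipping
effect at n = 500.

Cohort-characteristics tables use Wilcoxon rank-sum for continuous
variables and the chi-square test of independence for categorical ones,
with Yates continuity correction on 2×2 tables — the dialect required to
reproduce published trial-table p-values (e.g. a 59/55 vs 46/46 smoking
split gives p = 0.91 only with the correction).

## Differential selection

Screening fits one univariable Cox model per variable per arm.
Multi-level categorical covariates are encoded as dummies against a
stated reference level (histology reference: Leiomyosarcoma); their
screen p is the likelihood-ratio test of the whole covariate and the
reported HR is that of the largest-magnitude level, which also defines
the direction used by criterion (ii). BH correction is applied across
radiomic features only, within arm; the p entering the selection
criteria is the adjusted p for radiomic features and the raw p for
clinical covariates. Thresholds (0.05 significant, 0.30 no/potential
association) are strict inequalities.

Correlation groups among candidates are connected components of the
graph with an edge for every significantly associated pair (Pearson for
continuous–continuous, chi-square for categorical–categorical, one-way
ANOVA for mixed pairs; α = 0.05). Components are deterministic and
order-free, which is why grouping is transitive rather than clique-based.
Within a group the member with the lowest target-arm criteria p is
retained; exact ties (possible after BH, which maps many raw p to one
adjusted value) fall back to the pre-correction p, then to lexicographic
order with a log entry. Representatives are ranked by
`min(p_A, p_B) / max(p_A, p_B)` with p floored at 1e-300; the final model
set is every retained clinical representative plus the single
top-ranked radiomic feature (`n_radiomic_selected` is configurable).

## Enrichment

The risk model is a multivariable Cox fit on target-arm training
patients only; its linear predictor, centred at the training covariate
means, is the risk score (an all-reference-level patient with mean
continuous values scores ≈ 0; downstream inclusion sets are invariant to
this affine centring). Thresholds are linear-interpolation percentiles
(1..97) of the pooled training-cohort scores; a patient with score ≥
threshold is included (include-above; the mirrored direction is
supported). At each threshold the included subset is compared between
arms by log-rank and by a univariable Cox fit on the arm indicator
(experimental = 1). The chosen threshold must have p < α **and** HR < 1
— significance alone without a benefit direction does not qualify — and
among qualifying points the largest inclusion fraction wins. The chosen
threshold value is then applied verbatim to the test cohort; nothing
computed on test data can influence the model or the threshold, and the
sweep applies no multiplicity correction across its 97 points (the
resulting optimism is quantified by the null simulations instead of
corrected away).

## Radiomic features

Extraction operates on an intensity grid, boolean ROI mask and voxel
spacing. Grey levels use fixed-bin-number discretization (default 32
bins) over the in-mask intensity range; a constant region maps to a
single level. Texture matrices aggregate the 13 unique 3D directions
into one merged matrix before statistics; GLSZM zones are 26-connected
components of equal level; NGTDM uses the 26-neighbourhood. Runs are
maximal and broken by out-of-mask voxels, so each in-mask voxel is
covered exactly 13 times by the run-length matrix — an invariant the
suite checks, along with exact equality of GLRLM/GLSZM/GLCM counts
against brute-force enumerators on random grids. Shape features come
from a marching-cubes mesh of the zero-padded mask (spacing-aware); a
single-voxel mask keeps its conventional mesh surface rather than
erroring, while texture features require ≥ 2 in-mask voxels and raise
otherwise. The peritumoral ring is the shell within a Euclidean
distance (default 2 mm, spacing-aware) of the mask, excluding the mask;
its 16 features are first-order statistics with a `peri_` prefix.
Optional isotropic resampling (trilinear intensities, nearest-neighbour
mask) can precede extraction; it is off by default because the synthetic
volumes are already isotropic. The registry holds 88 named features; the
full feature list of any given clinical platform is not reproduced —
the named subset plus configurable classes is the contract.

## Feature filters

Spatial stability is probed by recomputing all features after one-voxel
6-connected erosion and dilation of each lesion's ROI and taking, per
feature, the minimum Lin concordance correlation
`CCC = 2·cov(x,y) / (var x + var y + (mean x − mean y)²)` across
perturbations (population moments by default, sample moments
switchable). A feature is excluded iff min-CCC < 0.5, strictly; lesions
whose erosion empties the mask are skipped with a log entry; a CCC
undefined because both value sequences are constant leaves the feature
retained with a warning. Volume redundancy then drops features with
|Pearson r| > 0.8 (strict) against volume, always retaining volume
itself. Every run reports the accounting identity
`n_total = n_unstable + n_volume_redundant + n_retained`, and both
filters are idempotent.

## Synthetic cohort

The generator's defaults are the study conditions: 296 patients split
70:30 (train size = round(0.7·n), simple random, no stratification),
1:1 randomization independent of covariates, 164 standardized features
of which ten blocks of six share a latent factor at within-block
correlation 0.7, histology as a four-level multinomial dominated by
Leiomyosarcoma (~40%, the reference level; small levels are topped up so
every level is populated at n ≥ 50), binary ever/never smoking (45%
ever), grade and prior radiotherapy as extra categoricals, and age ~
N(57, 15²) clipped to 18–90. Survival uses a Weibull baseline (shape
1.2, scale 24.5 months, median ≈ 18 months — the register of metastatic
soft-tissue-sarcoma trial cohorts) sampled by inverse CDF with
arm-specific planted log-linear effects, and administrative censoring at
a 36-month horizon minus a uniform 18-month accrual offset (≈ 33%
censored; the empirical fraction tracks the quadrature-computed nominal
value within 10%). Planted effects are the instrument for
treatment-differential structure: `beta_dox` acts on control-arm hazards
and `beta_doxevo` on experimental-arm hazards, per SD of the feature.

Optional voxel mode draws one ellipsoidal lesion per patient (radius
fraction 0.25–0.45 of a 20–24³ grid) filled with a Gaussian random field
whose smoothing length (`texture_scale_mm`, log-normal around 2 mm) sets
its heterogeneity: finer scales give shorter grey-level runs and higher
SRE, and Spearman correlation between scale and extracted SRE is
reliably negative at the default lesion size. What the generator does
*not* emulate: CT physics and scanner artifacts, multi-lesion patients,
informative dropout, covariate-dependent randomization, and real
radiomic marginals (features are Gaussian; Cox inference is invariant to
monotone marginal transforms, but absolute feature values carry no
physical meaning). Passing tests therefore demonstrate the statistical
machinery and its operating characteristics under the assumed structure,
not performance on real trial imaging.

## Operating characteristics and problem sizes

The simulation checks in the suite and in `scripts/acceptance.py` use:
planted-recovery (β = 0.5/SD in the control arm, n = 300, 164 features)
over 100 trials — the planted feature's correlation block tops the
radiomic ranking in ~85–90% of trials; null trials (no planted effect,
200 trials) — a radiomic feature passes the differential criteria in
~3–9%, consistent with BH's family-wise behaviour under the global null;
enrichment sims (β = 0.6, n = 300, 50 trials) — the sweep's arm-HR trend
over thresholds is negative in essentially all trials, the frozen
threshold yields a benefit-direction test-cohort HR (< 1) in ~75–80%,
and the included-vs-excluded survival contrast is significant within the
control arm (~90%) but rarely within the experimental arm (~10%), the
asymmetry that identifies the score as a control-therapy prognosticator
rather than an experimental-therapy response marker. Single test-cohort
significance at n_test ≈ 90 is uncommon (~10%) and is reported as an
informational quantity, not a requirement.

One caveat is recorded deliberately: the asymptotic log-rank p cannot
match an exact permutation p to within Monte-Carlo error at small n —
the chi-square approximation error (0.005–0.02 at n = 16–30, identical
in other mainstream implementations of the same statistic) dominates the
Monte-Carlo noise of a 100k-permutation oracle. The suite asserts the
strict bound anyway and documents the measured excess rather than
widening the tolerance; the test's calibration is instead established by
its type-I error (0.052 over 2000 null trials at α = 0.05).

## Known limitations

* Clinical covariates with more than two levels participate in
  criterion (ii) through the direction of their largest-magnitude level
  only; a covariate with internally opposing level effects is not
  specially handled.
* The stability screen perturbs ROIs by a single voxel; it is a proxy
  for segmentation variability, not a test–retest repeatability study.
* The PH diagnostic uses the pooled-information approximation of the
  Grambsch–Therneau test; small-sample p-values differ in the third
  decimal from implementations that recompute per-event information.
* No multiplicity control across the 97 sweep thresholds (by design);
  the chosen-threshold optimism under the null is visible in the null
  simulations and should be kept in mind when reading single-trial
  sweep p-values.
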