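# Methods

## The analysis

`dosemine` implements a voxel-based data-mining pipeline linking small
residual patient-setup errors after image-guided radiotherapy (IGRT) to
survival through the dose they deliver to the heart. The chain is:

1. **IGRT protocol simulation** (`setup_errors`). Per-fraction setup errors
   follow the standard decomposition e_f = Σ + δ_f with a systematic
   component Σ ~ N(0, Σ_sd²) drawn once per patient and random components
   δ_f ~ N(0, σ_sd²) i.i.d. per fraction, independently per axis. Imaging
   happens at fractions 1–3 and then weekly ({1,2,3,8,13,18} for a
   20-fraction course at 5 fractions/week); at an imaged fraction an online
   couch correction is applied only if the measured error exceeds the 5 mm
   action threshold (per-axis rule by default; a vector-norm rule is a config
   option). Corrections are assumed perfect and purely online; non-imaged
   fractions keep the full setup error as the residual ("truth" mode), with a
   last-observation-carried-forward estimate available as the clinically
   observable alternative.

2. **Shift-invariant dose accumulation** (`dose_accum`). The delivered dose
   at a fraction is approximated by translating the planned dose against the
   patient: an anatomy point x receives D(x + r_f), where r_f is the residual
   (patient displacement). The accumulated course dose is the equal-weight
   mean over fractions, and Δdose = accumulated − planned, so positive values
   mean more dose was delivered than planned. Interpolation is trilinear with
   zero fill outside the grid; the implementation aggregates the trilinear
   corner weights of all fractions onto the integer-offset lattice first,
   which is algebraically identical to shifting per fraction and summing but
   an order of magnitude faster.

3. **Voxel-wise data-mining** (`ibdm`). Patient maps are resampled to a
   common reference lattice through exactly known affine transforms (see the
   synthetic-cohort design below), blurred with a Gaussian representing
   spatial-normalisation uncertainty, and compared between patients dead vs
   alive at one year. The voxel statistic is the group mean Δdose difference
   (dead − alive) divided by the standard deviation of that difference over
   random label permutations; global inference uses the permutation
   distribution of the maximum |t| (maxT), which controls family-wise error
   and produces a single cohort-level p-value with the add-one estimator
   p = (1 + #{perm max|t| ≥ observed max t}) / (n_perm + 1). The significant
   region is the 26-connected component of {t ≥ 0.8·max t} containing the
   peak voxel.

4. **Survival modelling** (`survival`). Mean Δdose and mean planned dose over
   the mined region are extracted per patient and joined with the clinical
   table. Variable selection uses elastic-net penalized Cox regression with
   equal ridge and lasso weight (l1_ratio 0.5) on standardized covariates;
   the penalty is chosen by minimum cross-validated partial-likelihood
   deviance (Breslow ties), computed by scoring held-out folds with the
   hand-written partial likelihood. The final model is an unpenalized Cox fit
   of the two dose terms plus the selected clinical factors, with ECOG-PS
   expanded against reference level 0. The octile analysis re-fits that model
   inside planned-region-dose octiles (empirical k/8 quantiles, linear
   interpolation; the lowest three octiles merged to span a comparable dose
   range); the dose threshold estimate is the lower bound of the lowest
   stratum in which the Δdose term reaches p < 0.05. A cut-point validation
   compares Kaplan–Meier curves and the univariable hazard ratio across the
   threshold.

## The synthetic cohort

No suitable public cohort carries per-fraction setup errors, dose grids and
survival together, so the pipeline ships a fully synthetic cohort generator
(`cohort_sim`) that reproduces the statistical structure the analysis
assumes and plants a known ground truth to recover.

**Anatomy** is parametric: an ellipsoidal body (semi-axes 110 × 90 × 85 mm),
an ellipsoidal heart (35 × 30 × 30 mm) offset inferior-left, and a spherical
tumour whose radius follows from a log-normal GTV volume (median 30 cm³) and
whose centre sits in either lung at a randomised offset from the heart
(lateral 10–60 mm with random side, AP ±25 mm, SI −35 to +55 mm). A fixed
sub-ellipsoid at the heart base (semi-axes 26 × 20 × 16 mm, the scale of the
aortic root plus proximal coronary arteries) is the planted dose-sensitive
region; it is identical in reference coordinates for every patient. Each
patient's frame is the reference frame translated by a uniform ±8 mm offset,
so spatial normalisation is an exactly invertible translation — the
registration step of a real study replaced by a known transform, with a QA
rule (heart-centre deviation vs tolerance) standing in for visual rejection
of failed registrations.

**Planned dose** is a superposition of five coplanar Gaussian-profile beams
intersecting at the tumour (gantry angles 72° apart, per-beam jitter ±30°,
whole arrangement rotated uniformly per patient, per-beam out-of-plane tilt
±20°), with profile width σ = 0.7·r_GTV + 6 mm, attenuated to 2% outside the
body, and normalised so the mean GTV dose equals the 55 Gy prescription.
Per-patient beam geometry matters: it decorrelates, across patients, the
dose-gradient directions at voxels far from the planted region, which is
what lets the voxel-wise analysis localise the planted signal rather than
the shared beam corridors. With these defaults the cohort's planned mean
dose to the sensitive region spans ~0–50 Gy with median ~13 Gy (populating
all octiles), and the per-patient mean region Δdose spans roughly ±7 Gy with
SD ≈ 2 Gy — the same scale as reported ranges for this quantity in clinical
cohorts of this regimen.

**Survival** is proportional-hazards Weibull (exponential by default,
baseline median 18 months, typical for stage III NSCLC at this prescription)
with linear predictor

    β_Δ · Δdose_region · 1[planned_region ∈ window]
    + β_plan · planned_region + β_age (age − 70) + β_ecog[ECOG]
    + β_gtv (ln GTV − ln 30)

and administrative censoring at 5 years. Default effect sizes are hazard
ratios of 1.216/Gy (region Δdose), 1.013/Gy (planned region dose), 1.013 per
year of age, 1.456 per ln-cm³, and ECOG level effects (1.31, 1.77, 1.49,
3.29 vs level 0) — values of the magnitude reported for multivariable
models in this setting. The Δdose effect is gated to a planned-dose window
(default 16–24 Gy) so the octile analysis has a planted threshold to
recover. Setup-error SDs default to 3.5 mm per axis — population-scale
setup errors are realistic here because only 6 of 20 fractions are imaged,
so most fractions carry the full uncorrected error.

Patients censored before one year have indeterminate one-year status and
are excluded from the data-mining grouping (they still enter the survival
models); this avoids contaminating the two outcome groups with unknown
labels.

## Seed policy

One master seed drives everything. Per-patient substreams are
`SeedSequence([master_seed, patient_index, stage])` with stage codes for
covariates, anatomy, setup errors, survival and beam geometry; the
permutation stream is `SeedSequence([master_seed, 1000001])`. Any stage can
be re-run in isolation and full reruns are bit-identical.

## Validation experiments and problem sizes

The test suite validates the chain end-to-end at sizes chosen for a single
desktop CPU:

- **Oracle equivalence**: integer-voxel shifts against a brute-force voxel
  loop (exact); fractional shifts of linear fields (exact in the interior);
  accumulation against direct per-fraction summation (≤1e−6 Gy in float64).
- **Exact permutation oracle**: 4 patients, 2×2×1 maps, all 6 label splits
  enumerated.
- **Type-I calibration**: 50 replicate null cohorts (β_Δ = 0, n = 120,
  200 permutations); the rate of global p ≤ 0.05 must fall in the exact
  binomial 95% interval around 0.05.
- **Region recovery**: 20 replicate cohorts (n = 300, planted HR 1.25/Gy
  applied to every patient, i.e. the gate opened — with the gated default
  only ~15–20% of patients carry the effect and the voxel-level signal,
  corr ≈ 0.035, is undetectable at desk scale; the gated configuration is
  probed by the threshold experiment instead). The 80%-of-max-t region must
  reach Dice ≥ 0.3 against the planted mask in ≥ 16 of 20 replicates.
- **Cox recovery**: 95% CI coverage of a true HR 2.0 over 100 replicates,
  and a 6-subject fit against grid-search partial-likelihood maximisation.
- **Threshold recovery**: 20 replicate gated cohorts (n = 600); all
  significant octile strata must overlap the planted 16–24 Gy window, with
  at least one significant, in ≥ 14 of 20 replicates. The per-stratum 5%
  false-positive rate makes this bound intrinsically stochastic
  (≈0.95⁴ ≈ 0.81 per replicate is the design ceiling).

What passing these shows — and does not show. The generator produces rigid
anatomy, analytic beams, exactly known transforms, exponential survival and
exchangeable labels under the null. Passing demonstrates the estimators are
correctly implemented and calibrated under the model's own assumptions. It
does not demonstrate robustness to deformable anatomy, registration error
beyond a Gaussian blur, dose-calculation error, respiratory or cardiac
motion, informative censoring, or non-proportional hazards — all absent
from the generator by design.

## Numerical choices

- Trilinear interpolation everywhere; out-of-grid dose sampled as 0 Gy
  (grids cover the body with margin, so this matters only at edges).
- Δdose sign: accumulated − planned (positive = delivered higher).
- Permutation SD uses ddof = 1; voxels with zero permutation SD are masked.
- Analysis mask: reference body voxels with valid mapped values in ≥ 90% of
  QA-passed patients; rare invalid voxels inside the mask contribute 0 Gy.
- maxT is the signed maximum of t (dead − alive); the permutation reference
  distribution uses max |t|.
- Octile quantiles: linear interpolation of order statistics. Per-stratum
  Cox fits require n ≥ 30 and ≥ 10 events, otherwise the stratum is flagged,
  not dropped; covariates constant within a stratum are removed from that
  stratum's model.
- Cox fits retry once with a 0.01 ridge penalty on convergence failure
  (near-separation in sparse indicator columns); indicator columns with
  fewer than 5 members are dropped from the pipeline's final model.
- The pipeline's validation cut-point is the octile threshold estimate when
  it splits the cohort, otherwise the median planned region dose.

## Known limitations

- The beam model has no depth dose, heterogeneity or scatter; dose realism
  is limited to smooth profiles, penumbra-scale gradients and a body
  boundary.
- The shift-invariance approximation is exact in this generator by
  construction (the ground truth is defined through the same analytic dose
  function evaluated at shifted points), so the experiments cannot detect
  its physical error; published full-recalculation comparisons place that
  error below 0.1 Gy mean in the heart for 5 mm-scale shifts.
- Rotational setup errors, intra-fraction drift and anatomical change over
  the course are not simulated.
- The elastic-net penalty is selected by CV-deviance minimum; the 1-SE rule
  would select sparser models and is not implemented.
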