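# Methods

## Composition scoring

A CT slice is a 2D grid of Hounsfield units with physical pixel spacing
(mm). A paraspinal compartment is supplied either as a binary mask
congruent with the grid or as a closed polygon in pixel coordinates;
polygons are rasterized by the pixel-center rule (a pixel belongs to the
ROI iff its center lies inside under the even-odd rule, with a center
exactly on the boundary counted inside). Self-intersecting polygons are
rejected, naming the crossing edge pair.

Threshold bands are inclusive on integer-stored HU: fatty muscle
[−30, 29], lean muscle [30, 100]. For float-valued grids the fatty band
becomes [−30, 30) so the two bands stay contiguous; the integer phrasing
of the bounds presumes CT's integer storage convention. Pixels outside
both bands remain in the *compartment* area but are excluded from the
*muscle* area — the traced fascia routinely encloses vessels and bone
flecks, which is why compartment area exceeds muscle area.

FFMF uses lean area over muscle area (lean + fatty), not over the
compartment. Mean muscle attenuation averages HU over muscle pixels
only; averaging over the whole compartment is available via
`compute_composition(..., attenuation_over="compartment")` because the
field is not uniform on this convention. Left/right compartments must be
disjoint; the combined result pools the raw class counts, so combined
counts are exactly the per-side sums.

Published group-mean tables are internally consistent with this
definition only approximately, because a mean of per-patient ratios is
not the ratio of mean areas; with typical group means (muscle ≈ 34 cm²,
fatty ≈ 13.5 or 6.8 cm²) the two routes differ by under one percentage
point. The package computes per-subject FFMF and never averages areas
first.

## Phantom generator

The phantom is deliberately minimal: an air background, a soft-tissue
disc, a high-HU "vertebral" ellipse, and two elliptical compartments.
It is a *control instrument* for the thresholding step, not an anatomic
simulation — no scanner physics (beam hardening, kernels), no realistic
anatomy, no multi-slice geometry.

Class planting is exact: with n compartment pixels and target fat
fraction f, exactly round(n·f) pixels become fatty (largest-remainder
rounding), positions shuffled by the seeded generator. Class HU values
are drawn from normals truncated so that the *stored integer* value
stays inside the class band (lean 50 ± 8 HU on [30, 100]; fatty 0 ± 10
HU on [−30, 29]). Truncation is what makes the planted labels exact
ground truth: with zero added noise and blur, threshold classification
reproduces the planted counts bit-exactly at any compartment size.
Degradation is then controlled by two explicit knobs applied after
class assignment — additive Gaussian noise in HU, and a Gaussian PSF
(FWHM in mm) emulating partial volume. Output HU is rounded to int16,
mirroring clinical storage; classification operates on stored values.

Noise bias is asymmetric by construction: the lean mean sits ~20 HU
above the 30 HU cut while the fatty mean sits ~30 HU below it, so
symmetric noise leaks lean→fatty faster than the reverse (at 10 HU
noise, ≈5.5% vs ≈1.8% analytically). Measured FFMF is therefore biased
*low* by up to ~4.5 percentage points at low fat fractions — the
property suite asserts this true behaviour rather than a symmetric
bound. Blur biases FFMF *high*: fatty pixels embedded in a lean
majority are averaged over the 30 HU cut. Passing tests therefore show
correctness of the counting chain and the stated noise responses; they
do not show robustness to real-scanner effects.

## Cohort simulator

One row per patient with FFMF, demographics, risk factors, labs,
treatment variables and ordinal scores. Defaults describe a 66-patient
anterior-circulation thrombectomy cohort: FFMF ~ N(71, 12²) truncated
to [0, 100]; age 76 ± 13; 45% female; risk-factor prevalences around
typical registry values (AF 50%, hypertension 85%, diabetes 21%, ...).

The scientifically meaningful link is FFMF → 90-day mRS, generated from
the proportional-odds model via its latent representation: z = β·(FFMF −
mean) + logistic noise, mRS = #{k : z > c_k}. Cutpoints are expressed on
the *centred* predictor scale (defaults (−2.20, −1.39, −0.75, −0.24,
0.49, 1.39), giving mean mRS ≈ 3.5–3.8 at the cohort-mean FFMF), so the
marginal outcome mix stays realistic for any β including the null, and
a refit on raw FFMF recovers the same β with the centring absorbed into
its cutpoints. The default β = −0.08 per FFMF percentage point is an
adjustable effect size with no published anchor; it was chosen to give
group differences of roughly the magnitude seen in small thrombectomy
cohorts (about one mRS point across the median split).

Admission and discharge scores are monotone noisy transforms of the
same latent z — with deliberately large noise at admission and small
noise at discharge, encoding the premise that muscle quality predicts
*recovery* rather than initial severity. Pre-stroke mRS is independent
(right-skewed gamma, rounded). Atrial fibrillation depends on FFMF
through logit P(AF) = a + γ·FFMF with default γ = −0.10; the intercept
a is solved numerically so the marginal prevalence matches its target
regardless of γ, and γ = −0.10 reproduces an AF split of roughly
70%/30% across the FFMF median. All other covariates are independent
draws, so under a null configuration (β = 0, γ = 0) every comparison-
table p-value is a true null draw — the basis of the type-I-error and
calibration tests.

What the simulator does not emulate: correlated comorbidities, missing
data, measurement error in clinical scores, site effects, or any real
association structure beyond the two planted links.

## Statistics

- **Median split:** cutoff = sample median; "low" iff value < cutoff
  (ties at the median go to "high"). An all-identical sample is a
  degenerate split and an error.
- **Routing:** Shapiro-Wilk in each group; pooled-variance Student t
  only if both p > α, otherwise Mann-Whitney U. The pooled (not Welch)
  form is used deliberately for the unqualified "unpaired t test"
  convention.
- **Mann-Whitney:** exact enumeration p when n1+n2 ≤ 12 without ties;
  otherwise normal approximation with tie-corrected variance and
  continuity correction. Reported U is min(U1, U2).
- **2×2 tests:** the "cell count > 5" rule is interpreted as the
  minimum *expected* count (standard practice); χ² is Pearson without
  continuity correction, Fisher is two-sided by summing tables no more
  probable than the observed one. Odds ratios use Haldane's 0.5
  correction only when a zero cell occurs.
- **Power:** two-sided two-sample t power from the noncentral t with
  noncentrality d·√(n/2) and 2n−2 df. At d = 0.7, n = 33/group,
  α = 0.05 this is 0.7997 — "80% power" at two-digit precision.
- No multiple-testing correction is applied; the routing log records
  the number of tests performed. Percentages render with
  round-half-away-from-zero to integers.

These primitives are thin, validated wrappers over scipy; the test
suite checks them against independent enumeration and closed-form
oracles (all rank assignments for Mann-Whitney, all hypergeometric
tables for Fisher, the closed 2×2 χ² form, a 20,000-replicate Monte
Carlo for power).

## Proportional-odds model

Parameterization logit P(Y ≤ k|x) = c_k − βx, so β > 0 (OR > 1) means
higher predictor → worse outcome; the direction convention is printed in
every summary. Fitting maximizes the cumulative-logit likelihood with
BFGS on (β, c_0, log-increments) — which enforces cutpoint monotonicity
— then Newton refinement on the original parameters to gradient norm
< 1e-8 (cap 200 iterations), with the observed information obtained by
central differences of the analytic score. Inference is Wald (SE, 95%
CI, two-sided p), matching the odds-ratio/CI/p presentation convention.
Intercept-only log-likelihood comes from the closed-form multinomial
MLE, so the LR statistic is available without a second fit.

Degenerate inputs are handled explicitly: unobserved intermediate
outcome levels are collapsed (with a diagnostic note) to keep the
information matrix nonsingular; non-convergence, a singular information
matrix, or extreme coefficient/SE magnitudes (heuristic for complete or
quasi-complete separation) are flagged in `diagnostics` rather than
silently returned. The test suite cross-checks β, its SE and the
log-likelihood against an independent ordinal-regression implementation
(statsmodels) to 1e-4 on random datasets, and verifies 93–97% empirical
coverage of the 95% Wald CI at the 66-patient study size.

A note on published single-study values for this kind of model: an odds
ratio of 1.025 with 95% CI (0.917, 1.150) and p = 0.026 is internally
inconsistent under Wald inference (a CI containing 1 cannot accompany
p < 0.05), and an OR > 1 per FFMF point contradicts the group-level
finding that higher FFMF predicts better outcomes. The package
implements the standard model and makes no attempt to reproduce such a
triplet.

## Pipeline & reproducibility

`run_pipeline` chains simulate → (optionally) compose → analyze → fit →
power. With `use_phantom_ffmf=True` each patient's sampled FFMF is
replaced by the value *measured* on a phantom planted with that
patient's fat fraction, exercising the image path inside the cohort
flow. All randomness derives from the config seed; a fixed config
reproduces every output byte-for-byte. Every output file carries a
`.provenance.json` sidecar with the config hash, seed and package
version.

## Problem sizes

The validation suite uses phantom grids of 112–128 px (compartments of
~280–560 pixels; 112 px makes the compartment count a multiple of 20 so
probed fat fractions are exactly representable in counts), cohorts of
66 (the study size) for calibration/coverage replicates, 5,000 for
point recovery, and 10⁴–10⁵ draws for marginal and GOF checks — sizes
at which the Monte-Carlo error is well below each asserted tolerance.

## Known limitations

- Single-slice, single-modality scoring; no volumetric composition, no
  cross-scanner calibration, no automatic fascia segmentation.
- Wald inference is first-order; at n = 66 its CI coverage is verified
  empirically but small-sample likelihood-ratio intervals would be
  preferable near separation.
- The simulated cohort is a validation instrument: its passing tests
  establish correctness of the statistical machinery, not clinical
  properties of FFMF in real patients.
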