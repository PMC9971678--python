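# ffmf — CT-derived cervical fat-free muscle fraction

`ffmf` implements an opportunistic CT body-composition analysis for
stroke research: scoring the **fat-free muscle fraction (FFMF)** of the
cervical paraspinal muscles on a single axial CT slice, and relating it
to ordinal stroke outcomes (mRS, NIHSS) in a cohort. It is aimed at
researchers who want a tested, reproducible reference implementation of
the whole analysis chain — image scoring, group statistics, ordinal
regression — exercised end-to-end on synthetic phantoms and simulated
cohorts, so no patient data is required to validate any stage.

## The method

**Composition scoring.** Within a traced paraspinal compartment on a
C3/4-level axial slice, every pixel is classified by its Hounsfield-unit
value: *fatty muscle* in [−30, 29] HU, *lean muscle* in [30, 100] HU;
pixels outside both bands (vessels, calcifications) stay in the
compartment area but not in the muscle area. With `A_lean` and `A_fatty`
the class areas (pixel count × pixel area),

```
FFMF = 100 · A_lean / (A_lean + A_fatty)   [%]
```

and mean muscle attenuation is the HU average over muscle pixels.

**Cohort analysis.** The cohort is split at the median FFMF (`low` iff
FFMF < median). Continuous variables are compared by an unpaired pooled
t test or Mann-Whitney U, routed by Shapiro-Wilk normality in both
groups; dichotomous variables by Pearson χ² (minimum expected cell
count > 5) or Fisher's exact test; FFMF–outcome association by Spearman
correlation; study power by the noncentral-t power of the two-sample t
test at Cohen's d.

**Ordinal outcome model.** A univariable proportional-odds model

```
logit P(mRS ≤ k | x) = c_k − β·x ,   k = 0..5
```

is fitted by maximum likelihood (BFGS on an order-preserving
reparameterization, Newton-refined to gradient norm < 1e-8), with Wald
SE/CI/p from the observed information. `exp(β)` is the cumulative odds
ratio of a worse 90-day mRS per FFMF percentage point.

**Synthetic data.** `generate_phantom` builds neck-like slices with two
elliptical paraspinal compartments whose fatty/lean pixel counts are
planted *exactly* (largest-remainder rounding), plus optional Gaussian
noise and partial-volume blur — so the scoring chain can be validated
against exact ground truth. `generate_cohort` simulates a thrombectomy
cohort whose 90-day mRS is drawn from the proportional-odds link above,
with atrial fibrillation negatively linked to FFMF.

## Worked example

```python
from ffmf import (PhantomSpec, generate_phantom, compose_slice,
                  CohortSpec, generate_cohort, ProportionalOdds)

# score a noiseless phantom with 35% planted fat fraction
ct, left, right, truth = generate_phantom(
    PhantomSpec(target_fat_fraction=0.35, noise_sd_hu=0.0, seed=11))
combined, l, r = compose_slice(ct, left, right)
print(f"true FFMF {truth.ffmf_percent():.2f}%  measured {combined.ffmf_percent:.2f}%")
# -> true FFMF 64.95%  measured 64.95%   (exact recovery without noise)

# fit the outcome model on a simulated cohort
cohort, _ = generate_cohort(CohortSpec(n_patients=3000, beta_mrs_per_ffmf=-0.08, seed=1))
res = ProportionalOdds.from_dataframe(cohort, y="mrs_90d", x="ffmf_percent").fit()
print(res.summary())
```

The summary prints, among other lines,

```
beta      = -0.07880  (SE 0.00313)
OR        = 0.9242  [95% CI 0.9186, 0.9299]
```

i.e. the fit recovers the simulated β = −0.08: each FFMF percentage
point multiplies the odds of a worse 90-day mRS by ≈0.92 in this cohort.

The same steps are available from a shell:

```sh
ffmf simulate-cohort --n 66 --seed 3 --out cohort.csv
ffmf analyze --cohort cohort.csv --group-by ffmf-median --out table1.csv
ffmf ordinal-fit --cohort cohort.csv --out fit.json
ffmf power --d 0.7 --n-per-group 33
ffmf run-all --seed 4 --out-dir out/
```

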