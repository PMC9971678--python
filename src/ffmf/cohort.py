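"""Simulated stroke cohorts with outcomes linked to muscle quality.

Generates a cohort table shaped like a thrombectomy-stroke registry: one
row per patient with fat-free muscle fraction (FFMF, %), demographics,
vascular risk factors, admission labs, treatment variables and ordinal
outcome scores (NIHSS 0-42, mRS 0-6 pre-stroke / on admission / at
discharge / at 90 days).

The generative link that matters scientifically is FFMF -> 90-day mRS:
the 90-day score is drawn from a cumulative-logit (proportional-odds)
model, logit P(mRS <= k) = c_k - beta * FFMF, so a negative beta means
better muscle quality predicts better outcome.  Discharge and admission
scores are monotone noisy transforms of the same latent severity (with
much more noise at admission, emulating a biomarker that predicts
recovery rather than initial severity).  Atrial fibrillation is linked
to FFMF through its own log-odds slope, reproducing the kind of
risk-factor imbalance a median split can surface; all other risk factors
are independent Bernoulli draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import expit, logit

__all__ = ["CohortSpec", "generate_cohort", "sample_ordinal", "COLUMN_DICTIONARY"]

# column dictionary for the generated CSV (shipped with every cohort)
COLUMN_DICTIONARY: dict[str, str] = {
    "patient_id": "sequential identifier",
    "ffmf_percent": "fat-free muscle fraction at C3/4, percent [0, 100]",
    "age_years": "age in years",
    "sex": "F or M",
    "bmi": "body-mass index, kg/m^2",
    "nihss_admission": "NIHSS on admission, integer 0-42",
    "nihss_discharge": "NIHSS at discharge, integer 0-42",
    "mrs_prestroke": "pre-stroke mRS, integer 0-6",
    "mrs_admission": "mRS on admission, integer 0-6",
    "mrs_discharge": "mRS at discharge, integer 0-6",
    "mrs_90d": "mRS 90 days after stroke, integer 0-6",
    "atrial_fibrillation": "0/1",
    "hypertension": "0/1",
    "diabetes": "0/1",
    "smoking": "0/1",
    "hypercholesterolemia": "0/1",
    "prior_infarction": "previous cerebral infarction, 0/1",
    "valvular_disease": "valvular heart disease, 0/1",
    "coronary_disease": "coronary heart disease, 0/1",
    "thrombolysis": "systemic thrombolysis before thrombectomy, 0/1",
    "tici": "post-thrombectomy TICI grade: 0, 1, 2a, 2b, 3",
    "systolic_bp": "systolic blood pressure at admission, mmHg",
    "diastolic_bp": "diastolic blood pressure at admission, mmHg",
    "platelet_count": "platelet count, G/L",
    "creatinine": "serum creatinine, mg/dl",
    "hba1c": "HbA1c, percent",
    "ldl": "low-density lipoprotein, mg/dl",
    "hdl": "high-density lipoprotein, mg/dl",
}

_TICI_LEVELS = ("0", "1", "2a", "2b", "3")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the simulated cohort.

    Defaults mirror a 66-patient anterior-circulation thrombectomy
    cohort: FFMF ~ 71 +/- 12 %, AF in about half the patients and
    negatively linked to FFMF, and a 90-day mRS distribution centred
    around 3-4.  ``beta_mrs_per_ffmf`` is the log cumulative odds of a
    higher 90-day mRS per FFMF percentage point (negative: higher FFMF
    -> better outcome); it has no published anchor and is an adjustable
    effect size.
    """

    n_patients: int = 66
    ffmf_mean: float = 71.0
    ffmf_sd: float = 12.0
    beta_mrs_per_ffmf: float = -0.08
    # cutpoints of the 90-day mRS cumulative-logit model, on the *centred*
    # predictor scale: logit P(mRS <= k) = c_k - beta * (FFMF - ffmf_mean).
    # Defaults are the marginal logits of a distribution with mean mRS ~3.7
    # at the cohort-mean FFMF, so the outcome mix stays realistic for any
    # choice of beta (including the null beta = 0)
    cutpoints: tuple[float, ...] = (-2.20, -1.39, -0.75, -0.24, 0.49, 1.39)
    # admission/discharge transforms of the shared latent severity
    nihss_admission_mean: float = 13.0
    nihss_admission_sd: float = 4.5
    nihss_discharge_gain: float = 3.2   # NIHSS points per latent-severity unit
    severity_noise_sd: dict = field(
        default_factory=lambda: {"admission": 6.0, "discharge": 1.0}
    )
    # risk-factor prevalences (marginal)
    prevalence: dict = field(
        default_factory=lambda: {
            "atrial_fibrillation": 0.50,
            "hypertension": 0.85,
            "diabetes": 0.21,
            "smoking": 0.18,
            "hypercholesterolemia": 0.61,
            "prior_infarction": 0.12,
            "valvular_disease": 0.50,
            "coronary_disease": 0.14,
            "thrombolysis": 0.48,
        }
    )
    af_ffmf_association: float = -0.10  # log-odds of AF per FFMF point
    female_fraction: float = 0.45
    age_mean: float = 76.0
    age_sd: float = 13.0
    bmi_mean: float = 26.0
    bmi_sd: float = 4.5
    tici_probs: tuple[float, ...] = (0.10, 0.01, 0.01, 0.32, 0.56)
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        c = np.asarray(self.cutpoints, dtype=float)
        if len(c) != 6 or not np.all(np.diff(c) > 0):
            raise ValueError("cutpoints must be 6 strictly increasing reals")
        for name, p in self.prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"prevalence of {name} must lie in [0, 1]")
        if not (self.ffmf_sd > 0 and self.age_sd > 0 and self.bmi_sd > 0):
            raise ValueError("scale parameters must be > 0")
        if abs(sum(self.tici_probs) - 1.0) > 1e-9 or len(self.tici_probs) != 5:
            raise ValueError("tici_probs must be 5 probabilities summing to 1")


def sample_ordinal(eta, cutpoints, rng: np.random.Generator | int) -> np.ndarray:
    """Draw ordinal levels 0..K from the cumulative-logit model.

    ``P(level <= k) = expit(c_k - eta)`` for each of the K cutpoints; the
    draw uses the latent-variable representation level = #{k : z > c_k}
    with z = eta + logistic noise, which realizes exactly those category
    probabilities.

    Parameters
    ----------
    eta : scalar or array of latent linear predictors.
    cutpoints : strictly increasing sequence of K reals (levels 0..K).
    rng : numpy Generator or a seed.
    """
    c = np.asarray(cutpoints, dtype=float)
    if not np.all(np.diff(c) > 0):
        raise ValueError("cutpoints must be strictly increasing")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    z = eta + rng.logistic(0.0, 1.0, size=eta.shape)
    return (z[:, None] > c[None, :]).sum(axis=1)


def ordinal_category_probs(eta: float, cutpoints) -> np.ndarray:
    """Closed-form category probabilities of the cumulative-logit model."""
    c = np.asarray(cutpoints, dtype=float)
    cum = np.concatenate([[0.0], expit(c - eta), [1.0]])
    return np.diff(cum)


def _af_intercept(gamma: float, ffmf: np.ndarray, prevalence: float) -> float:
    """Intercept a such that mean(expit(a + gamma * ffmf)) == prevalence."""
    if prevalence in (0.0, 1.0):
        return -np.inf if prevalence == 0.0 else np.inf
    def f(a):
        return expit(a + gamma * ffmf).mean() - prevalence
    lo, hi = -50.0 - abs(gamma) * 100, 50.0 + abs(gamma) * 100
    return float(optimize.brentq(f, lo, hi))


def _score_from_latent(latent, gain, center, noise, rng, hi):
    """Monotone noisy integer transform of the latent severity onto a
    clinical score range [0, hi]."""
    raw = center + gain * latent + rng.normal(0.0, noise, size=latent.shape)
    return np.clip(np.rint(raw), 0, hi).astype(int)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort table and return it with the true parameters.

    Returns ``(cohort, truth)`` where ``truth`` records every generative
    parameter actually used (including the AF intercept solved for the
    requested marginal prevalence), for provenance sidecars and for
    parameter-recovery experiments.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    c = np.asarray(spec.cutpoints, dtype=float)

    # FFMF: normal truncated to [0, 100]
    a, b = (0.0 - spec.ffmf_mean) / spec.ffmf_sd, (100.0 - spec.ffmf_mean) / spec.ffmf_sd
    ffmf = sps.truncnorm.rvs(
        a, b, loc=spec.ffmf_mean, scale=spec.ffmf_sd, size=n, random_state=rng
    )

    # 90-day mRS from the proportional-odds link, via a shared latent
    # severity; the predictor is centred so the cutpoints stay on a
    # marginal scale (a refit on raw FFMF recovers the same beta, with
    # the centring absorbed into its cutpoints)
    eta = spec.beta_mrs_per_ffmf * (ffmf - spec.ffmf_mean)
    z = eta + rng.logistic(0.0, 1.0, size=n)          # latent severity
    mrs_90d = (z[:, None] > c[None, :]).sum(axis=1)

    # admission & discharge scores: monotone noisy transforms of z
    z_std = (z - eta.mean()) / np.sqrt(np.var(eta) + np.pi**2 / 3.0)
    nihss_adm = _score_from_latent(
        z_std, spec.nihss_admission_sd * 0.6, spec.nihss_admission_mean,
        spec.severity_noise_sd["admission"], rng, 42,
    )
    nihss_dis = _score_from_latent(
        z_std, spec.nihss_discharge_gain, 7.0,
        spec.severity_noise_sd["discharge"], rng, 42,
    )
    mrs_adm = _score_from_latent(z_std, 0.4, 4.3, 0.8, rng, 6)
    mrs_dis = _score_from_latent(z_std, 1.2, 3.4, 0.9, rng, 6)
    mrs_pre = np.clip(
        np.rint(rng.gamma(shape=0.8, scale=1.2, size=n)), 0, 6
    ).astype(int)

    # atrial fibrillation linked to FFMF; other risk factors independent
    af_a = _af_intercept(
        spec.af_ffmf_association, ffmf, spec.prevalence["atrial_fibrillation"]
    )
    af = (rng.uniform(size=n) < expit(af_a + spec.af_ffmf_association * ffmf)).astype(int)
    risk = {}
    for name, p in spec.prevalence.items():
        if name == "atrial_fibrillation":
            continue
        risk[name] = (rng.uniform(size=n) < p).astype(int)

    sex = np.where(rng.uniform(size=n) < spec.female_fraction, "F", "M")
    age = np.clip(rng.normal(spec.age_mean, spec.age_sd, size=n), 18, 105)
    bmi = np.clip(rng.normal(spec.bmi_mean, spec.bmi_sd, size=n), 14, 60)
    tici = rng.choice(_TICI_LEVELS, size=n, p=spec.tici_probs)

    cohort = pd.DataFrame(
        {
            "patient_id": np.arange(1, n + 1),
            "ffmf_percent": ffmf,
            "age_years": age,
            "sex": sex,
            "bmi": bmi,
            "nihss_admission": nihss_adm,
            "nihss_discharge": nihss_dis,
            "mrs_prestroke": mrs_pre,
            "mrs_admission": mrs_adm,
            "mrs_discharge": mrs_dis,
            "mrs_90d": mrs_90d,
            "atrial_fibrillation": af,
            **risk,
            "tici": tici,
            "systolic_bp": np.clip(rng.normal(155, 22, size=n), 70, 260),
            "diastolic_bp": np.clip(rng.normal(85, 13, size=n), 40, 160),
            "platelet_count": np.clip(rng.normal(230, 90, size=n), 10, 900),
            "creatinine": np.clip(rng.normal(1.06, 0.7, size=n), 0.3, 9.0),
            "hba1c": np.clip(rng.normal(6.1, 1.2, size=n), 4.0, 15.0),
            "ldl": np.clip(rng.normal(118, 38, size=n), 20, 350),
            "hdl": np.clip(rng.normal(50, 17, size=n), 10, 150),
        }
    )
    truth = {
        "spec": asdict(spec),
        "beta_mrs_per_ffmf": spec.beta_mrs_per_ffmf,
        "cutpoints": list(spec.cutpoints),
        "af_intercept": af_a,
        "af_ffmf_association": spec.af_ffmf_association,
    }
    return cohort, truth
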