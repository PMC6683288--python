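"""Synthetic cohort generation with the statistical structure the analyses assume.

One row per subject, with frailty group, demographics, intracranial volume,
log-scale WMH volumes, shape features, lacunar-infarct indicator, perfusion
summaries and raw frailty measurements.  The generative model mirrors the
fitted models downstream:

* ln(100 · V_total) is linear in group indicators, age, sex and ICV with
  Gaussian residuals, so the covariate-adjusted OLS fit is correctly
  specified and its Wald intervals attain nominal coverage;
* the lacunar indicator follows a logistic model in the group indicators
  (no covariate effects by default, so conditional and marginal odds ratios
  coincide);
* shape features are group-conditional normals, optionally coupled to
  ln-volume through ``volume_shape_coupling`` so that volume-adjusted
  secondary models attenuate the group effect;
* raw frailty measurements (TUG, grip, weight loss, questionnaire flags)
  are generated consistent with each subject's component flags, so scoring
  them reproduces the subject's group exactly.

Default group sizes, age/sex distributions, effect sizes and feature
means emulate an elective-surgery cohort of adults aged 65+ with frail /
pre-frail / non-frail subgroups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import frailty as fr

#: column dictionary for the generated table
COLUMN_DICTIONARY = {
    "subject_id": "unique subject identifier",
    "group": "frailty category: non_frail | pre_frail | frail",
    "age": "years (truncated normal, >= 65)",
    "sex": "1 = female, 0 = male",
    "icv_ml": "intracranial volume (ml)",
    "vol_total_ml": "total WMH volume (ml)",
    "vol_pvconf_ml": "periventricular + confluent WMH volume (ml)",
    "vol_deep_ml": "deep WMH volume (ml)",
    "solidity_pvconf": "mean solidity of pv/confluent WMH",
    "convexity_pvconf": "mean convexity of pv/confluent WMH",
    "concavity_index_pvconf": "mean concavity index of pv/confluent WMH",
    "fractal_dimension_pvconf": "mean fractal dimension of pv/confluent WMH",
    "eccentricity_deep": "mean eccentricity of deep WMH",
    "fractal_dimension_deep": "mean fractal dimension of deep WMH",
    "lacunar_present": "1 = lacunar infarct present (visual rating input)",
    "gm_cbf": "gray-matter CBF (ml/100g/min); NaN unless qc=cbf_contrast",
    "deepwm_cbf": "deep-WM CBF (ml/100g/min); NaN unless qc=cbf_contrast",
    "spatial_cov": "spatial CoV in GM; NaN if qc=no_contrast",
    "qc_label": "ASL visual QC: cbf_contrast | vascular_contrast | no_contrast",
    "slowness|weakness|weight_loss|exhaustion|mobility": "component flags (0/1)",
    "n_components": "number of positive frailty components",
    "tug_seconds": "timed up-and-go (s)",
    "grip_kg": "maximal hand grip (kg)",
    "bmi": "body-mass index (kg/m^2)",
    "weight_loss_kg": "self-reported 1-yr weight loss (kg)",
    "weight_loss_pct": "self-reported 1-yr weight loss (%)",
    "exhaustion_flag": "questionnaire exhaustion (0/1)",
    "mobility_difficulty_flag": "questionnaire mobility difficulty (0/1)",
    "hads_depression": "HADS depression subscale (integer)",
    "mmse": "mini-mental state exam (24-30)",
    "asa": "ASA physical-status class (1-3)",
    "diabetes|hypertension|hyperlipidemia|smoker|tia_cva": "vascular risk flags",
}

_GROUPS = (fr.FRAIL, fr.PRE_FRAIL, fr.NON_FRAIL)


@dataclass
class CohortSpec:
    """Generative parameters; defaults emulate the study conditions."""

    n_frail: int = 30
    n_prefrail: int = 85
    n_nonfrail: int = 55
    # (mean, sd) of age per group, truncated at 65
    age_mean_sd_per_group: dict = field(
        default_factory=lambda: {
            fr.FRAIL: (74.0, 5.0),
            fr.PRE_FRAIL: (72.0, 5.0),
            fr.NON_FRAIL: (70.0, 4.0),
        }
    )
    female_prob_per_group: dict = field(
        default_factory=lambda: {
            fr.FRAIL: 0.53,
            fr.PRE_FRAIL: 0.28,
            fr.NON_FRAIL: 0.22,
        }
    )
    # ln(100 * V_total) linear model
    beta_frail: float = 0.69
    beta_prefrail: float = 0.43
    beta_age: float = 0.04  # per year
    beta_sex: float = 0.10  # female vs male
    beta_icv: float = 0.001  # per ml
    beta_slowness: float = 0.0  # component-level effect, exploratory analyses
    intercept_ln_vol: float = 6.0  # at age 70, male, ICV 1450 ml
    sigma_resid: float = 1.2
    # concavity index / fractal dimension group effects (pv/confluent WMH)
    shape_effect_prefrail_ci: float = 0.04
    shape_effect_frail_ci: float = 0.05
    shape_effect_prefrail_fd: float = 0.07
    shape_effect_frail_fd: float = 0.08
    volume_shape_coupling: float = 0.0  # d(feature)/d(ln-volume), optional knob
    # lacunar infarcts
    lacunar_baseline_prob: float = 0.22
    lacunar_or_frail: float = 1.25
    lacunar_or_prefrail: float = 1.35
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_frail, self.n_prefrail, self.n_nonfrail) < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0 <= self.lacunar_baseline_prob <= 1:
            raise ValueError("lacunar_baseline_prob must lie in [0, 1]")
        for g, p in self.female_prob_per_group.items():
            if not 0 <= p <= 1:
                raise ValueError(f"female probability for {g} must lie in [0, 1]")
        if self.sigma_resid <= 0:
            raise ValueError("sigma_resid must be positive")


# per-group nuisance distributions (means, sds) for emulated features
_BMI = {fr.FRAIL: (29.0, 6.0), fr.PRE_FRAIL: (27.0, 4.0), fr.NON_FRAIL: (26.0, 4.0)}
_GM_CBF = {fr.FRAIL: (97.0, 24.0), fr.PRE_FRAIL: (82.0, 17.0), fr.NON_FRAIL: (85.0, 20.0)}
_DWM_CBF = {fr.FRAIL: (28.0, 8.0), fr.PRE_FRAIL: (26.0, 10.0), fr.NON_FRAIL: (25.0, 8.0)}
_SCOV = {fr.FRAIL: (2.51, 0.70), fr.PRE_FRAIL: (2.52, 0.61), fr.NON_FRAIL: (2.36, 0.56)}
_SOLIDITY = {fr.FRAIL: 0.29, fr.PRE_FRAIL: 0.31, fr.NON_FRAIL: 0.36}
_CONVEXITY = {fr.FRAIL: 1.15, fr.PRE_FRAIL: 1.14, fr.NON_FRAIL: 1.17}
_CI_BASE = 1.08
_FD_BASE = 1.57
_ECC_DEEP = 0.58
_FD_DEEP = {fr.FRAIL: 1.83, fr.PRE_FRAIL: 1.81, fr.NON_FRAIL: 1.88}
_DEPRESSIVE_P = {fr.FRAIL: 0.13, fr.PRE_FRAIL: 0.07, fr.NON_FRAIL: 0.02}
_ASA_P = {
    fr.FRAIL: (0.03, 0.50, 0.47),
    fr.PRE_FRAIL: (0.09, 0.53, 0.38),
    fr.NON_FRAIL: (0.20, 0.58, 0.22),
}
_RISK_P = {
    "diabetes": {fr.FRAIL: 0.27, fr.PRE_FRAIL: 0.14, fr.NON_FRAIL: 0.11},
    "hypertension": {fr.FRAIL: 0.57, fr.PRE_FRAIL: 0.53, fr.NON_FRAIL: 0.40},
    "hyperlipidemia": {fr.FRAIL: 0.40, fr.PRE_FRAIL: 0.42, fr.NON_FRAIL: 0.29},
    "smoker": {fr.FRAIL: 0.10, fr.PRE_FRAIL: 0.10, fr.NON_FRAIL: 0.05},
    "tia_cva": {fr.FRAIL: 0.10, fr.PRE_FRAIL: 0.06, fr.NON_FRAIL: 0.02},
}
# component prevalence weights within pre-frail and frail subjects
_COMPONENT_W = {
    fr.PRE_FRAIL: np.array([0.21, 0.32, 0.22, 0.26, 0.40]),
    fr.FRAIL: np.array([0.77, 0.60, 0.37, 0.80, 0.90]),
}
_QC_P = (0.53, 0.39, 0.08)  # cbf_contrast, vascular_contrast, no_contrast


def _truncnorm_ge(rng, mean, sd, lower, size):
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(
        a, np.inf, loc=mean, scale=sd, size=size, random_state=rng
    )


def _component_flags(rng: np.random.Generator, group: str) -> np.ndarray:
    """Boolean vector over the five components consistent with the group."""
    flags = np.zeros(5, bool)
    if group == fr.NON_FRAIL:
        return flags
    if group == fr.PRE_FRAIL:
        k = rng.integers(1, 3)
    else:
        k = rng.choice([3, 4, 5], p=[0.6, 0.3, 0.1])
    w = _COMPONENT_W[group]
    # weighted sampling without replacement via Gumbel keys
    keys = np.log(w) + rng.gumbel(size=5)
    flags[np.argsort(keys)[::-1][:k]] = True
    return flags


def generate_cohort(spec: CohortSpec | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort table (deterministic given ``spec.seed``)."""
    spec = spec or CohortSpec()
    rng = np.random.default_rng(spec.seed)
    cutoffs = fr.load_grip_cutoffs()

    rows = []
    sid = 0
    for group, n in (
        (fr.FRAIL, spec.n_frail),
        (fr.PRE_FRAIL, spec.n_prefrail),
        (fr.NON_FRAIL, spec.n_nonfrail),
    ):
        if n == 0:
            continue
        mean, sd = spec.age_mean_sd_per_group[group]
        ages = _truncnorm_ge(rng, mean, sd, 65.0, n)
        females = rng.random(n) < spec.female_prob_per_group[group]
        for i in range(n):
            sid += 1
            age = float(ages[i])
            female = bool(females[i])
            icv = float(rng.normal(1350.0 if female else 1500.0, 110.0))

            flags = _component_flags(rng, group)
            slow, weak, wloss, exh, mob = flags

            lnv = (
                spec.intercept_ln_vol
                + (spec.beta_frail if group == fr.FRAIL else 0.0)
                + (spec.beta_prefrail if group == fr.PRE_FRAIL else 0.0)
                + spec.beta_age * (age - 70.0)
                + spec.beta_sex * float(female)
                + spec.beta_icv * (icv - 1450.0)
                + spec.beta_slowness * float(slow)
                + rng.normal(0.0, spec.sigma_resid)
            )
            vol_total = float(np.exp(lnv) / 100.0)
            deep_frac = float(rng.beta(1.5, 28.0))
            vol_deep = vol_total * deep_frac
            vol_pvconf = vol_total - vol_deep

            coupling = spec.volume_shape_coupling * (lnv - spec.intercept_ln_vol)
            ci = (
                _CI_BASE
                + (spec.shape_effect_frail_ci if group == fr.FRAIL else 0.0)
                + (spec.shape_effect_prefrail_ci if group == fr.PRE_FRAIL else 0.0)
                + coupling
                + rng.normal(0.0, 0.10)
            )
            fd_pv = (
                _FD_BASE
                + (spec.shape_effect_frail_fd if group == fr.FRAIL else 0.0)
                + (spec.shape_effect_prefrail_fd if group == fr.PRE_FRAIL else 0.0)
                + coupling
                + rng.normal(0.0, 0.22)
            )
            solidity = float(np.clip(rng.normal(_SOLIDITY[group], 0.20), 0.01, 1.0))
            convexity = float(rng.normal(_CONVEXITY[group], 0.17))
            ecc = float(np.clip(rng.normal(_ECC_DEEP, 0.12), 0.0, 0.99))
            fd_deep = float(rng.normal(_FD_DEEP[group], 0.25))

            logit = np.log(spec.lacunar_baseline_prob / (1 - spec.lacunar_baseline_prob))
            if group == fr.FRAIL:
                logit += np.log(spec.lacunar_or_frail)
            elif group == fr.PRE_FRAIL:
                logit += np.log(spec.lacunar_or_prefrail)
            lacunar = bool(rng.random() < 1.0 / (1.0 + np.exp(-logit)))

            qc = rng.choice(
                [
                    "cbf_contrast",
                    "vascular_contrast",
                    "no_contrast",
                ],
                p=_QC_P,
            )
            gm_cbf = dwm_cbf = scov = np.nan
            if qc != "no_contrast":
                scov = float(
                    max(0.05, rng.normal(*_SCOV[group]))
                )
            if qc == "cbf_contrast":
                gm_cbf = float(max(5.0, rng.normal(*_GM_CBF[group])))
                dwm_cbf = float(max(2.0, rng.normal(*_DWM_CBF[group])))

            # raw frailty measurements consistent with the component flags
            bmi = float(max(16.0, rng.normal(*_BMI[group])))
            tug = float(10.5 + rng.exponential(2.0)) if slow else float(rng.uniform(6.0, 9.8))
            cutoff = fr.grip_cutoff_kg("female" if female else "male", bmi, cutoffs)
            grip = (
                float(max(2.0, cutoff - rng.uniform(1.0, 6.0)))
                if weak
                else float(cutoff + rng.uniform(1.0, 10.0))
            )
            wl_kg = float(rng.uniform(3.0, 8.0)) if wloss else float(rng.uniform(0.0, 2.5))
            wl_pct = float(rng.uniform(5.0, 10.0)) if wloss else float(rng.uniform(0.0, 4.5))

            depressive = rng.random() < _DEPRESSIVE_P[group]
            hads = int(8 + rng.poisson(2.0)) if depressive else int(rng.integers(0, 8))
            mmse = int(np.clip(round(rng.normal(28.7, 1.3)), 24, 30))
            asa = int(rng.choice([1, 2, 3], p=_ASA_P[group]))

            row = {
                "subject_id": f"S{sid:04d}",
                "group": group,
                "age": age,
                "sex": int(female),
                "icv_ml": icv,
                "vol_total_ml": vol_total,
                "vol_pvconf_ml": vol_pvconf,
                "vol_deep_ml": vol_deep,
                "solidity_pvconf": solidity,
                "convexity_pvconf": convexity,
                "concavity_index_pvconf": float(ci),
                "fractal_dimension_pvconf": float(fd_pv),
                "eccentricity_deep": ecc,
                "fractal_dimension_deep": fd_deep,
                "lacunar_present": int(lacunar),
                "gm_cbf": gm_cbf,
                "deepwm_cbf": dwm_cbf,
                "spatial_cov": scov,
                "qc_label": qc,
                "slowness": int(slow),
                "weakness": int(weak),
                "weight_loss": int(wloss),
                "exhaustion": int(exh),
                "mobility": int(mob),
                "n_components": int(flags.sum()),
                "tug_seconds": tug,
                "grip_kg": grip,
                "bmi": bmi,
                "weight_loss_kg": wl_kg,
                "weight_loss_pct": wl_pct,
                "exhaustion_flag": int(exh),
                "mobility_difficulty_flag": int(mob),
                "hads_depression": hads,
                "mmse": mmse,
                "asa": asa,
            }
            for name, probs in _RISK_P.items():
                row[name] = int(rng.random() < probs[group])
            rows.append(row)

    return pd.DataFrame(rows)
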