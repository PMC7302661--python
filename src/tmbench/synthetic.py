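"""Synthetic multi-hospital cohort generator.

Emulates the structure of a large integrated hospital system: ~40+ acute-care
hospitals with annual volumes spanning an order of magnitude, strong
between-hospital case-mix variation (surgical share, emergency-department
admission share, psychiatric/substance-abuse share, demographics, comorbidity
burden, admission labs), and a known per-hospital quality effect on the
log-odds of 30-day mortality.  The quality effect is the estimand every
downstream benchmarking stage tries to recover, which gives the whole
pipeline a parameter-recovery test surface.

Case-mix heterogeneity is controlled by a single scale ``heterogeneity``:
every hospital-level deviation (mean-age shift, logit-scale prevalence
shifts, diagnosis-mix tilts, lab-mean shifts) is proportional to it, so 0
yields identical case-mix blocks at every hospital and larger values emulate
progressively more divergent hospitals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    COMORBIDITIES,
    COMORBIDITY_COLS,
    DX_CATEGORIES,
    LABS,
    RACE_ETHNICITY,
    CohortTable,
)

# ---------------------------------------------------------------------------
# population-level ("system at large") case-mix constants

AGE_MEAN, AGE_SD = 66.0, 12.0
P_FEMALE = 0.07
RACE_PROBS = {"white": 0.66, "black": 0.20, "hispanic": 0.08, "other": 0.06}
DX_PROBS = {
    "cardiovascular": 0.20,
    "psychiatric_substance": 0.18,
    "infection": 0.12,
    "gastrointestinal": 0.10,
    "respiratory": 0.12,
    "genitourinary_renal": 0.08,
    "other": 0.20,
}
P_SURGICAL = 0.07
P_ED = 0.60
P_NURSING = 0.05

#: baseline prevalence of each of the 29 comorbidity indicators
COMORBIDITY_PREV = {
    "chf": 0.16, "arrhythmia": 0.22, "valvular": 0.05, "pulm_circ": 0.04,
    "pvd": 0.10, "htn": 0.55, "paralysis": 0.03, "neuro_other": 0.08,
    "chronic_pulm": 0.25, "dm_uncomplicated": 0.25, "dm_complicated": 0.12,
    "hypothyroid": 0.09, "renal_failure": 0.18, "liver": 0.07,
    "peptic_ulcer": 0.02, "aids": 0.01, "lymphoma": 0.015,
    "mets_cancer": 0.03, "solid_tumor": 0.05, "rheumatoid": 0.03,
    "coagulopathy": 0.05, "obesity": 0.18, "weight_loss": 0.06,
    "fluid_electrolyte": 0.22, "blood_loss_anemia": 0.02,
    "deficiency_anemia": 0.08, "alcohol_abuse": 0.14, "drug_abuse": 0.10,
    "depression": 0.22,
}

#: admission-lab population mean and SD (plausible adult inpatient values)
LAB_PARAMS = {
    "sodium": (139.0, 4.0), "bun": (22.0, 15.0), "gfr": (70.0, 25.0),
    "glucose": (130.0, 55.0), "albumin": (3.7, 0.6), "bilirubin": (0.9, 1.0),
    "wbc": (9.0, 4.0), "hematocrit": (39.0, 6.0), "ph": (7.40, 0.06),
    "paco2": (40.0, 8.0), "pao2": (85.0, 25.0),
}

#: fixed plausible lab correlation structure (all other pairs independent)
_LAB_CORR_PAIRS = {
    ("bun", "gfr"): -0.6,
    ("ph", "paco2"): -0.4,
    ("hematocrit", "albumin"): 0.3,
    ("wbc", "bilirubin"): 0.1,
}

#: mean shifts applied to labs for selected principal-diagnosis categories
_DX_LAB_SHIFTS = {
    "infection": {"wbc": 3.0, "albumin": -0.3},
    "genitourinary_renal": {"bun": 12.0, "gfr": -20.0},
    "respiratory": {"pao2": -12.0, "paco2": 4.0},
}

# hospital-level deviation scales, all multiplied by config.heterogeneity
_H_SCALES = {
    "age_mean": 4.0,          # years, additive
    "female": 0.5,            # logit
    "race": {"white": 0.3, "black": 0.8, "hispanic": 1.5, "other": 0.5},
    "comorbidity": 0.4,       # logit
    "dx": {"cardiovascular": 0.4, "psychiatric_substance": 1.2,
           "infection": 0.4, "gastrointestinal": 0.4, "respiratory": 0.4,
           "genitourinary_renal": 0.4, "other": 0.4},  # log-softmax
    "surgical": 0.9,          # logit
    "ed": 2.0,                # logit
    "nursing": 0.6,           # logit
    "lab": 0.25,              # fraction of the lab SD, additive mean shift
}


def default_outcome_coefficients() -> dict[str, float]:
    """True 30-day-mortality model of the generator (log-odds scale).

    Keys: ``intercept``; ``age_dec`` (per decade above 65); ``sex_M``;
    ``race[level]`` (reference white); ``dx[level]`` (reference
    cardiovascular); the binary admission indicators; ``cm_*`` comorbidities;
    ``lab_*`` per population SD.  Magnitudes are chosen to give a pooled
    mortality around 5% and a risk-model c-statistic near 0.8, typical of
    inpatient 30-day mortality models.
    """
    coef = {
        "intercept": -4.1,
        "age_dec": 0.55,
        "sex_M": 0.10,
        "race[black]": 0.05, "race[hispanic]": -0.05, "race[other]": 0.0,
        "surgical": -0.30,
        "ed_admission": 0.25,
        "nursing_facility": 0.50,
        "dx[psychiatric_substance]": -1.80,
        "dx[infection]": 0.60,
        "dx[respiratory]": 0.35,
        "dx[gastrointestinal]": 0.10,
        "dx[genitourinary_renal]": 0.10,
        "dx[other]": -0.20,
    }
    cm = {c: 0.0 for c in COMORBIDITIES}
    cm.update({
        "mets_cancer": 1.20, "chf": 0.50, "renal_failure": 0.35,
        "liver": 0.50, "weight_loss": 0.50, "coagulopathy": 0.45,
        "fluid_electrolyte": 0.40, "chronic_pulm": 0.25, "paralysis": 0.30,
        "solid_tumor": 0.50, "lymphoma": 0.60, "pulm_circ": 0.25,
        "pvd": 0.15, "arrhythmia": 0.20, "depression": -0.10,
        "obesity": -0.20, "dm_complicated": 0.15, "htn": -0.10,
    })
    coef.update({f"cm_{c}": v for c, v in cm.items()})
    lab = {x: 0.0 for x in LABS}
    lab.update({
        "albumin": -0.50, "bun": 0.35, "wbc": 0.25, "sodium": -0.10,
        "ph": -0.30, "hematocrit": -0.10, "pao2": -0.15, "bilirubin": 0.20,
        "gfr": -0.15, "glucose": 0.05, "paco2": 0.05,
    })
    coef.update({f"lab_{x}": v for x, v in lab.items()})
    return coef


def required_coefficient_keys() -> set[str]:
    keys = {"intercept", "age_dec", "sex_M", "surgical", "ed_admission",
            "nursing_facility"}
    keys |= {f"race[{r}]" for r in RACE_ETHNICITY if r != "white"}
    keys |= {f"dx[{d}]" for d in DX_CATEGORIES if d != "cardiovascular"}
    keys |= {f"cm_{c}" for c in COMORBIDITIES}
    keys |= {f"lab_{x}" for x in LABS}
    return keys


@dataclass
class GeneratorConfig:
    """Settings for :func:`generate_system`.

    Defaults are a scaled-down hospital system: 40 hospitals, annual volumes
    log-uniform on 300–3,000 (mimicking the right-skew of real systems whose
    volumes span a 50-fold range), quality-effect SD 0.3 on the log-odds
    scale (odds-ratio spread ~e^{±0.6} across hospitals).
    """

    n_hospitals: int = 40
    volume_range: tuple[int, int] = (300, 3000)
    heterogeneity: float = 1.0
    quality_sd: float = 0.3
    quality_effects: tuple[float, ...] | None = None  # fixed per-hospital overrides
    coefficients: dict[str, float] | None = None
    n_psych_dominant: int = 0
    psych_dominant_prob: float = 0.95
    transfer_rate: float = 0.005
    transplant_rate: float = 0.0003
    missing_dx_rate: float = 0.0002
    fine_per_category: int = 8
    zipf_exponent: float = 1.6
    n_tiers: int = 5

    def validate(self) -> None:
        if self.n_hospitals < 2:
            raise ValueError("n_hospitals must be >= 2")
        lo, hi = self.volume_range
        if lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("volume_range must be positive with hi >= lo")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity scale must be >= 0")
        if self.quality_sd < 0:
            raise ValueError("quality_sd must be >= 0")
        for name in ("transfer_rate", "transplant_rate", "missing_dx_rate",
                     "psych_dominant_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0 <= self.n_psych_dominant <= self.n_hospitals:
            raise ValueError("n_psych_dominant out of range")
        if (self.quality_effects is not None
                and len(self.quality_effects) != self.n_hospitals):
            raise ValueError("quality_effects must list one value per hospital")


@dataclass
class HospitalProfile:
    """True data-generating parameters of one hospital."""

    hospital_id: str
    tier: int
    volume: int
    casemix: dict
    quality_effect: float

    def __post_init__(self):
        if self.volume < 1:
            raise ValueError("volume must be >= 1")
        if not 1 <= self.tier <= 5:
            raise ValueError("tier must be in 1..5")
        for key in ("race_probs", "dx_probs"):
            probs = np.array(list(self.casemix[key].values()))
            if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError(f"{key} must be a probability vector")
        for key in ("p_female", "p_surgical", "p_ed", "p_nursing"):
            if not 0.0 <= self.casemix[key] <= 1.0:
                raise ValueError(f"{key} must be in [0, 1]")
        for p in self.casemix["comorbidity_prev"].values():
            if not 0.0 <= p <= 1.0:
                raise ValueError("comorbidity prevalence must be in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "hospital_id": self.hospital_id, "tier": self.tier,
            "volume": self.volume, "quality_effect": self.quality_effect,
            "casemix": self.casemix,
        }


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _softmax_probs(base: dict[str, float], shifts: dict[str, float]) -> dict[str, float]:
    keys = list(base)
    z = np.array([np.log(base[k]) + shifts.get(k, 0.0) for k in keys])
    z -= z.max()
    p = np.exp(z)
    p /= p.sum()
    return dict(zip(keys, p))


def _draw_profile(i: int, tier: int, volume: int, h: float, quality: float,
                  rng: np.random.Generator, psych_dominant: bool,
                  psych_prob: float) -> HospitalProfile:
    s = _H_SCALES
    casemix = {
        "age_mean": AGE_MEAN + rng.normal(0.0, s["age_mean"] * h),
        "age_sd": AGE_SD,
        "p_female": float(_expit(_logit(P_FEMALE) + rng.normal(0.0, s["female"] * h))),
        "race_probs": _softmax_probs(
            RACE_PROBS,
            {k: rng.normal(0.0, s["race"][k] * h) for k in RACE_PROBS}),
        "comorbidity_prev": {
            c: float(_expit(_logit(p) + rng.normal(0.0, s["comorbidity"] * h)))
            for c, p in COMORBIDITY_PREV.items()},
        "dx_probs": _softmax_probs(
            DX_PROBS, {k: rng.normal(0.0, s["dx"][k] * h) for k in DX_PROBS}),
        "p_surgical": float(_expit(_logit(P_SURGICAL) + rng.normal(0.0, s["surgical"] * h))),
        "p_ed": float(_expit(_logit(P_ED) + rng.normal(0.0, s["ed"] * h))),
        "p_nursing": float(_expit(_logit(P_NURSING) + rng.normal(0.0, s["nursing"] * h))),
        "lab_shifts": {
            x: float(rng.normal(0.0, s["lab"] * h * LAB_PARAMS[x][1]))
            for x in LABS},
    }
    if psych_dominant:
        # force a psychiatric/substance-dominant case-mix at this hospital
        dx = dict(casemix["dx_probs"])
        rest = 1.0 - dx["psychiatric_substance"]
        scale = (1.0 - psych_prob) / rest if rest > 0 else 0.0
        dx = {k: (psych_prob if k == "psychiatric_substance" else v * scale)
              for k, v in dx.items()}
        casemix["dx_probs"] = dx
    return HospitalProfile(
        hospital_id=f"H{i + 1:03d}", tier=tier, volume=volume,
        casemix=casemix, quality_effect=quality,
    )


def _fine_dx_weights(config: GeneratorConfig) -> np.ndarray:
    k = np.arange(1, config.fine_per_category + 1, dtype=float)
    w = k ** (-config.zipf_exponent)
    return w / w.sum()


def _lab_covariance() -> np.ndarray:
    sd = np.array([LAB_PARAMS[x][1] for x in LABS])
    corr = np.eye(len(LABS))
    idx = {x: i for i, x in enumerate(LABS)}
    for (a, b), r in _LAB_CORR_PAIRS.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    return corr * np.outer(sd, sd)


def linear_predictor(df: pd.DataFrame, coefficients: dict[str, float]) -> np.ndarray:
    """True-model log-odds of 30-day mortality, excluding quality effects."""
    missing = required_coefficient_keys() - set(coefficients)
    if missing:
        raise ValueError(f"missing outcome-model coefficient(s): {sorted(missing)}")
    c = coefficients
    lp = np.full(len(df), c["intercept"], dtype=float)
    lp += c["age_dec"] * (df["age"].to_numpy(float) - 65.0) / 10.0
    lp += c["sex_M"] * (df["sex"] == "M").to_numpy(float)
    for r in RACE_ETHNICITY:
        if r != "white":
            lp += c[f"race[{r}]"] * (df["race_ethnicity"] == r).to_numpy(float)
    for name in ("surgical", "ed_admission", "nursing_facility"):
        lp += c[name] * df[name].to_numpy(float)
    for d in DX_CATEGORIES:
        if d != "cardiovascular":
            lp += c[f"dx[{d}]"] * (df["dx_category"] == d).to_numpy(float)
    for cm in COMORBIDITIES:
        lp += c[f"cm_{cm}"] * df[f"cm_{cm}"].to_numpy(float)
    for x in LABS:
        mu, sd = LAB_PARAMS[x]
        lp += c[f"lab_{x}"] * (df[f"lab_{x}"].to_numpy(float) - mu) / sd
    return lp


def true_mortality_probability(
    df: pd.DataFrame, coefficients: dict[str, float], quality_effect: float = 0.0
) -> np.ndarray:
    """Per-row true death probability under the generator's outcome model."""
    return _expit(linear_predictor(df, coefficients) + quality_effect)


def simulate_outcome(record, profile: HospitalProfile,
                     coefficients: dict[str, float],
                     rng: np.random.Generator) -> int:
    """Draw one 30-day mortality outcome for a single hospitalization."""
    df = pd.DataFrame([record]) if not isinstance(record, pd.DataFrame) else record
    p = true_mortality_probability(df, coefficients, profile.quality_effect)
    return int(rng.random() < p[0])


def _generate_hospital_rows(profile: HospitalProfile, config: GeneratorConfig,
                            coefficients: dict[str, float],
                            rng: np.random.Generator) -> pd.DataFrame:
    n = profile.volume
    cm = profile.casemix
    cols: dict[str, np.ndarray | list] = {}
    cols["hospital_id"] = [profile.hospital_id] * n
    cols["tier"] = np.full(n, profile.tier, dtype=int)
    cols["age"] = np.clip(rng.normal(cm["age_mean"], cm["age_sd"], n), 18.0, 100.0)
    cols["sex"] = np.where(rng.random(n) < cm["p_female"], "F", "M")
    races = list(cm["race_probs"])
    cols["race_ethnicity"] = rng.choice(races, size=n, p=list(cm["race_probs"].values()))
    for c in COMORBIDITIES:
        cols[f"cm_{c}"] = (rng.random(n) < cm["comorbidity_prev"][c]).astype(int)
    dx_levels = list(cm["dx_probs"])
    dx = rng.choice(dx_levels, size=n, p=list(cm["dx_probs"].values()))
    w = _fine_dx_weights(config)
    fine_idx = rng.choice(len(w), size=n, p=w)
    fine = np.array([f"{d}_{j + 1:02d}" for d, j in zip(dx, fine_idx)], dtype=object)
    missing = rng.random(n) < config.missing_dx_rate
    dx = dx.astype(object)
    dx[missing] = None
    fine[missing] = None
    cols["dx_category"] = dx
    cols["fine_dx_category"] = fine
    cols["surgical"] = (rng.random(n) < cm["p_surgical"]).astype(int)
    cols["ed_admission"] = (rng.random(n) < cm["p_ed"]).astype(int)
    cols["nursing_facility"] = (rng.random(n) < cm["p_nursing"]).astype(int)
    cols["transfer_from_va"] = (rng.random(n) < config.transfer_rate).astype(int)
    cols["organ_transplant"] = (rng.random(n) < config.transplant_rate).astype(int)

    mean = np.array([LAB_PARAMS[x][0] + cm["lab_shifts"][x] for x in LABS])
    labs = rng.multivariate_normal(np.zeros(len(LABS)), _lab_covariance(), size=n)
    labs += mean
    lab_idx = {x: i for i, x in enumerate(LABS)}
    for d, shifts in _DX_LAB_SHIFTS.items():
        mask = np.array([v == d for v in cols["dx_category"]])
        for x, delta in shifts.items():
            labs[mask, lab_idx[x]] += delta
    for i, x in enumerate(LABS):
        cols[f"lab_{x}"] = labs[:, i]

    df = pd.DataFrame(cols)
    # rows with a missing principal diagnosis get reference-category risk
    lp_df = df.copy()
    lp_df["dx_category"] = lp_df["dx_category"].fillna("cardiovascular")
    p = _expit(linear_predictor(lp_df, coefficients) + profile.quality_effect)
    df["died_30d"] = (rng.random(n) < p).astype(int)
    df["predicted_mortality"] = np.nan
    return df


def generate_system(
    config: GeneratorConfig, seed: int
) -> tuple[CohortTable, list[HospitalProfile]]:
    """Generate a full multi-hospital cohort plus the true hospital profiles.

    Deterministic for a fixed ``(config, seed)``: a master stream draws the
    hospital profiles, and each hospital's rows come from its own spawned
    substream, so the table is reproducible even if per-hospital generation
    were parallelized.
    """
    config.validate()
    coefficients = config.coefficients or default_outcome_coefficients()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(config.n_hospitals + 1)
    master = np.random.default_rng(children[0])

    lo, hi = config.volume_range
    volumes = np.exp(master.uniform(np.log(lo), np.log(hi), config.n_hospitals))
    volumes = np.maximum(1, np.round(volumes)).astype(int)
    tiers = master.integers(1, config.n_tiers + 1, size=config.n_hospitals)
    qualities = master.normal(0.0, config.quality_sd, config.n_hospitals)
    if config.quality_sd == 0:
        qualities = np.zeros(config.n_hospitals)
    if config.quality_effects is not None:
        qualities = np.asarray(config.quality_effects, dtype=float)

    profiles = []
    frames = []
    for i in range(config.n_hospitals):
        profile = _draw_profile(
            i, int(tiers[i]), int(volumes[i]), config.heterogeneity,
            float(qualities[i]), master,
            psych_dominant=i < config.n_psych_dominant,
            psych_prob=config.psych_dominant_prob,
        )
        profiles.append(profile)
        h_rng = np.random.default_rng(children[i + 1])
        frames.append(_generate_hospital_rows(profile, config, coefficients, h_rng))
    table = CohortTable(pd.concat(frames, ignore_index=True))
    return table, profiles


def write_truth(profiles: list[HospitalProfile], path) -> None:
    """Persist the true hospital profiles as a JSON sidecar."""
    import json

    with open(path, "w") as fh:
        json.dump([p.to_dict() for p in profiles], fh, indent=1)
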