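"""Synthetic matched case-control studies with known interaction truth.

The generator emulates a 1:1 sex/age-matched hypertension case-control
study. Individuals carry a binary family-history flag, a continuous BMI
(categorized by the standard cutoffs), and correlated anthropometrics;
disease follows a logistic model on the log-odds scale:

    logit P(case) = beta0 + beta_fh*FH + beta_cat(BMI category)
                    + beta_int * FH * 1[BMI abnormal]

Because the additive-interaction target (RERI) lives on the odds-ratio
scale while the generative interaction term lives on the log-odds scale,
``calibrate_interaction`` root-finds ``beta_int`` so the *theoretical*
crude-table RERI equals a requested value. ``theoretical_measures``
computes the implied (OR11, OR10, OR01) exactly by enumerating the eight
(FH x BMI-category) strata with normal-CDF category probabilities — no
Monte Carlo needed. Exposures are generated independently of age and sex
and disease depends only on the exposures, so the matched study's crude
2x4 table estimates exactly these population odds ratios.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

from .errors import MatchingError, ValidationError
from .interaction import compute_measures
from .records import (
    BMI_LOW_CUTOFF,
    BMI_OBESE_CUTOFF,
    BMI_OVERWEIGHT_CUTOFF,
    MAX_PAIR_AGE_GAP,
    StudyDataset,
    SubjectRecord,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_population",
    "sample_matched_study",
    "theoretical_measures",
    "calibrate_interaction",
    "simulate_matched_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Generative-model parameters for a paper-like matched study.

    Defaults mirror the study this package was designed around: 342 pairs
    aged 28-87, control-group-like population margins (BMI ~ N(23.46,
    3.18^2) kg/m^2, family-history prevalence 0.617), and log-odds effects
    equal to the logs of the reported per-category odds ratios. ``beta_int``
    defaults to the value that makes the theoretical RERI equal 5.674 (see
    ``calibrate_interaction``); pass ``beta_int`` explicitly to override.
    """

    n_pairs: int = 342
    seed: int = 0
    p_fh: float = 0.617
    bmi_mean: float = 23.46
    bmi_sd: float = 3.18
    beta0: float = math.log(0.05 / 0.95)  # baseline odds of disease
    beta_fh: float = math.log(4.986)
    beta_low: float = math.log(1.528)
    beta_over: float = math.log(3.333)
    beta_obese: float = math.log(7.312)
    beta_int: float = 0.0
    age_mean: float = 62.0
    age_sd: float = 10.7
    age_range: tuple[float, float] = (28.0, 87.0)
    # anthropometrics: sex-specific height, WC/HC tied to BMI
    height_mean: dict = field(
        default_factory=lambda: {"male": 168.0, "female": 158.5}
    )
    height_sd: float = 6.0
    wc_mean: float = 83.7
    wc_sd: float = 9.96
    hc_mean: float = 92.8
    hc_sd: float = 9.26
    bmi_anthro_corr: float = 0.8
    #: odds-scale FH<->BMI-abnormality association (1 = independent)
    fh_bmi_association: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.p_fh < 1:
            raise ValidationError(f"p_fh must be in (0,1), got {self.p_fh}")
        if self.n_pairs < 1:
            raise ValidationError("n_pairs must be >= 1")
        if self.bmi_sd <= 0 or self.age_sd <= 0:
            raise ValidationError("scale parameters must be positive")

    def category_probabilities(self) -> np.ndarray:
        """P(low, normal, overweight, obese) under the BMI normal model."""
        cuts = np.array([BMI_LOW_CUTOFF, BMI_OVERWEIGHT_CUTOFF, BMI_OBESE_CUTOFF])
        cdf = stats.norm.cdf(cuts, loc=self.bmi_mean, scale=self.bmi_sd)
        return np.array([cdf[0], cdf[1] - cdf[0], cdf[2] - cdf[1], 1 - cdf[2]])

    def category_betas(self) -> np.ndarray:
        """Log-odds effect per BMI category (low, normal, over, obese)."""
        return np.array([self.beta_low, 0.0, self.beta_over, self.beta_obese])

    def to_dict(self) -> dict:
        doc = asdict(self)
        doc["age_range"] = list(self.age_range)
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "SimulationConfig":
        doc = dict(doc)
        target = doc.pop("target_reri", None)
        if "age_range" in doc:
            doc["age_range"] = tuple(doc["age_range"])
        config = cls(**doc)
        if target is not None:
            config = calibrate_interaction(config, target_reri=float(target))
        return config

    def config_hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]

    @classmethod
    def paperlike(cls, seed: int = 0, target_reri: float = 5.674) -> "SimulationConfig":
        """Default study conditions with beta_int calibrated to the target RERI."""
        return calibrate_interaction(cls(seed=seed), target_reri=target_reri)

    @classmethod
    def additive_null(cls, seed: int = 0) -> "SimulationConfig":
        """The global null: no exposure effects and no interaction term.

        All exposure log-odds effects and ``beta_int`` are zero, so the
        theoretical odds-ratio triple is (1, 1, 1) and RERI = 0 exactly.
        The baseline is raised so the marginal disease prevalence stays
        near the paper-like configuration's (about 23%), keeping cohort
        and cell sizes comparable between the null and alternative arms.
        """
        return cls(
            seed=seed,
            beta0=math.log(0.23 / 0.77),
            beta_fh=0.0,
            beta_low=0.0,
            beta_over=0.0,
            beta_obese=0.0,
            beta_int=0.0,
        )

    @classmethod
    def additive_null_with_main_effects(cls, seed: int = 0) -> "SimulationConfig":
        """An exactly additive configuration retaining the BMI effects.

        With ``beta_int = 0`` and the family-history effect removed,
        OR10 = 1 and OR11 = OR01, so RERI = 0 holds exactly while the BMI
        category effects stay at their study values. Delta-method RERI
        intervals are known to be conservative in this skewed regime (see
        the methods note); the symmetric :meth:`additive_null` is the
        configuration used for type-I-error calibration.
        """
        return cls(seed=seed, beta_fh=0.0, beta_int=0.0)


@dataclass(frozen=True)
class SimulationTruth:
    """Theoretical crude-table odds ratios and implied interaction measures."""

    or11: float
    or10: float
    or01: float
    reri: float
    si: float | None
    ap: float
    pap: float | None

    def as_dict(self) -> dict:
        return asdict(self)


def _cell_probabilities(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Joint P(stratum, case) and P(stratum, control) over 8 strata.

    Strata are (FH in {0,1}) x (4 BMI categories); returns two (2, 4)
    arrays. An FH<->BMI association multiplies the joint exposure odds.
    """
    p_cat = config.category_probabilities()
    betas = config.category_betas()
    abnormal = np.array([1.0, 0.0, 1.0, 1.0])
    p_case = np.empty((2, 4))
    p_joint = np.empty((2, 4))
    for fh in (0, 1):
        logit = (
            config.beta0
            + config.beta_fh * fh
            + betas
            + config.beta_int * fh * abnormal
        )
        p_case[fh] = expit(logit)
        p_joint[fh] = (config.p_fh if fh else 1 - config.p_fh) * p_cat
    if config.fh_bmi_association != 1.0:
        # tilt the joint exposure distribution on the odds scale
        tilt = np.where(abnormal[None, :] * np.array([[0], [1]]) > 0,
                        config.fh_bmi_association, 1.0)
        p_joint = p_joint * tilt
        p_joint = p_joint / p_joint.sum()
    return p_joint * p_case, p_joint * (1 - p_case)


def theoretical_measures(config: SimulationConfig) -> SimulationTruth:
    """Exact crude-table odds ratios implied by the generative model.

    The 2x4 cells aggregate the BMI categories into abnormal vs normal;
    each cell OR is the case/control odds of the cell against the
    doubly-unexposed cell, computed from the closed-form joint stratum
    probabilities.
    """
    case, control = _cell_probabilities(config)
    if case.sum() <= 0 or control.sum() <= 0:
        raise ValidationError("configuration implies all-case or all-control population")
    normal = 1  # index of the normal BMI category
    abn = [0, 2, 3]

    def cell(fh: int, abnormal_flag: int) -> tuple[float, float]:
        idx = abn if abnormal_flag else [normal]
        return case[fh, idx].sum(), control[fh, idx].sum()

    ref_case, ref_control = cell(0, 0)
    ref_odds = ref_case / ref_control

    def odds_ratio(fh: int, ab: int) -> float:
        c, k = cell(fh, ab)
        return (c / k) / ref_odds

    or11, or10, or01 = odds_ratio(1, 1), odds_ratio(1, 0), odds_ratio(0, 1)
    m = compute_measures(or11, or10, or01)
    return SimulationTruth(
        or11=or11,
        or10=or10,
        or01=or01,
        reri=m.reri.estimate,
        si=m.si.estimate if m.si else None,
        ap=m.ap.estimate,
        pap=m.pap.estimate if m.pap else None,
    )


def calibrate_interaction(
    config: SimulationConfig, target_reri: float
) -> SimulationConfig:
    """Root-find ``beta_int`` so the theoretical RERI hits ``target_reri``.

    RERI is strictly increasing in ``beta_int``, so Brent's method on a
    bracketing interval converges; the result is returned as a new config.
    """

    def objective(beta_int: float) -> float:
        truth = theoretical_measures(replace(config, beta_int=beta_int))
        return truth.reri - target_reri

    lo, hi = -6.0, 8.0
    if objective(lo) > 0 or objective(hi) < 0:
        raise ValidationError(
            f"target RERI {target_reri} not reachable within beta_int in [{lo}, {hi}]"
        )
    beta_int = optimize.brentq(objective, lo, hi, xtol=1e-10)
    return replace(config, beta_int=float(beta_int))


def simulate_population(
    config: SimulationConfig, n: int, seed: int | None = None
) -> pd.DataFrame:
    """Draw a source cohort of ``n`` individuals with disease status.

    Sex ~ Bernoulli(0.5); age ~ truncated normal on the configured range;
    FH ~ Bernoulli(p_fh); continuous BMI ~ normal; height sex-specific
    normal, weight back-solved from BMI and height; waist and hip drawn
    with the configured BMI correlation; disease ~ Bernoulli(logistic(...)).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    lo, hi = config.age_range
    # truncated normal by inverse-CDF (vectorized, reproducible)
    cdf_lo = stats.norm.cdf((lo - config.age_mean) / config.age_sd)
    cdf_hi = stats.norm.cdf((hi - config.age_mean) / config.age_sd)
    u = rng.uniform(cdf_lo, cdf_hi, size=n)
    age = config.age_mean + config.age_sd * stats.norm.ppf(u)
    fh = rng.random(n) < config.p_fh
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    bmi = np.clip(bmi, 12.0, 60.0)  # physiological plausibility guard
    if config.fh_bmi_association != 1.0:
        # re-draw FH with tilted odds for abnormal-BMI individuals
        abnormal_draw = (bmi < BMI_LOW_CUTOFF) | (bmi >= BMI_OVERWEIGHT_CUTOFF)
        odds = config.p_fh / (1 - config.p_fh) * np.where(
            abnormal_draw, config.fh_bmi_association, 1.0
        )
        fh = rng.random(n) < odds / (1 + odds)
    height = np.where(
        sex == "male",
        rng.normal(config.height_mean["male"], config.height_sd, size=n),
        rng.normal(config.height_mean["female"], config.height_sd, size=n),
    )
    weight = bmi * (height / 100.0) ** 2
    r = config.bmi_anthro_corr
    z_bmi = (bmi - config.bmi_mean) / config.bmi_sd
    wc = (
        config.wc_mean
        + r * config.wc_sd * z_bmi
        + math.sqrt(1 - r**2) * config.wc_sd * rng.standard_normal(n)
    )
    hc = (
        config.hc_mean
        + r * config.hc_sd * z_bmi
        + math.sqrt(1 - r**2) * config.hc_sd * rng.standard_normal(n)
    )
    wc = np.clip(wc, 40.0, None)
    hc = np.clip(hc, 50.0, None)
    category = np.digitize(
        bmi, [BMI_LOW_CUTOFF, BMI_OVERWEIGHT_CUTOFF, BMI_OBESE_CUTOFF]
    )  # 0 low, 1 normal, 2 over, 3 obese
    betas = config.category_betas()
    abnormal = category != 1
    logit = (
        config.beta0
        + config.beta_fh * fh
        + betas[category]
        + config.beta_int * fh * abnormal
    )
    p = expit(logit)
    if p.min() >= 1.0 or p.max() <= 0.0:
        raise ValidationError("configuration implies degenerate disease probability")
    disease = rng.random(n) < p
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "sex": sex,
            "age": np.round(age, 1),
            "height_cm": np.round(height, 1),
            "weight_kg": np.round(weight, 1),
            "waist_cm": np.round(wc, 1),
            "hip_cm": np.round(hc, 1),
            "family_history": fh.astype(int),
            "disease": disease.astype(int),
        }
    )


def sample_matched_study(
    cohort: pd.DataFrame, n_pairs: int, seed: int
) -> StudyDataset:
    """Sample a 1:1 matched study (same sex, age gap <= 5 y) from a cohort.

    Cases are sampled without replacement from the diseased individuals;
    each is matched to one unused non-case of the same sex within the age
    window. Exhausting eligible controls raises :class:`MatchingError`
    reporting the achievable pair count.
    """
    rng = np.random.default_rng(seed)
    cases = cohort[cohort["disease"] == 1]
    controls = cohort[cohort["disease"] == 0]
    if len(cases) < n_pairs:
        raise MatchingError(
            f"cohort holds only {len(cases)} cases, {n_pairs} pairs requested",
            achievable_pairs=len(cases),
        )
    case_order = rng.permutation(len(cases))
    case_cols = {c: cases[c].to_numpy() for c in cases.columns}
    ctrl_cols = {c: controls[c].to_numpy() for c in controls.columns}
    ctrl_sex = ctrl_cols["sex"]
    ctrl_age = ctrl_cols["age"].astype(float)
    used = np.zeros(len(controls), dtype=bool)
    records: list[SubjectRecord] = []

    def make_record(cols, i, pair_id, status):
        return SubjectRecord(
            subject_id=str(cols["subject_id"][i]),
            pair_id=pair_id,
            status=status,
            sex=str(cols["sex"][i]),
            age=float(cols["age"][i]),
            height=float(cols["height_cm"][i]),
            weight=float(cols["weight_kg"][i]),
            waist=float(cols["waist_cm"][i]),
            hip=float(cols["hip_cm"][i]),
            family_history=bool(cols["family_history"][i]),
        )

    achieved = 0
    for ci in case_order:
        if achieved == n_pairs:
            break
        eligible = np.flatnonzero(
            ~used
            & (ctrl_sex == case_cols["sex"][ci])
            & (np.abs(ctrl_age - float(case_cols["age"][ci])) <= MAX_PAIR_AGE_GAP)
        )
        if eligible.size == 0:
            continue
        pick = int(rng.choice(eligible))
        used[pick] = True
        pair_id = f"P{achieved:04d}"
        records.append(make_record(case_cols, ci, pair_id, "case"))
        records.append(make_record(ctrl_cols, pick, pair_id, "control"))
        achieved += 1
    if achieved < n_pairs:
        raise MatchingError(
            f"only {achieved} of {n_pairs} pairs could be matched "
            "(eligible controls exhausted)",
            achievable_pairs=achieved,
        )
    return StudyDataset(records=records)


def simulate_matched_study(
    config: SimulationConfig,
    seed: int | None = None,
    cohort_multiplier: float = 10.0,
) -> StudyDataset:
    """Convenience: draw a cohort and sample a matched study from it.

    The cohort is sized ``cohort_multiplier * n_pairs / expected disease
    rate`` (bounded below at 8x the pair count) so enough cases and matched
    controls exist with high probability.
    """
    seed = config.seed if seed is None else seed
    case_mass, control_mass = _cell_probabilities(config)
    prevalence = case_mass.sum() / (case_mass.sum() + control_mass.sum())
    n = int(max(cohort_multiplier * config.n_pairs / max(prevalence, 0.02),
                8 * config.n_pairs))
    cohort = simulate_population(config, n, seed=seed)
    return sample_matched_study(cohort, config.n_pairs, seed=seed + 1)
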