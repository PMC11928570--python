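"""Conditional-Gaussian engine ("site4802").

Static variables are drawn by simple random generation: sex and autism
diagnosis uniform, parental education from the (0.05, 0.35, 0.25, 0.35)
categorical, IQ from N(100, 15).  Ages are uniform within each wave's
two-year window.  The eight dynamic variables (six brain measures plus
CBCL internalizing and externalizing) are then sampled from a Gaussian
whose mean is a mixed-effects polynomial in age with main effects and
age interactions for the statics (plus a subject-level random
intercept), and whose 8x8 covariance is a documented fixture.

Three variants: (1) the base simulation; (2) base plus cell-level MCAR
attrition (up to 10%) and a perturbed covariance — Gaussian noise
(sd 0.2) added on the correlation scale to every entry with |r| <= 0.8,
followed by eigenvalue-clipping PSD repair; (3) the same perturbed
covariance plus a diagnosis-dependent polynomial effect that raises the
level and steepness of behavioral curves and lowers them for brain
measures.

The CBCL attention-problems score is not part of the 8-variable Gaussian
block; it is completed from its own polynomial mean with independent
noise so every dataset carries the full 19-column dictionary.

Note: taking "uniform probability" for the diagnosis at face value gives
a default autism prevalence of 0.5 — far above the population rate, and
prominently overridable via ``StaticSamplingSpec.autism_probability``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..schema import (
    BRAIN_COLUMNS,
    CBCL_COLUMNS,
    LongTable,
    WaveSchedule,
    assemble_long_table,
    default_data_dictionary,
    sample_timelines,
)
from ..seeding import derive_seeds
from ..missingness import MCARSpec, apply_mcar
from ..stats import cholesky_factor, nearest_psd

__all__ = [
    "StaticSamplingSpec",
    "MixedPolyMean",
    "DynamicCovariance",
    "PerturbationSpec",
    "AutismEffectSpec",
    "Site4802Params",
    "DYNAMIC_VARIABLES",
    "sample_statics",
    "conditional_mean",
    "perturb_covariance",
    "apply_autism_effect",
    "sample_dynamics",
    "generate_site4802_dataset",
]

#: Order of the jointly Gaussian dynamic variables.
DYNAMIC_VARIABLES = BRAIN_COLUMNS + (
    "cbcl_internalizing_raw_score",
    "cbcl_externalizing_raw_score",
)


@dataclass(frozen=True)
class StaticSamplingSpec:
    """Random generation of the static variables."""

    sex_probability: float = 0.5  # P(female)
    autism_probability: float = 0.5  # uniform assignment at face value
    education_probs: tuple[float, ...] = (0.05, 0.35, 0.25, 0.35)
    iq_mean: float = 100.0
    iq_sd: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sex_probability <= 1.0:
            raise ValueError("sex probability must be in [0, 1]")
        if not 0.0 <= self.autism_probability <= 1.0:
            raise ValueError("autism probability must be in [0, 1]")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education probabilities must sum to 1")


@dataclass(frozen=True)
class MixedPolyMean:
    """Mixed-effects polynomial mean for one dynamic variable.

    Linear predictor in centered age ``u = (age_months - 168) / 12``
    (years from the cohort midpoint):

    ``mean = intercept + a1*u + a2*u^2 + a3*u^3 + b_sex*female
    + b_autism*asd + b_edu*education + b_iq*(iq - 100)
    + c_sex*u*female + c_autism*u*asd``

    plus a subject-level random intercept with sd ``subject_sd``.
    """

    intercept: float = 0.0
    age: float = 0.0
    age2: float = 0.0
    age3: float = 0.0
    sex: float = 0.0
    autism: float = 0.0
    education: float = 0.0
    iq: float = 0.0
    age_x_sex: float = 0.0
    age_x_autism: float = 0.0
    subject_sd: float = 0.0


def _default_means() -> dict[str, MixedPolyMean]:
    return {
        "wm_volume": MixedPolyMean(
            4.45e5, 8.0e3, -250.0, sex=-3.0e4, autism=-5.0e3, education=1.5e3,
            iq=300.0, age_x_autism=-300.0, subject_sd=2.2e4,
        ),
        "gm_volume": MixedPolyMean(
            7.00e5, 1.5e3, -600.0, sex=-5.0e4, autism=-6.0e3, education=2.0e3,
            iq=400.0, subject_sd=3.5e4,
        ),
        "hippo_volume": MixedPolyMean(
            3900.0, 35.0, -1.5, sex=-220.0, autism=-60.0, education=20.0,
            iq=3.0, age_x_autism=-6.0, subject_sd=200.0,
        ),
        "amygdala_volume": MixedPolyMean(
            3000.0, 28.0, -1.2, sex=-200.0, autism=-40.0, education=15.0,
            iq=2.0, subject_sd=160.0,
        ),
        "frontal_lobe_gm_thickness": MixedPolyMean(
            2.95, -0.035, 0.0008, autism=-0.02, education=0.008,
            iq=0.0008, subject_sd=0.16,
        ),
        "icv": MixedPolyMean(
            1.43e6, 9.0e3, -350.0, sex=-1.2e5, autism=-8.0e3, education=3.0e3,
            iq=600.0, subject_sd=7.0e4,
        ),
        "cbcl_internalizing_raw_score": MixedPolyMean(
            10.5, 0.25, sex=0.5, autism=2.5, education=-0.3, iq=-0.02,
            age_x_autism=0.08, subject_sd=2.0,
        ),
        "cbcl_externalizing_raw_score": MixedPolyMean(
            13.0, -0.20, sex=-0.8, autism=3.0, education=-0.4, iq=-0.03,
            age_x_autism=0.06, subject_sd=2.5,
        ),
    }


#: Attention problems is completed outside the Gaussian block.
_ATTENTION_MEAN = MixedPolyMean(
    6.5, 0.12, autism=2.0, education=-0.3, iq=-0.03, subject_sd=1.5
)
_ATTENTION_RESIDUAL_SD = 1.5


def _default_covariance() -> np.ndarray:
    p = len(DYNAMIC_VARIABLES)
    idx = {n: i for i, n in enumerate(DYNAMIC_VARIABLES)}
    R = np.eye(p)

    def set_r(a, b, r):
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r

    set_r("wm_volume", "gm_volume", 0.45)
    set_r("wm_volume", "icv", 0.65)
    set_r("gm_volume", "icv", 0.75)
    set_r("hippo_volume", "amygdala_volume", 0.55)
    set_r("hippo_volume", "gm_volume", 0.30)
    set_r("amygdala_volume", "gm_volume", 0.28)
    set_r("hippo_volume", "icv", 0.38)
    set_r("amygdala_volume", "icv", 0.33)
    set_r("frontal_lobe_gm_thickness", "gm_volume", 0.25)
    set_r(
        "cbcl_internalizing_raw_score", "cbcl_externalizing_raw_score", 0.60
    )
    for brain in BRAIN_COLUMNS:
        set_r(brain, "cbcl_internalizing_raw_score", -0.06)
        set_r(brain, "cbcl_externalizing_raw_score", -0.08)
    sds = np.array([1.2e4, 1.5e4, 90.0, 70.0, 0.05, 1.8e4, 3.0, 3.5])
    return R * np.outer(sds, sds)


@dataclass(frozen=True)
class DynamicCovariance:
    """8x8 occasion-level covariance of the dynamic variables."""

    matrix: np.ndarray = field(default_factory=_default_covariance)

    def __post_init__(self) -> None:
        M = self.matrix
        if M.shape != (len(DYNAMIC_VARIABLES),) * 2 or not np.allclose(M, M.T):
            raise ValueError("covariance must be symmetric 8x8")
        w = np.linalg.eigvalsh(M)
        if w.min() < -1e-8 * max(1.0, w.max()):
            raise ValueError("covariance is not PSD")


@dataclass(frozen=True)
class PerturbationSpec:
    """Covariance perturbation + attrition used by variants 2 and 3."""

    noise_sd: float = 0.2
    correlation_threshold: float = 0.8
    attrition_rate: float = 0.08  # up to 10%

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if not 0.0 <= self.correlation_threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if not 0.0 <= self.attrition_rate <= 0.10:
            raise ValueError("attrition rate bounded by 10%")


@dataclass(frozen=True)
class AutismEffectSpec:
    """Multipliers applied to diagnosed subjects' polynomial curves.

    Behavioral measures get level/steepness raised (multipliers >= 1),
    brain measures lowered (multipliers <= 1).
    """

    behavioral_level: float = 1.2
    behavioral_steepness: float = 1.2
    brain_level: float = 0.97
    brain_steepness: float = 0.90

    def __post_init__(self) -> None:
        if self.behavioral_level < 1 or self.behavioral_steepness < 1:
            raise ValueError("behavioral multipliers must be >= 1")
        if self.brain_level > 1 or self.brain_steepness > 1:
            raise ValueError("brain multipliers must be <= 1")


@dataclass(frozen=True)
class Site4802Params:
    statics: StaticSamplingSpec = field(default_factory=StaticSamplingSpec)
    means: dict[str, MixedPolyMean] = field(default_factory=_default_means)
    covariance: DynamicCovariance = field(default_factory=DynamicCovariance)
    perturbation: PerturbationSpec = field(default_factory=PerturbationSpec)
    autism_effect: AutismEffectSpec = field(default_factory=AutismEffectSpec)


def sample_statics(
    spec: StaticSamplingSpec, n: int, rng: np.random.Generator
) -> pd.DataFrame:
    """One row per subject: sex, autism, education, IQ."""
    sex = (rng.uniform(size=n) < spec.sex_probability).astype(np.int64)
    autism = (rng.uniform(size=n) < spec.autism_probability).astype(np.int64)
    probs = np.asarray(spec.education_probs)
    education = rng.choice(np.arange(len(probs)), size=n, p=probs).astype(np.int64)
    iq = rng.normal(spec.iq_mean, spec.iq_sd, size=n)
    return pd.DataFrame(
        {"sex": sex, "autism_diagnosis": autism, "parental_education": education, "iq": iq}
    )


def conditional_mean(
    model: MixedPolyMean,
    age_months: np.ndarray,
    sex: np.ndarray,
    autism: np.ndarray,
    education: np.ndarray,
    iq: np.ndarray,
) -> np.ndarray:
    """Deterministic linear predictor for one dynamic variable."""
    u = (np.asarray(age_months, dtype=float) - 168.0) / 12.0
    female = (np.asarray(sex) == 1).astype(float)
    asd = np.asarray(autism, dtype=float)
    edu = np.asarray(education, dtype=float)
    iqc = np.asarray(iq, dtype=float) - 100.0
    return (
        model.intercept
        + model.age * u
        + model.age2 * u**2
        + model.age3 * u**3
        + model.sex * female
        + model.autism * asd
        + model.education * edu
        + model.iq * iqc
        + model.age_x_sex * u * female
        + model.age_x_autism * u * asd
    )


def perturb_covariance(
    C: np.ndarray, spec: PerturbationSpec, rng: np.random.Generator
) -> np.ndarray:
    """Noise the low-correlation entries on the correlation scale.

    Off-diagonal pairs with |r| <= threshold receive symmetric
    N(0, sd^2) noise added to r; the result is rescaled to covariance and
    repaired to the nearest PSD matrix by eigenvalue clipping.
    """
    C = np.asarray(C, dtype=float)
    if spec.correlation_threshold == 0.0 or spec.noise_sd == 0.0:
        return C.copy()
    d = np.sqrt(np.diag(C))
    R = C / np.outer(d, d)
    p = R.shape[0]
    noise = rng.standard_normal((p, p)) * spec.noise_sd
    noise = np.triu(noise, k=1)
    noise = noise + noise.T
    qualifies = (np.abs(R) <= spec.correlation_threshold) & ~np.eye(p, dtype=bool)
    R_pert = np.where(qualifies, np.clip(R + noise, -1.0, 1.0), R)
    # repair on the correlation scale, then restore the variances
    R_psd = nearest_psd(R_pert)
    return R_psd * np.outer(d, d)


def apply_autism_effect(
    model: MixedPolyMean, effect: AutismEffectSpec, behavioral: bool
) -> MixedPolyMean:
    """Diagnosed-subject model with scaled level and age-steepness."""
    level = effect.behavioral_level if behavioral else effect.brain_level
    steep = effect.behavioral_steepness if behavioral else effect.brain_steepness
    return replace(
        model,
        intercept=model.intercept * level,
        age=model.age * steep,
        age2=model.age2 * steep,
        age3=model.age3 * steep,
    )


def sample_dynamics(
    mean: np.ndarray, C: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian draws around per-row means with shared covariance."""
    mean = np.atleast_2d(np.asarray(mean, dtype=float))
    if np.allclose(C, 0.0):
        return mean.copy()
    L = cholesky_factor(C)
    z = rng.standard_normal(mean.shape)
    return mean + z @ L.T


def generate_site4802_dataset(
    seed: int = 0,
    n_subjects: int = 10_000,
    variant: int = 1,
    params: Site4802Params | None = None,
    schedule: WaveSchedule | None = None,
) -> LongTable:
    """Variant 1 base; 2 adds MCAR attrition + covariance perturbation;
    3 adds the perturbation and the autism polynomial effect."""
    if variant not in (1, 2, 3):
        raise ValueError("variant must be 1, 2 or 3")
    params = params or Site4802Params()
    schedule = schedule or WaveSchedule()
    site = f"site4802_data{variant}"
    rngs = derive_seeds(
        seed,
        [
            f"{site}/statics",
            f"{site}/timeline",
            f"{site}/perturb",
            f"{site}/subject",
            f"{site}/dynamics",
            f"{site}/attention",
            f"{site}/mcar",
        ],
    )
    n, w = n_subjects, schedule.n_waves
    dictionary = default_data_dictionary()

    statics = sample_statics(params.statics, n, rngs[f"{site}/statics"])
    dobs, dates, ages = sample_timelines(rngs[f"{site}/timeline"], n, schedule)

    C = params.covariance.matrix
    if variant in (2, 3):
        C = perturb_covariance(C, params.perturbation, rngs[f"{site}/perturb"])

    sex_r = np.repeat(statics["sex"].to_numpy(), w)
    asd_r = np.repeat(statics["autism_diagnosis"].to_numpy(), w)
    edu_r = np.repeat(statics["parental_education"].to_numpy(), w)
    iq_r = np.repeat(statics["iq"].to_numpy(), w)
    age_r = ages.ravel().astype(float)

    means = np.empty((n * w, len(DYNAMIC_VARIABLES)))
    for j, name in enumerate(DYNAMIC_VARIABLES):
        model = params.means[name]
        mu = conditional_mean(model, age_r, sex_r, asd_r, edu_r, iq_r)
        if variant == 3:
            behavioral = name in CBCL_COLUMNS
            diag_model = apply_autism_effect(model, params.autism_effect, behavioral)
            mu_diag = conditional_mean(diag_model, age_r, sex_r, asd_r, edu_r, iq_r)
            mu = np.where(asd_r == 1, mu_diag, mu)
        means[:, j] = mu

    # subject-level random intercepts, constant over waves
    subj = rngs[f"{site}/subject"].standard_normal((n, len(DYNAMIC_VARIABLES)))
    subj_sd = np.array([params.means[v].subject_sd for v in DYNAMIC_VARIABLES])
    means = means + np.repeat(subj * subj_sd, w, axis=0)

    values = sample_dynamics(means, C, rngs[f"{site}/dynamics"])

    # attention problems: completed outside the Gaussian block
    att_rng = rngs[f"{site}/attention"]
    att_mu = conditional_mean(_ATTENTION_MEAN, age_r, sex_r, asd_r, edu_r, iq_r)
    att_mu = att_mu + np.repeat(
        att_rng.standard_normal(n) * _ATTENTION_MEAN.subject_sd, w
    )
    att = att_mu + att_rng.standard_normal(n * w) * _ATTENTION_RESIDUAL_SD

    subject_ids = np.array([f"{site}_s{i:06d}" for i in range(n)])
    obs = {
        "subject_id": np.repeat(subject_ids, w),
        "wave_number": np.tile(np.arange(1, w + 1), n),
        "brain_behavior_measurement_date": pd.to_datetime(
            [d for row in dates for d in row]
        ),
        "age": ages.ravel(),
        "iq": np.clip(iq_r, *dictionary["iq"].allowed_range),
    }
    for j, name in enumerate(DYNAMIC_VARIABLES):
        lo, hi = dictionary[name].allowed_range
        col = values[:, j]
        if name in CBCL_COLUMNS:
            obs[name] = pd.array(np.clip(np.round(col), lo, hi), dtype="Int64")
        else:
            obs[name] = np.clip(col, lo, hi)
    lo, hi = dictionary["cbcl_attentionproblem_raw_score"].allowed_range
    obs["cbcl_attentionproblem_raw_score"] = pd.array(
        np.clip(np.round(att), lo, hi), dtype="Int64"
    )

    statics_frame = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "site_id": site,
            "dob": pd.to_datetime(dobs),
            "sex": statics["sex"].to_numpy(),
            "parental_education": statics["parental_education"].to_numpy(),
            "autism_diagnosis": statics["autism_diagnosis"].to_numpy(),
        }
    )
    table = assemble_long_table(statics_frame, pd.DataFrame(obs))
    if variant == 2:
        mcar = MCARSpec(
            rate=params.perturbation.attrition_rate,
            columns=DYNAMIC_VARIABLES + ("cbcl_attentionproblem_raw_score",),
        )
        table = apply_mcar(table, mcar, rngs[f"{site}/mcar"])
    return table
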