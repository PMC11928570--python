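"""Cross-sectional + spline engine ("OSA").

A cross-sectional cohort is defined first: sex about 50/50, parental
education over four levels, autism as a sex-specific Bernoulli with
overall prevalence at most 2% and a higher male rate, IQ from a truncated
normal, and the three CBCL subscale scores drawn through a Gaussian copula
against a predefined 3x3 correlation structure with additive sex and
autism shifts.  The cross-section is then expanded into seven waves with
age incremented (with variability) across waves, and the six brain
measures follow sex-specific cubic spline age trajectories with a joint
latent block correlating ICV, hippocampal volume, parental education and
IQ, subject-level random intercepts, occasion residuals, and an
age-dependent hippocampal offset for diagnosed subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

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
from ..stats import (
    check_correlation_matrix,
    cholesky_factor,
    sample_truncated_normal,
)
from ..trajectories import SplineTrajectory, eval_spline

__all__ = [
    "CrossSectionSpec",
    "SplineBrainModel",
    "AutismHippocampalEffect",
    "OSAParams",
    "sample_correlated_cbcl",
    "sample_cross_section",
    "expand_to_waves",
    "eval_brain_measures",
    "generate_osa_dataset",
]


@dataclass(frozen=True)
class CrossSectionSpec:
    """Demographic, cognitive and behavioral marginals for the baseline."""

    male_proportion: float = 0.5
    education_probs: tuple[float, ...] = (0.053, 0.354, 0.253, 0.340)
    autism_prevalence_male: float = 0.025
    autism_prevalence_female: float = 0.008
    iq_mean: float = 100.0
    iq_sd: float = 15.0
    iq_lo: float = 55.0
    iq_hi: float = 145.0
    #: CBCL order (externalizing, internalizing, attention)
    cbcl_correlation: np.ndarray = field(
        default_factory=lambda: np.array(
            [[1.0, 0.60, 0.55], [0.60, 1.0, 0.45], [0.55, 0.45, 1.0]]
        )
    )
    #: right-skewed beta shapes scaled to each subscale range
    cbcl_beta_shapes: tuple[tuple[float, float], ...] = (
        (1.3, 6.0),
        (1.3, 6.5),
        (1.4, 5.0),
    )
    #: additive shifts (male_shift, autism_shift) per subscale
    cbcl_sex_shift: tuple[float, ...] = (1.5, -0.8, 1.0)  # applied to males
    cbcl_autism_shift: tuple[float, ...] = (4.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education probabilities must sum to 1")
        overall = 0.5 * (self.autism_prevalence_male + self.autism_prevalence_female)
        if overall > 0.02 or not (
            self.autism_prevalence_male > self.autism_prevalence_female
        ):
            raise ValueError(
                "autism prevalence must be <= 2% overall with male > female"
            )
        check_correlation_matrix(self.cbcl_correlation, "CBCL correlation")


def _spline(values: tuple[float, ...]) -> SplineTrajectory:
    # five cubic basis coefficients over knots spanning the age support
    return SplineTrajectory(knots=(84.0, 167.5, 251.0), coefficients=values)


def _default_splines() -> dict[str, dict[int, SplineTrajectory]]:
    """Sex-specific cubic spline mean curves (0 = male, 1 = female)."""
    male = {
        "icv": _spline((1.29e6, 1.38e6, 1.47e6, 1.50e6, 1.50e6)),
        "gm_volume": _spline((6.6e5, 7.0e5, 7.3e5, 7.25e5, 7.2e5)),
        "wm_volume": _spline((3.8e5, 4.2e5, 4.6e5, 4.9e5, 5.0e5)),
        "hippo_volume": _spline((3600.0, 3750.0, 3950.0, 4050.0, 4100.0)),
        "amygdala_volume": _spline((2800.0, 2900.0, 3060.0, 3150.0, 3200.0)),
        "frontal_lobe_gm_thickness": _spline((3.22, 3.10, 2.92, 2.80, 2.70)),
    }
    ratios = {
        "icv": 0.91,
        "gm_volume": 0.92,
        "wm_volume": 0.92,
        "hippo_volume": 0.94,
        "amygdala_volume": 0.93,
        "frontal_lobe_gm_thickness": 1.00,
    }
    female = {
        name: SplineTrajectory(
            traj.knots,
            tuple(ratios[name] * c for c in traj.coefficients),
            traj.degree,
        )
        for name, traj in male.items()
    }
    return {name: {0: male[name], 1: female[name]} for name in male}


@dataclass(frozen=True)
class AutismHippocampalEffect:
    """Age-dependent hippocampal offset for diagnosed subjects.

    Defaults to a negative offset that widens through adolescence:
    ``offset(age) = -max_offset * (age - 84) / 167``.
    """

    max_offset: float = 300.0

    def offset(self, age_months) -> np.ndarray:
        a = np.asarray(age_months, dtype=float)
        return -self.max_offset * (a - 84.0) / 167.0


@dataclass(frozen=True)
class SplineBrainModel:
    """Sex-specific spline curves plus coupling and noise components.

    The four-way coupling among ICV, hippocampal volume, parental
    education and IQ is realized as a joint latent Gaussian block: one
    latent vector per subject feeds the education quantile cut, the IQ
    truncated-normal quantile, and the ICV/hippocampus subject intercepts,
    making the stated correlation structure symmetric and auditable.
    """

    splines: dict[str, dict[int, SplineTrajectory]] = field(
        default_factory=_default_splines
    )
    coupling_R: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                # icv, hippo, education, iq
                [1.00, 0.45, 0.15, 0.20],
                [0.45, 1.00, 0.10, 0.15],
                [0.15, 0.10, 1.00, 0.30],
                [0.20, 0.15, 0.30, 1.00],
            ]
        )
    )
    #: subject random-intercept sd per measure
    intercept_sd: dict[str, float] = field(
        default_factory=lambda: {
            "icv": 7.5e4,
            "gm_volume": 4.0e4,
            "wm_volume": 2.4e4,
            "hippo_volume": 210.0,
            "amygdala_volume": 165.0,
            "frontal_lobe_gm_thickness": 0.17,
        }
    )
    residual_sd: dict[str, float] = field(
        default_factory=lambda: {
            "icv": 1.2e4,
            "gm_volume": 1.0e4,
            "wm_volume": 7.0e3,
            "hippo_volume": 65.0,
            "amygdala_volume": 50.0,
            "frontal_lobe_gm_thickness": 0.045,
        }
    )
    autism_effect: AutismHippocampalEffect = field(
        default_factory=AutismHippocampalEffect
    )

    def __post_init__(self) -> None:
        check_correlation_matrix(self.coupling_R, "coupling block")


@dataclass(frozen=True)
class OSAParams:
    cross_section: CrossSectionSpec = field(default_factory=CrossSectionSpec)
    brain: SplineBrainModel = field(default_factory=SplineBrainModel)


def sample_correlated_cbcl(
    spec: CrossSectionSpec,
    n: int,
    sex: np.ndarray,
    autism: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """n x 3 CBCL scores: Gaussian copula to beta marginals, then shifts."""
    L = cholesky_factor(spec.cbcl_correlation)
    z = rng.standard_normal((n, 3)) @ L.T
    u = sps.norm.cdf(z)
    ranges = np.array([70.0, 64.0, 20.0])
    scores = np.empty((n, 3))
    for j, (a, b) in enumerate(spec.cbcl_beta_shapes):
        scores[:, j] = sps.beta.ppf(u[:, j], a, b) * ranges[j]
    male = (np.asarray(sex) == 0).astype(float)[:, None]
    asd = np.asarray(autism, dtype=float)[:, None]
    scores = (
        scores
        + male * np.asarray(spec.cbcl_sex_shift)
        + asd * np.asarray(spec.cbcl_autism_shift)
    )
    scores = np.round(scores)
    return np.clip(scores, 0.0, ranges)


def sample_cross_section(
    spec: CrossSectionSpec,
    n: int,
    rng: np.random.Generator,
    coupling_latent: np.ndarray | None = None,
) -> pd.DataFrame:
    """Baseline demographic/cognitive/behavioral frame (one row/subject).

    ``coupling_latent`` optionally supplies standard-normal columns
    (education, iq) from the joint brain-coupling block so that education
    and IQ correlate with the brain intercepts.
    """
    sex = (rng.uniform(size=n) >= spec.male_proportion).astype(np.int64)
    if coupling_latent is None:
        edu_latent = rng.standard_normal(n)
        iq_latent = rng.standard_normal(n)
    else:
        edu_latent, iq_latent = coupling_latent[:, 0], coupling_latent[:, 1]

    probs = np.asarray(spec.education_probs)
    cuts = sps.norm.ppf(np.cumsum(probs)[:-1])
    education = np.searchsorted(cuts, edu_latent, side="left").astype(np.int64)

    prev = np.where(sex == 0, spec.autism_prevalence_male, spec.autism_prevalence_female)
    autism = (rng.uniform(size=n) < prev).astype(np.int64)

    a = (spec.iq_lo - spec.iq_mean) / spec.iq_sd
    b = (spec.iq_hi - spec.iq_mean) / spec.iq_sd
    iq = sps.truncnorm.ppf(
        sps.norm.cdf(iq_latent), a, b, loc=spec.iq_mean, scale=spec.iq_sd
    )

    cbcl = sample_correlated_cbcl(spec, n, sex, autism, rng)
    frame = pd.DataFrame(
        {
            "sex": sex,
            "parental_education": education,
            "autism_diagnosis": autism,
            "iq": iq,
        }
    )
    for j, name in enumerate(CBCL_COLUMNS):
        frame[name] = cbcl[:, j]
    return frame


def expand_to_waves(
    cross_section: pd.DataFrame,
    schedule: WaveSchedule,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list, list, np.ndarray]:
    """Repeat the cross-section over waves and attach timelines."""
    n = len(cross_section)
    dobs, dates, ages = sample_timelines(rng, n, schedule)
    w = schedule.n_waves
    frame = cross_section.loc[cross_section.index.repeat(w)].reset_index(drop=True)
    frame["wave_number"] = np.tile(np.arange(1, w + 1), n)
    frame["age"] = ages.ravel()
    return frame, dobs, dates, ages


def eval_brain_measures(
    model: SplineBrainModel,
    sex: np.ndarray,
    autism: np.ndarray,
    age_months: np.ndarray,
    intercepts: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Per-row brain values: sex spline + intercept + residual (+ ASD)."""
    age = np.asarray(age_months, dtype=float)
    sex = np.asarray(sex, dtype=int)
    out: dict[str, np.ndarray] = {}
    for name in BRAIN_COLUMNS:
        base = np.where(
            sex == 1,
            eval_spline(model.splines[name][1], age),
            eval_spline(model.splines[name][0], age),
        )
        value = base + intercepts[name] + rng.standard_normal(len(age)) * model.residual_sd[name]
        if name == "hippo_volume":
            value = value + np.asarray(autism, float) * model.autism_effect.offset(age)
        out[name] = value
    return out


def generate_osa_dataset(
    seed: int = 0,
    n_subjects: int = 10_000,
    variant: int = 1,
    params: OSAParams | None = None,
    schedule: WaveSchedule | None = None,
) -> LongTable:
    """End-to-end generation of one cross-section + spline dataset."""
    params = params or OSAParams()
    schedule = schedule or WaveSchedule()
    site = f"OSA_data{variant}"
    rngs = derive_seeds(
        seed,
        [
            f"{site}/coupling",
            f"{site}/cross-section",
            f"{site}/timeline",
            f"{site}/intercepts",
            f"{site}/residuals",
        ],
    )
    n, w = n_subjects, schedule.n_waves
    dictionary = default_data_dictionary()

    # joint latent block: (icv, hippo, education, iq)
    Lc = cholesky_factor(params.brain.coupling_R)
    latent = rngs[f"{site}/coupling"].standard_normal((n, 4)) @ Lc.T

    cs = sample_cross_section(
        params.cross_section,
        n,
        rngs[f"{site}/cross-section"],
        coupling_latent=latent[:, 2:],
    )
    long, dobs, dates, ages = expand_to_waves(cs, schedule, rngs[f"{site}/timeline"])

    # subject random intercepts; icv and hippo take theirs from the latent block
    irng = rngs[f"{site}/intercepts"]
    intercepts = {}
    for name in BRAIN_COLUMNS:
        sd = params.brain.intercept_sd[name]
        if name == "icv":
            intercepts[name] = latent[:, 0] * sd
        elif name == "hippo_volume":
            intercepts[name] = latent[:, 1] * sd
        else:
            intercepts[name] = irng.standard_normal(n) * sd
    row_intercepts = {k: np.repeat(v, w) for k, v in intercepts.items()}

    brain = eval_brain_measures(
        params.brain,
        long["sex"].to_numpy(),
        long["autism_diagnosis"].to_numpy(),
        long["age"].to_numpy(),
        row_intercepts,
        rngs[f"{site}/residuals"],
    )

    subject_ids = np.array([f"{site}_s{i:06d}" for i in range(n)])
    obs = {
        "subject_id": np.repeat(subject_ids, w),
        "wave_number": long["wave_number"].to_numpy(),
        "brain_behavior_measurement_date": pd.to_datetime(
            [d for row in dates for d in row]
        ),
        "age": long["age"].to_numpy(),
        "iq": np.clip(long["iq"].to_numpy(), *dictionary["iq"].allowed_range),
    }
    for name in CBCL_COLUMNS:
        obs[name] = pd.array(long[name].to_numpy(), dtype="Int64")
    for name in BRAIN_COLUMNS:
        lo, hi = dictionary[name].allowed_range
        obs[name] = np.clip(brain[name], lo, hi)

    statics = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "site_id": site,
            "dob": pd.to_datetime(dobs),
            "sex": cs["sex"].to_numpy(),
            "parental_education": cs["parental_education"].to_numpy(),
            "autism_diagnosis": cs["autism_diagnosis"].to_numpy(),
        }
    )
    return assemble_long_table(statics, pd.DataFrame(obs))
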