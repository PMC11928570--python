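"""Normative z-score engine ("dpn").

Generative process: per-subject *true* z-scores for six brain phenotypes
plus latent cognition/behavior channels are drawn jointly from a target
correlation matrix via its Cholesky factor and clipped to a biologically
plausible band.  Each subject then follows an individual quadratic z-score
trajectory over the seven waves; measurement noise is added per wave; the
observed z-scores are mapped to raw units through the normative
mean/spread curves, with female values scaled by phenotype-specific sex
ratios.  IQ and the three CBCL subscale scores derive from the correlated
latent channels, and an autism diagnosis is thresholded from a latent
score combining brain z-scores, true IQ and noise, with sex-specific
thresholds giving the higher male prevalence.
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
from ..stats import BoundedScoreMap, check_correlation_matrix, cholesky_factor
from ..trajectories import NormativeModel, default_normative_model, z_to_raw

__all__ = [
    "PhenotypeCorrelationModel",
    "ZTrajectoryRange",
    "NoiseSpec",
    "AutismModel",
    "DPNParams",
    "sample_baseline_z",
    "sample_z_trajectory",
    "add_measurement_noise",
    "assign_autism",
    "generate_dpn_dataset",
    "CHANNELS",
    "EDUCATION_PROBS",
]

#: Criteria-list parental education distribution (levels 0..3).
EDUCATION_PROBS = (0.053, 0.354, 0.253, 0.340)

#: Latent channel order: six brain phenotypes, IQ, three CBCL subscales.
CHANNELS = BRAIN_COLUMNS + ("iq",) + CBCL_COLUMNS


def _default_R() -> np.ndarray:
    """Documented default phenotype correlation matrix (PSD-verified)."""
    p = len(CHANNELS)
    idx = {name: i for i, name in enumerate(CHANNELS)}
    R = np.eye(p)

    def set_r(a: str, b: str, r: float) -> None:
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r

    # brain-brain block
    set_r("wm_volume", "gm_volume", 0.45)
    set_r("wm_volume", "icv", 0.65)
    set_r("gm_volume", "icv", 0.75)
    set_r("hippo_volume", "amygdala_volume", 0.55)
    set_r("hippo_volume", "gm_volume", 0.35)
    set_r("amygdala_volume", "gm_volume", 0.30)
    set_r("hippo_volume", "wm_volume", 0.30)
    set_r("amygdala_volume", "wm_volume", 0.25)
    set_r("hippo_volume", "icv", 0.40)
    set_r("amygdala_volume", "icv", 0.35)
    set_r("frontal_lobe_gm_thickness", "gm_volume", 0.30)
    set_r("frontal_lobe_gm_thickness", "wm_volume", 0.10)
    set_r("frontal_lobe_gm_thickness", "icv", 0.15)
    set_r("frontal_lobe_gm_thickness", "hippo_volume", 0.10)
    set_r("frontal_lobe_gm_thickness", "amygdala_volume", 0.10)
    # brain-IQ (weak positive)
    for name, r in (
        ("wm_volume", 0.18),
        ("gm_volume", 0.22),
        ("hippo_volume", 0.15),
        ("amygdala_volume", 0.12),
        ("frontal_lobe_gm_thickness", 0.10),
        ("icv", 0.20),
    ):
        set_r(name, "iq", r)
    # brain-CBCL (small negative) and CBCL-IQ
    for cbcl, brain_r, iq_r in (
        ("cbcl_externalizing_raw_score", -0.08, -0.15),
        ("cbcl_internalizing_raw_score", -0.06, -0.10),
        ("cbcl_attentionproblem_raw_score", -0.10, -0.25),
    ):
        for brain in BRAIN_COLUMNS:
            set_r(brain, cbcl, brain_r)
        set_r(cbcl, "iq", iq_r)
    # CBCL inter-correlations
    set_r("cbcl_externalizing_raw_score", "cbcl_internalizing_raw_score", 0.60)
    set_r("cbcl_externalizing_raw_score", "cbcl_attentionproblem_raw_score", 0.55)
    set_r("cbcl_internalizing_raw_score", "cbcl_attentionproblem_raw_score", 0.45)
    return R


@dataclass(frozen=True)
class PhenotypeCorrelationModel:
    """Ordered phenotype channels and their target correlation matrix."""

    phenotype_names: tuple[str, ...] = CHANNELS
    R: np.ndarray = field(default_factory=_default_R)

    def __post_init__(self) -> None:
        check_correlation_matrix(self.R, "phenotype correlation matrix")
        if self.R.shape[0] != len(self.phenotype_names):
            raise ValueError("R dimension must match channel count")

    def index(self, name: str) -> int:
        return self.phenotype_names.index(name)


@dataclass(frozen=True)
class ZTrajectoryRange:
    """Sampling intervals for individual quadratic z-score trajectories.

    ``z(t) = z0 + alpha*u + beta*u**2`` with u = (age - 168 months) / 120
    (centered age in decades); coefficients drawn uniformly from the
    intervals, trajectories clipped to ``[-z_bound, z_bound]``.
    """

    alpha: tuple[float, float] = (-0.35, 0.35)
    beta: tuple[float, float] = (-0.15, 0.15)
    z_bound: float = 4.0
    center_months: float = 168.0
    scale_months: float = 120.0

    def __post_init__(self) -> None:
        if self.z_bound <= 0:
            raise ValueError("z_bound must be positive")
        for lo, hi in (self.alpha, self.beta):
            if not np.isfinite([lo, hi]).all() or lo > hi:
                raise ValueError("coefficient intervals must be finite and ordered")

    def centered_age(self, age_months) -> np.ndarray:
        return (np.asarray(age_months, dtype=float) - self.center_months) / self.scale_months


@dataclass(frozen=True)
class NoiseSpec:
    """Per-phenotype measurement noise sd on the z scale."""

    sd: dict[str, float] = field(
        default_factory=lambda: {name: 0.15 for name in CHANNELS}
    )

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.sd.values()):
            raise ValueError("noise sd must be non-negative")

    def as_array(self, names: tuple[str, ...]) -> np.ndarray:
        return np.array([self.sd.get(n, 0.0) for n in names])


@dataclass(frozen=True)
class AutismModel:
    """Threshold model: diagnosis when a latent score exceeds a sex cutoff.

    latent = sum_j w_j * z_j + w_iq * z_iq + noise; thresholds are placed
    at the per-sex target prevalences using the analytic latent variance,
    so the male prevalence exceeds the female one at defaults.
    """

    weights: dict[str, float] = field(
        default_factory=lambda: {
            "gm_volume": -0.20,
            "hippo_volume": -0.30,
            "amygdala_volume": -0.25,
            "frontal_lobe_gm_thickness": 0.10,
            "iq": -0.30,
        }
    )
    noise_sd: float = 1.0
    prevalence_male: float = 0.030
    prevalence_female: float = 0.0075

    def __post_init__(self) -> None:
        if not self.prevalence_male > self.prevalence_female:
            raise ValueError("defaults require male prevalence > female")

    def latent_sd(self, model: PhenotypeCorrelationModel) -> float:
        w = np.array([self.weights.get(n, 0.0) for n in model.phenotype_names])
        return float(np.sqrt(w @ model.R @ w + self.noise_sd**2))

    def thresholds(self, model: PhenotypeCorrelationModel) -> tuple[float, float]:
        """(male, female) latent cutoffs for the target prevalences."""
        sd = self.latent_sd(model)
        male = sd * sps.norm.ppf(1.0 - self.prevalence_male)
        female = sd * sps.norm.ppf(1.0 - self.prevalence_female)
        return float(male), float(female)


#: Right-skewed latent-to-score maps for the CBCL subscales.
DEFAULT_CBCL_MAPS = {
    "cbcl_externalizing_raw_score": BoundedScoreMap(0, 70, loc=2.0, scale=1.2),
    "cbcl_internalizing_raw_score": BoundedScoreMap(0, 64, loc=2.0, scale=1.2),
    "cbcl_attentionproblem_raw_score": BoundedScoreMap(0, 20, loc=1.5, scale=1.2),
}


@dataclass(frozen=True)
class DPNParams:
    """Full parameter set for the normative z-score engine."""

    correlation: PhenotypeCorrelationModel = field(
        default_factory=PhenotypeCorrelationModel
    )
    trajectory: ZTrajectoryRange = field(default_factory=ZTrajectoryRange)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    autism: AutismModel = field(default_factory=AutismModel)
    normative: NormativeModel = field(default_factory=default_normative_model)
    cbcl_maps: dict[str, BoundedScoreMap] = field(
        default_factory=lambda: dict(DEFAULT_CBCL_MAPS)
    )
    iq_noise_sd: float = 3.0
    education_probs: tuple[float, ...] = EDUCATION_PROBS


def sample_baseline_z(
    model: PhenotypeCorrelationModel,
    n: int,
    rng: np.random.Generator,
    z_bound: float = 4.0,
) -> np.ndarray:
    """n x p correlated true z-scores, clipped to the plausible band."""
    if n < 1:
        raise ValueError("n must be at least 1")
    L = cholesky_factor(model.R)
    z = rng.standard_normal((n, len(model.phenotype_names))) @ L.T
    return np.clip(z, -z_bound, z_bound)


def sample_z_trajectory(
    z0: np.ndarray,
    traj_range: ZTrajectoryRange,
    wave_ages: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Individual quadratic z trajectories: (n, waves, p) true z-scores."""
    z0 = np.atleast_2d(np.asarray(z0, dtype=float))
    wave_ages = np.atleast_2d(np.asarray(wave_ages, dtype=float))
    if np.any(np.diff(wave_ages, axis=1) <= 0):
        raise ValueError("wave ages must be ascending")
    n, p = z0.shape
    alpha = rng.uniform(*traj_range.alpha, size=(n, p))
    beta = rng.uniform(*traj_range.beta, size=(n, p))
    u = traj_range.centered_age(wave_ages)  # (n, waves)
    z = (
        z0[:, None, :]
        + alpha[:, None, :] * u[:, :, None]
        + beta[:, None, :] * u[:, :, None] ** 2
    )
    return np.clip(z, -traj_range.z_bound, traj_range.z_bound)


def add_measurement_noise(
    z_true: np.ndarray,
    spec: NoiseSpec,
    rng: np.random.Generator,
    names: tuple[str, ...] = CHANNELS,
) -> np.ndarray:
    """Observed z = true z + independent N(0, sd^2) per phenotype."""
    z_true = np.asarray(z_true, dtype=float)
    sd = spec.as_array(names)
    return z_true + rng.standard_normal(z_true.shape) * sd


def assign_autism(
    z_baseline: np.ndarray,
    iq_true: np.ndarray,
    model: AutismModel,
    sex: np.ndarray,
    rng: np.random.Generator,
    correlation: PhenotypeCorrelationModel | None = None,
) -> np.ndarray:
    """Wave-constant diagnosis from brain z-scores, true IQ and noise."""
    correlation = correlation or PhenotypeCorrelationModel()
    names = correlation.phenotype_names
    w = np.array([model.weights.get(n, 0.0) for n in names])
    z = np.array(z_baseline, dtype=float, copy=True)
    if "iq" in names:
        z[:, names.index("iq")] = (np.asarray(iq_true, float) - 100.0) / 15.0
    latent = z @ w + rng.standard_normal(len(z)) * model.noise_sd
    male_thr, female_thr = model.thresholds(correlation)
    thr = np.where(np.asarray(sex) == 0, male_thr, female_thr)
    return (latent > thr).astype(np.int64)


def sample_statics(
    n: int,
    rng: np.random.Generator,
    education_probs: tuple[float, ...] = EDUCATION_PROBS,
) -> tuple[np.ndarray, np.ndarray]:
    """(sex, parental_education) draws under the criteria-list marginals."""
    sex = (rng.uniform(size=n) < 0.5).astype(np.int64)  # 1 = female
    probs = np.asarray(education_probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("education probabilities must sum to 1")
    education = rng.choice(np.arange(len(probs)), size=n, p=probs).astype(np.int64)
    return sex, education


def generate_dpn_dataset(
    seed: int = 0,
    n_subjects: int = 10_000,
    variant: int = 1,
    params: DPNParams | None = None,
    schedule: WaveSchedule | None = None,
) -> LongTable:
    """End-to-end generation of one normative z-score dataset."""
    params = params or DPNParams()
    schedule = schedule or WaveSchedule()
    site = f"dpn_data{variant}"
    rngs = derive_seeds(
        seed,
        [
            f"{site}/statics",
            f"{site}/timeline",
            f"{site}/baseline",
            f"{site}/trajectory",
            f"{site}/noise",
            f"{site}/autism",
            f"{site}/iq",
        ],
    )
    n, w = n_subjects, schedule.n_waves
    names = params.correlation.phenotype_names

    sex, education = sample_statics(n, rngs[f"{site}/statics"], params.education_probs)
    dobs, dates, ages = sample_timelines(rngs[f"{site}/timeline"], n, schedule)

    z0 = sample_baseline_z(
        params.correlation, n, rngs[f"{site}/baseline"], params.trajectory.z_bound
    )
    iq_true = 100.0 + 15.0 * z0[:, names.index("iq")]
    autism = assign_autism(
        z0, iq_true, params.autism, sex, rngs[f"{site}/autism"], params.correlation
    )

    z_true = sample_z_trajectory(z0, params.trajectory, ages, rngs[f"{site}/trajectory"])
    z_obs = add_measurement_noise(z_true, params.noise, rngs[f"{site}/noise"], names)

    dictionary = default_data_dictionary()
    subject_ids = np.array([f"{site}_s{i:06d}" for i in range(n)])

    obs = {
        "subject_id": np.repeat(subject_ids, w),
        "wave_number": np.tile(np.arange(1, w + 1), n),
        "brain_behavior_measurement_date": pd.to_datetime(
            [d for row in dates for d in row]
        ),
        "age": ages.ravel(),
    }
    age_flat = ages.ravel().astype(float)
    sex_flat = np.repeat(sex, w)

    # brain measures: observed z -> raw units, clipped to dictionary ranges
    for name in BRAIN_COLUMNS:
        j = names.index(name)
        raw = z_to_raw(z_obs[:, :, j].ravel(), params.normative, name, age_flat, sex_flat)
        lo, hi = dictionary[name].allowed_range
        obs[name] = np.clip(raw, lo, hi)

    # IQ: true score constant over waves; per-wave observation noise, then
    # affine calibration back to the population mean-100/sd-15 scale.
    eps = rngs[f"{site}/iq"].standard_normal((n, w)) * params.iq_noise_sd
    shrink = 15.0 / np.sqrt(15.0**2 + params.iq_noise_sd**2)
    iq_obs = 100.0 + (iq_true[:, None] - 100.0 + eps) * shrink
    obs["iq"] = np.clip(iq_obs.ravel(), *dictionary["iq"].allowed_range)

    for name in CBCL_COLUMNS:
        j = names.index(name)
        scores = params.cbcl_maps[name](z_obs[:, :, j].ravel())
        obs[name] = pd.array(scores, dtype="Int64")

    statics = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "site_id": site,
            "dob": pd.to_datetime(dobs),
            "sex": sex,
            "parental_education": education,
            "autism_diagnosis": autism,
        }
    )
    return assemble_long_table(statics, pd.DataFrame(obs))
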