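"""Latent growth curve engine ("leer").

Six brain measures are simulated jointly from a single latent growth curve
model grouped by sex: each subject draws an intercept and slope per
measure from a 12-dimensional growth-factor distribution (sex-specific
means, shared covariance), trajectories are realized over seven waves as
either quadratic curves with a dominant linear component or freely-loaded
basis curves, and occasion-level residual variance is constant over waves
and sex.

Covariates are then layered on as weighted sums of the standardized brain
intercept factors and previously built covariates plus Gaussian noise:
parental education (discretized by quantile cuts at the published category
proportions, small positive brain correlation), autism diagnosis
(thresholded, negative brain correlation), IQ (weak positive brain
correlation, calibrated to mean 100 / sd 15) and the three CBCL subscales
(externalizing negatively tied to brain, education and autism; the other
two riding on their high positive correlation with externalizing).
Covariate values at later waves drift with signed half-normal steps:
externalizing declines, internalizing and attention problems rise, IQ
stays stable with small symmetric variation.  Sex differences in
covariates are never injected directly — they arise only through the sex
differences in brain measures.

A pool of three cohorts is generated at once; the missingness stack (wave
dropout, exponentially decaying MRI dropout, MNAR psychopathology
dropout) is applied, the 20% cap enforced, and the pool is split into
three disjoint datasets.
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
from ..missingness import (
    MeasureDropoutModel,
    WaveDropoutModel,
    enforce_missing_cap,
    mnar_psych_dropout,
    mri_measure_dropout,
    wave_dropout,
)
from ..stats import BoundedScoreMap, cholesky_factor, nearest_psd
from ..trajectories import BasisLoadings

__all__ = [
    "MeasureGrowthSpec",
    "LGCSpec",
    "CovariateWeights",
    "DriftSpec",
    "LeerParams",
    "sample_growth_factors",
    "realize_trajectories",
    "build_covariate",
    "drift_covariate",
    "generate_leer_dataset",
]

_LINEAR = tuple(w / 6.0 for w in range(7))


@dataclass(frozen=True)
class MeasureGrowthSpec:
    """Growth-factor specification for one brain measure.

    Intercept is the wave-1 level; the slope factor is the total wave-1 to
    wave-7 change (loadings identified 0..1).  ``quad_mean`` adds a fixed
    population quadratic component on the squared loading; for a
    "quadratic with dominant linear component" shape its magnitude stays
    below the slope mean's.
    """

    name: str
    shape: str = "quadratic"  # or "basis"
    loadings: tuple[float, ...] = _LINEAR
    intercept_mean: tuple[float, float] = (0.0, 0.0)  # (male, female)
    slope_mean: tuple[float, float] = (0.0, 0.0)
    intercept_sd: float = 1.0
    slope_sd: float = 1.0
    is_corr: float = -0.3  # intercept-slope correlation
    quad_mean: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("quadratic", "basis"):
            raise ValueError(f"unknown shape {self.shape!r}")
        BasisLoadings(self.loadings)  # validates identification
        if self.residual_sd < 0 or self.intercept_sd < 0 or self.slope_sd < 0:
            raise ValueError("variances must be non-negative")
        if self.shape == "quadratic" and abs(self.quad_mean) >= abs(
            self.slope_mean[0]
        ) > 0:
            raise ValueError("quadratic component must stay below the linear one")


def _default_measures() -> tuple[MeasureGrowthSpec, ...]:
    return (
        MeasureGrowthSpec(
            "wm_volume",
            shape="quadratic",
            intercept_mean=(4.00e5, 3.70e5),
            slope_mean=(9.0e4, 8.5e4),
            intercept_sd=2.4e4,
            slope_sd=2.6e4,
            quad_mean=-1.5e4,
            residual_sd=8.0e3,
        ),
        MeasureGrowthSpec(
            "gm_volume",
            shape="basis",
            loadings=(0.0, 0.30, 0.55, 0.72, 0.84, 0.93, 1.0),
            intercept_mean=(7.30e5, 6.70e5),
            slope_mean=(-5.0e4, -4.6e4),
            intercept_sd=4.4e4,
            slope_sd=1.5e4,
            residual_sd=1.2e4,
        ),
        MeasureGrowthSpec(
            "hippo_volume",
            shape="quadratic",
            intercept_mean=(3700.0, 3480.0),
            slope_mean=(350.0, 330.0),
            intercept_sd=220.0,
            slope_sd=100.0,
            quad_mean=-60.0,
            residual_sd=70.0,
        ),
        MeasureGrowthSpec(
            "amygdala_volume",
            shape="quadratic",
            intercept_mean=(2850.0, 2650.0),
            slope_mean=(280.0, 260.0),
            intercept_sd=170.0,
            slope_sd=80.0,
            quad_mean=-50.0,
            residual_sd=55.0,
        ),
        MeasureGrowthSpec(
            "frontal_lobe_gm_thickness",
            shape="quadratic",
            intercept_mean=(3.15, 3.15),
            slope_mean=(-0.42, -0.42),
            intercept_sd=0.19,
            slope_sd=0.12,
            quad_mean=0.05,
            residual_sd=0.045,
        ),
        MeasureGrowthSpec(
            "icv",
            shape="basis",
            loadings=(0.0, 0.45, 0.70, 0.85, 0.93, 0.97, 1.0),
            intercept_mean=(1.35e6, 1.23e6),
            slope_mean=(1.5e5, 1.35e5),
            intercept_sd=8.0e4,
            slope_sd=4.0e4,
            residual_sd=1.5e4,
        ),
    )


@dataclass(frozen=True)
class LGCSpec:
    """Joint latent growth model for the six measures.

    Growth factors are ordered (I_1, S_1, ..., I_6, S_6).  The covariance
    is assembled from each measure's factor sds and intercept-slope
    correlation plus cross-measure correlations between intercepts and
    between slopes, then PSD-verified.
    """

    measures: tuple[MeasureGrowthSpec, ...] = field(default_factory=_default_measures)
    cross_intercept_corr: float = 0.40
    cross_slope_corr: float = 0.20

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.measures)

    def factor_means(self, sex: int) -> np.ndarray:
        out = []
        for m in self.measures:
            out += [m.intercept_mean[sex], m.slope_mean[sex]]
        return np.array(out)

    def factor_covariance(self) -> np.ndarray:
        k = len(self.measures)
        corr = np.eye(2 * k)
        for i, m in enumerate(self.measures):
            corr[2 * i, 2 * i + 1] = corr[2 * i + 1, 2 * i] = m.is_corr
        for i in range(k):
            for j in range(i + 1, k):
                corr[2 * i, 2 * j] = corr[2 * j, 2 * i] = self.cross_intercept_corr
                corr[2 * i + 1, 2 * j + 1] = corr[2 * j + 1, 2 * i + 1] = (
                    self.cross_slope_corr
                )
        corr = nearest_psd(corr)
        sds = np.array(
            [s for m in self.measures for s in (m.intercept_sd, m.slope_sd)]
        )
        cov = corr * np.outer(sds, sds)
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise ValueError("growth-factor covariance is not PSD")
        return cov


def sample_growth_factors(
    spec: LGCSpec, n: int, sex: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """n x 12 growth factors: sex-specific means, shared covariance."""
    sex = np.asarray(sex, dtype=int)
    cov = spec.factor_covariance()
    if np.allclose(cov, 0.0):
        draws = np.zeros((n, cov.shape[0]))
    else:
        L = cholesky_factor(cov)
        draws = rng.standard_normal((n, cov.shape[0])) @ L.T
    means = np.where(
        (sex == 1)[:, None], spec.factor_means(1)[None, :], spec.factor_means(0)[None, :]
    )
    return means + draws


def realize_trajectories(
    factors: np.ndarray, spec: LGCSpec, rng: np.random.Generator
) -> np.ndarray:
    """(n, waves, 6) per-wave values: y_w = I + lam_w*S + q*lam_w^2 + eps."""
    n = factors.shape[0]
    n_waves = len(spec.measures[0].loadings)
    out = np.empty((n, n_waves, len(spec.measures)))
    for j, m in enumerate(spec.measures):
        lam = np.asarray(m.loadings)
        intercept = factors[:, 2 * j]
        slope = factors[:, 2 * j + 1]
        quad = m.quad_mean * lam**2 if m.shape == "quadratic" else 0.0
        mean = intercept[:, None] + slope[:, None] * lam[None, :] + quad
        out[:, :, j] = mean + rng.standard_normal((n, n_waves)) * m.residual_sd
    return out


@dataclass(frozen=True)
class CovariateWeights:
    """One covariate as a weighted sum of brain factors and prior covariates.

    Weights act on *standardized* brain intercept factors and standardized
    continuous channels of previously built covariates; Gaussian noise is
    added and the standardized result is transformed to the target scale:
    ``("categorical", probs)`` quantile-cuts at the given proportions,
    ``("threshold", prevalence)`` thresholds the top fraction,
    ``("affine", mean, sd)`` rescales, ``("bounded", map)`` applies a
    :class:`~devcohort.stats.BoundedScoreMap`.
    """

    name: str
    brain_weights: dict[str, float] = field(default_factory=dict)
    covariate_weights: dict[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    transform: tuple = ("affine", 0.0, 1.0)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def build_covariate(
    brain_factors: np.ndarray,
    spec_lgc: LGCSpec,
    prior_channels: dict[str, np.ndarray],
    w: CovariateWeights,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Returns (standardized latent channel, transformed baseline values)."""
    n = brain_factors.shape[0]
    channel = rng.standard_normal(n) * w.noise_sd
    for name, weight in w.brain_weights.items():
        j = spec_lgc.names.index(name)
        channel = channel + weight * _standardize(brain_factors[:, 2 * j])
    for name, weight in w.covariate_weights.items():
        channel = channel + weight * prior_channels[name]
    channel = _standardize(channel)

    kind = w.transform[0]
    if kind == "categorical":
        probs = np.asarray(w.transform[1], dtype=float)
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("category probabilities must sum to 1")
        cuts = np.quantile(channel, np.cumsum(probs)[:-1])
        values = np.searchsorted(cuts, channel, side="left").astype(np.int64)
    elif kind == "threshold":
        prevalence = float(w.transform[1])
        cut = np.quantile(channel, 1.0 - prevalence)
        values = (channel > cut).astype(np.int64)
    elif kind == "affine":
        _, mean, sd = w.transform
        values = mean + sd * channel
    elif kind == "bounded":
        values = w.transform[1](channel)
    else:
        raise ValueError(f"unknown transform {kind!r}")
    return channel, values


@dataclass(frozen=True)
class DriftSpec:
    """Signed half-normal wave-to-wave drift for one covariate.

    ``direction`` +1 increases, -1 decreases, 0 adds symmetric noise; each
    wave step adds ``direction * |N(step_mean, step_sd)|`` (or plain
    ``N(0, step_sd)`` when direction is 0).
    """

    name: str
    direction: int
    step_mean: float = 0.0
    step_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in (-1, 0, 1):
            raise ValueError("direction must be -1, 0 or +1")


DEFAULT_DRIFTS = {
    "iq": DriftSpec("iq", 0, step_sd=1.2),
    "cbcl_externalizing_raw_score": DriftSpec(
        "cbcl_externalizing_raw_score", -1, step_mean=0.8, step_sd=0.6
    ),
    "cbcl_internalizing_raw_score": DriftSpec(
        "cbcl_internalizing_raw_score", +1, step_mean=0.6, step_sd=0.5
    ),
    "cbcl_attentionproblem_raw_score": DriftSpec(
        "cbcl_attentionproblem_raw_score", +1, step_mean=0.25, step_sd=0.2
    ),
}


def drift_covariate(
    baseline: np.ndarray, d: DriftSpec, n_waves: int, rng: np.random.Generator
) -> np.ndarray:
    """(n, waves) covariate values drifting from the baseline."""
    n = len(baseline)
    out = np.empty((n, n_waves))
    out[:, 0] = baseline
    for wv in range(1, n_waves):
        if d.direction == 0:
            step = rng.standard_normal(n) * d.step_sd
        else:
            step = d.direction * np.abs(
                rng.normal(d.step_mean, d.step_sd, size=n)
            )
        out[:, wv] = out[:, wv - 1] + step
    return out


def _default_covariates() -> tuple[CovariateWeights, ...]:
    brain = lambda w: {name: w for name in BRAIN_COLUMNS}
    return (
        CovariateWeights(
            "parental_education",
            brain_weights=brain(0.08),
            noise_sd=1.0,
            transform=("categorical", (0.053, 0.354, 0.253, 0.340)),
        ),
        CovariateWeights(
            "autism_diagnosis",
            brain_weights=brain(-0.12),
            noise_sd=1.0,
            transform=("threshold", 0.02),
        ),
        CovariateWeights(
            "iq",
            brain_weights=brain(0.07),
            covariate_weights={"parental_education": -0.25},
            noise_sd=0.9,
            transform=("affine", 100.0, 15.0),
        ),
        CovariateWeights(
            "cbcl_externalizing_raw_score",
            brain_weights=brain(-0.08),
            covariate_weights={"parental_education": -0.20, "autism_diagnosis": -0.15},
            noise_sd=0.9,
            transform=("bounded", BoundedScoreMap(0, 70, loc=2.0, scale=1.2)),
        ),
        CovariateWeights(
            "cbcl_internalizing_raw_score",
            brain_weights=brain(-0.05),
            covariate_weights={"cbcl_externalizing_raw_score": 0.60},
            noise_sd=0.8,
            transform=("bounded", BoundedScoreMap(0, 64, loc=2.0, scale=1.2)),
        ),
        CovariateWeights(
            "cbcl_attentionproblem_raw_score",
            brain_weights=brain(-0.08),
            covariate_weights={"cbcl_externalizing_raw_score": 0.50},
            noise_sd=0.8,
            transform=("bounded", BoundedScoreMap(0, 20, loc=1.5, scale=1.2)),
        ),
    )


@dataclass(frozen=True)
class LeerParams:
    """Full parameter set for the latent growth curve engine."""

    lgc: LGCSpec = field(default_factory=LGCSpec)
    covariates: tuple[CovariateWeights, ...] = field(
        default_factory=_default_covariates
    )
    drifts: dict[str, DriftSpec] = field(default_factory=lambda: dict(DEFAULT_DRIFTS))
    wave_dropout: WaveDropoutModel = field(default_factory=WaveDropoutModel)
    measure_dropout: MeasureDropoutModel = field(default_factory=MeasureDropoutModel)
    apply_missingness: bool = True
    pool_factor: int = 3  # pool size = pool_factor * n_subjects


def _pool_site(variant: int) -> str:
    return f"leer_data{variant}"


def generate_leer_pool(
    seed: int,
    pool_n: int,
    params: LeerParams,
    schedule: WaveSchedule,
) -> tuple[LongTable, pd.DataFrame]:
    """Simulate the full participant pool; returns (table, true CBCL scores)."""
    rngs = derive_seeds(
        seed,
        [
            "leer/statics",
            "leer/timeline",
            "leer/factors",
            "leer/residuals",
            "leer/covariates",
            "leer/drift",
            "leer/missing-wave",
            "leer/missing-mri",
            "leer/missing-mnar",
            "leer/cap",
        ],
    )
    n, w = pool_n, schedule.n_waves
    dictionary = default_data_dictionary()

    sex = (rngs["leer/statics"].uniform(size=n) < 0.5).astype(np.int64)
    dobs, dates, ages = sample_timelines(rngs["leer/timeline"], n, schedule)

    factors = sample_growth_factors(params.lgc, n, sex, rngs["leer/factors"])
    brain = realize_trajectories(factors, params.lgc, rngs["leer/residuals"])

    channels: dict[str, np.ndarray] = {}
    baselines: dict[str, np.ndarray] = {}
    cov_rng = rngs["leer/covariates"]
    for cw in params.covariates:
        channel, values = build_covariate(factors, params.lgc, channels, cw, cov_rng)
        channels[cw.name] = channel
        baselines[cw.name] = values

    # wave-varying covariates; education and autism stay static
    drift_rng = rngs["leer/drift"]
    per_wave: dict[str, np.ndarray] = {}
    for name in ("iq",) + CBCL_COLUMNS:
        per_wave[name] = drift_covariate(
            np.asarray(baselines[name], dtype=float),
            params.drifts[name],
            w,
            drift_rng,
        )

    subject_ids = np.array([f"leer_pool_s{i:06d}" for i in range(n)])
    obs = {
        "subject_id": np.repeat(subject_ids, w),
        "wave_number": np.tile(np.arange(1, w + 1), n),
        "brain_behavior_measurement_date": pd.to_datetime(
            [d for row in dates for d in row]
        ),
        "age": ages.ravel(),
    }
    for j, name in enumerate(params.lgc.names):
        lo, hi = dictionary[name].allowed_range
        obs[name] = np.clip(brain[:, :, j].ravel(), lo, hi)
    obs["iq"] = np.clip(per_wave["iq"].ravel(), *dictionary["iq"].allowed_range)
    true_scores = {}
    for name in CBCL_COLUMNS:
        lo, hi = dictionary[name].allowed_range
        vals = np.clip(np.round(per_wave[name].ravel()), lo, hi)
        true_scores[name] = vals
        obs[name] = pd.array(vals, dtype="Int64")

    statics = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "site_id": "leer_pool",
            "dob": pd.to_datetime(dobs),
            "sex": sex,
            "parental_education": np.asarray(
                baselines["parental_education"], dtype=np.int64
            ),
            "autism_diagnosis": np.asarray(
                baselines["autism_diagnosis"], dtype=np.int64
            ),
        }
    )
    table = assemble_long_table(statics, pd.DataFrame(obs))
    truth = pd.DataFrame(true_scores)

    if params.apply_missingness:
        pristine = table.copy()
        psych = truth[CBCL_COLUMNS[0]].to_numpy() + truth[CBCL_COLUMNS[1]].to_numpy()
        table = wave_dropout(
            table, params.wave_dropout, rngs["leer/missing-wave"], psych_scores=psych
        )
        table = mri_measure_dropout(
            table, params.measure_dropout, rngs["leer/missing-mri"]
        )
        table = mnar_psych_dropout(
            table, truth, params.measure_dropout, rngs["leer/missing-mnar"]
        )
        table, _ = enforce_missing_cap(table, pristine, rng=rngs["leer/cap"])
    return table, truth


def generate_leer_dataset(
    seed: int = 0,
    n_subjects: int = 10_000,
    variant: int = 1,
    params: LeerParams | None = None,
    schedule: WaveSchedule | None = None,
) -> LongTable:
    """One of the three disjoint splits of the simulated pool.

    The pool depends only on the seed; the variant selects a block of the
    seeded shuffle, so the three variants partition the pool.
    """
    if variant not in (1, 2, 3):
        raise ValueError("variant must be 1, 2 or 3")
    params = params or LeerParams()
    schedule = schedule or WaveSchedule()
    pool_n = params.pool_factor * n_subjects
    table, _ = generate_leer_pool(seed, pool_n, params, schedule)

    split_rng = derive_seeds(seed, ["leer/split"])["leer/split"]
    order = split_rng.permutation(pool_n)
    block = np.sort(order[(variant - 1) * n_subjects : variant * n_subjects])
    subject_ids = np.array([f"leer_pool_s{i:06d}" for i in block])
    frame = table.frame[table.frame["subject_id"].isin(subject_ids)].copy()
    site = _pool_site(variant)
    frame["site_id"] = site
    frame["subject_id"] = frame["subject_id"].str.replace(
        "leer_pool_", f"{site}_", regex=False
    )
    return LongTable(frame)
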