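"""Growth-chart mixed-model engine with embedded signals ("paint").

The base process resembles the normative z-score engine but models the
fixed growth curves as second-order polynomials in log(age) with a sex
covariate, fitted to the normative reference curves.  Each subject
carries a correlated z-score vector (the random effect) that offsets the
fixed curve in units of the age-dependent normative spread, and random
noise is added per subject and data point.  Autism is assigned by a
plain binomial draw at 3% prevalence.

Each variant embeds one ground-truth pattern:

1. wave-to-wave white-matter volume changes drive CBCL attention-score
   changes, plus 10% MCAR missingness on the brain phenotypes;
2. a multivariate amygdala/white-matter/ICV signature over waves 1-3
   that predicts the autism diagnosis with 100% accuracy;
3. a sensitive period where behavior changes drive frontal-lobe
   thickness changes between waves 4 and 6, plus MAR study dropout
   tied to being male and lower parental education.
"""

from __future__ import annotations

from dataclasses import dataclass, field

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
    MARDropoutSpec,
    MCARSpec,
    apply_mcar,
    enforce_missing_cap,
    mar_dropout,
)
from ..signals import (
    ASDSignatureSpec,
    CouplingSpec,
    SensitivePeriodSpec,
    embed_asd_signature,
    embed_coupled_change,
    embed_sensitive_period,
)
from ..stats import BoundedScoreMap, cholesky_factor
from ..trajectories import (
    PolynomialTrajectory,
    fit_polynomial,
    _ANCHOR_AGES,
    _ANCHOR_VALUES,
    _SEX_RATIOS,
)
from .dpn import CHANNELS, EDUCATION_PROBS, PhenotypeCorrelationModel, DEFAULT_CBCL_MAPS

__all__ = ["PaintParams", "generate_paint_dataset"]


def _log_age_curves() -> dict[str, dict[int, PolynomialTrajectory]]:
    """Second-order log(age) fits to the reference curves, per sex."""
    out: dict[str, dict[int, PolynomialTrajectory]] = {}
    ages = np.asarray(_ANCHOR_AGES)
    for name in BRAIN_COLUMNS:
        male_vals = np.asarray(_ANCHOR_VALUES[name])
        out[name] = {
            0: fit_polynomial(ages, male_vals, degree=2, predictor="log_age"),
            1: fit_polynomial(
                ages, male_vals * _SEX_RATIOS[name], degree=2, predictor="log_age"
            ),
        }
    return out


@dataclass(frozen=True)
class PaintParams:
    """Parameter set for the paint engine."""

    correlation: PhenotypeCorrelationModel = field(
        default_factory=PhenotypeCorrelationModel
    )
    autism_prevalence: float = 0.03
    sd_fraction: float = 0.06  # normative spread as fraction of the mean
    noise_sd: float = 0.10  # per-datapoint noise, z-units
    z_bound: float = 4.0
    iq_noise_sd: float = 3.0
    education_probs: tuple[float, ...] = EDUCATION_PROBS
    cbcl_maps: dict[str, BoundedScoreMap] = field(
        default_factory=lambda: dict(DEFAULT_CBCL_MAPS)
    )
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    signature: ASDSignatureSpec = field(default_factory=ASDSignatureSpec)
    sensitive_period: SensitivePeriodSpec = field(
        default_factory=SensitivePeriodSpec
    )
    mcar: MCARSpec = field(default_factory=lambda: MCARSpec(rate=0.10))
    mar: MARDropoutSpec = field(default_factory=MARDropoutSpec)


def generate_paint_base(
    seed: int,
    n_subjects: int,
    variant: int,
    params: PaintParams,
    schedule: WaveSchedule,
) -> LongTable:
    """The common pre-embedding simulation for every paint variant."""
    site = f"paint_data{variant}"
    rngs = derive_seeds(
        seed,
        [
            f"{site}/statics",
            f"{site}/timeline",
            f"{site}/baseline",
            f"{site}/noise",
            f"{site}/autism",
            f"{site}/iq",
        ],
    )
    n, w = n_subjects, schedule.n_waves
    names = params.correlation.phenotype_names
    dictionary = default_data_dictionary()
    curves = _log_age_curves()

    sex = (rngs[f"{site}/statics"].uniform(size=n) < 0.5).astype(np.int64)
    probs = np.asarray(params.education_probs)
    education = (
        rngs[f"{site}/statics"].choice(np.arange(len(probs)), size=n, p=probs)
    ).astype(np.int64)
    autism = (
        rngs[f"{site}/autism"].uniform(size=n) < params.autism_prevalence
    ).astype(np.int64)
    dobs, dates, ages = sample_timelines(rngs[f"{site}/timeline"], n, schedule)

    L = cholesky_factor(params.correlation.R)
    z0 = rngs[f"{site}/baseline"].standard_normal((n, len(names))) @ L.T
    z0 = np.clip(z0, -params.z_bound, params.z_bound)
    noise = rngs[f"{site}/noise"].standard_normal((n, w, len(names))) * params.noise_sd
    z_obs = z0[:, None, :] + noise

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
    for name in BRAIN_COLUMNS:
        j = names.index(name)
        mean = np.where(
            sex_flat == 1,
            curves[name][1](age_flat),
            curves[name][0](age_flat),
        )
        sd = params.sd_fraction * np.abs(mean)
        raw = mean + z_obs[:, :, j].ravel() * sd
        lo, hi = dictionary[name].allowed_range
        obs[name] = np.clip(raw, lo, hi)

    iq_true = 100.0 + 15.0 * z0[:, names.index("iq")]
    eps = rngs[f"{site}/iq"].standard_normal((n, w)) * params.iq_noise_sd
    shrink = 15.0 / np.sqrt(15.0**2 + params.iq_noise_sd**2)
    iq_obs = 100.0 + (iq_true[:, None] - 100.0 + eps) * shrink
    obs["iq"] = np.clip(iq_obs.ravel(), *dictionary["iq"].allowed_range)

    for name in CBCL_COLUMNS:
        j = names.index(name)
        obs[name] = pd.array(
            params.cbcl_maps[name](z_obs[:, :, j].ravel()), dtype="Int64"
        )

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


def generate_paint_dataset(
    seed: int = 0,
    n_subjects: int = 10_000,
    variant: int = 1,
    params: PaintParams | None = None,
    schedule: WaveSchedule | None = None,
) -> LongTable:
    """End-to-end paint generation: base process + variant embedding."""
    if variant not in (1, 2, 3):
        raise ValueError("variant must be 1, 2 or 3")
    params = params or PaintParams()
    schedule = schedule or WaveSchedule()
    site = f"paint_data{variant}"
    table = generate_paint_base(seed, n_subjects, variant, params, schedule)
    rngs = derive_seeds(
        seed, [f"{site}/signal", f"{site}/missing", f"{site}/cap"]
    )
    if variant == 1:
        table = embed_coupled_change(table, params.coupling, rngs[f"{site}/signal"])
        table = apply_mcar(table, params.mcar, rngs[f"{site}/missing"])
    elif variant == 2:
        table = embed_asd_signature(table, params.signature, rngs[f"{site}/signal"])
    else:
        table = embed_sensitive_period(
            table, params.sensitive_period, rngs[f"{site}/signal"]
        )
        pristine = table.copy()
        table = mar_dropout(table, params.mar, rngs[f"{site}/missing"])
        table, _ = enforce_missing_cap(table, pristine, rng=rngs[f"{site}/cap"])
    return table
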