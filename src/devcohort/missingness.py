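"""Attrition mechanisms: MCAR, MAR and MNAR missingness, plus the 20% cap.

All mechanisms take and return :class:`~devcohort.schema.LongTable` objects
and only ever blank measure cells — rows are never deleted, so row counts
are invariant under every mechanism.  Missingness flavors:

* MCAR cell deletion, independent of everything;
* wave-level dropout with log-odds increasing over waves and shifted by
  sex, parental education and concurrent psychopathology (non-absorbing:
  a subject can return at a later wave);
* scan-level MRI dropout decaying exponentially over waves (young
  children miss scans most often);
* MNAR psychopathology dropout where the *true* symptom score raises the
  log-odds that its own measurement is missing;
* subject-level absorbing study dropout driven by sex and parental
  education only (MAR given the statics).

The cap enforcer restores a seeded uniform subset of deleted cells until
the global missing fraction is within the cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import BRAIN_COLUMNS, CBCL_COLUMNS, MEASURE_COLUMNS, LongTable
from .stats import logistic
from .validation import MISSING_CAP

__all__ = [
    "MCARSpec",
    "WaveDropoutModel",
    "MeasureDropoutModel",
    "MARDropoutSpec",
    "apply_mcar",
    "wave_dropout",
    "mri_measure_dropout",
    "mnar_psych_dropout",
    "mar_dropout",
    "enforce_missing_cap",
]


@dataclass(frozen=True)
class MCARSpec:
    """Independent cell deletion at a fixed rate."""

    rate: float = 0.10
    columns: tuple[str, ...] = BRAIN_COLUMNS

    def __post_init__(self) -> None:
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must be in [0, 1]")


@dataclass(frozen=True)
class WaveDropoutModel:
    """Logistic wave-level dropout.

    log-odds = intercept_w + male_coef*[sex==0] + education_coef*education
    + psych_coef*psych_score.  Intercepts must be non-decreasing over waves
    (dropout becomes more likely later in the study); male and symptom
    coefficients raise dropout, the education coefficient lowers it for
    better-educated households.
    """

    intercepts: tuple[float, ...] = (-3.2, -3.0, -2.8, -2.6, -2.4, -2.2, -2.0)
    male_coef: float = 0.3
    education_coef: float = -0.2
    psych_coef: float = 0.03

    def __post_init__(self) -> None:
        if np.any(np.diff(self.intercepts) < 0):
            raise ValueError("wave intercepts must be non-decreasing")


@dataclass(frozen=True)
class MeasureDropoutModel:
    """Measure-specific dropout: exponential MRI decay + MNAR psych model.

    MRI scan missed at wave w with probability ``p1 * exp(-kappa*(w-1))``;
    a psychopathology score is missing with log-odds
    ``psych_intercept + psych_slope * true_score``.
    """

    mri_p1: float = 0.10
    mri_kappa: float = 0.5
    psych_intercept: float = -3.0
    psych_slope: float = 0.08

    def __post_init__(self) -> None:
        if self.mri_kappa < 0:
            raise ValueError("kappa must be non-negative")
        if not 0.0 <= self.mri_p1 <= 1.0:
            raise ValueError("mri_p1 must be a probability")

    def mri_rate(self, wave: np.ndarray) -> np.ndarray:
        return self.mri_p1 * np.exp(-self.mri_kappa * (np.asarray(wave) - 1))


@dataclass(frozen=True)
class MARDropoutSpec:
    """Absorbing study dropout from sex and parental education only."""

    intercept: float = -2.2
    male_coef: float = 0.5
    education_coef: float = -0.35


def _blank(frame: pd.DataFrame, mask: np.ndarray, columns) -> None:
    for c in columns:
        col_mask = mask if mask.ndim == 1 else mask[:, list(columns).index(c)]
        frame.loc[col_mask, c] = np.nan


def apply_mcar(
    table: LongTable, spec: MCARSpec, rng: np.random.Generator
) -> LongTable:
    """Blank each targeted cell independently with probability ``rate``."""
    out = table.copy()
    n = len(out)
    for c in spec.columns:
        mask = rng.uniform(size=n) < spec.rate
        out.frame.loc[mask, c] = np.nan
    return out


def _psych_score(frame: pd.DataFrame) -> np.ndarray:
    """Default symptom-load predictor: externalizing + internalizing sums."""
    ext = pd.to_numeric(frame[CBCL_COLUMNS[0]]).to_numpy(dtype=float)
    internal = pd.to_numeric(frame[CBCL_COLUMNS[1]]).to_numpy(dtype=float)
    score = np.nan_to_num(ext, nan=np.nanmean(ext) if np.isfinite(np.nanmean(ext)) else 0.0)
    score = score + np.nan_to_num(
        internal, nan=np.nanmean(internal) if np.isfinite(np.nanmean(internal)) else 0.0
    )
    return score


def wave_dropout(
    table: LongTable,
    model: WaveDropoutModel,
    rng: np.random.Generator,
    psych_scores: np.ndarray | None = None,
) -> LongTable:
    """Per-row stochastic wave dropout; dropped waves lose all measures."""
    out = table.copy()
    f = out.frame
    wave = f["wave_number"].to_numpy(dtype=int)
    intercept = np.asarray(model.intercepts, dtype=float)[wave - 1]
    male = (f["sex"].to_numpy(dtype=int) == 0).astype(float)
    edu = f["parental_education"].to_numpy(dtype=float)
    edu = np.where(edu == 777, np.nan, edu)
    edu = np.nan_to_num(edu, nan=float(np.nanmean(edu)) if np.isfinite(np.nanmean(edu)) else 1.5)
    psych = _psych_score(f) if psych_scores is None else np.asarray(psych_scores, float)
    p = logistic(
        intercept
        + model.male_coef * male
        + model.education_coef * edu
        + model.psych_coef * psych
    )
    dropped = rng.uniform(size=len(f)) < p
    _blank(f, dropped, MEASURE_COLUMNS)
    return out


def mri_measure_dropout(
    table: LongTable, model: MeasureDropoutModel, rng: np.random.Generator
) -> LongTable:
    """Scan-level MRI dropout with exponentially decaying per-wave rate."""
    out = table.copy()
    f = out.frame
    wave = f["wave_number"].to_numpy(dtype=int)
    p = model.mri_rate(wave)
    missed = rng.uniform(size=len(f)) < p
    _blank(f, missed, BRAIN_COLUMNS)
    return out


def mnar_psych_dropout(
    table: LongTable,
    true_scores: pd.DataFrame,
    model: MeasureDropoutModel,
    rng: np.random.Generator,
) -> LongTable:
    """MNAR deletion of each CBCL score driven by its own true value.

    ``true_scores`` holds the pre-deletion CBCL columns aligned with the
    table's rows; the observed-score mean falls below the true mean when
    the slope is positive (severe non-ignorability).
    """
    out = table.copy()
    f = out.frame
    for c in CBCL_COLUMNS:
        truth = pd.to_numeric(true_scores[c]).to_numpy(dtype=float)
        p = logistic(model.psych_intercept + model.psych_slope * truth)
        missed = rng.uniform(size=len(f)) < p
        f.loc[missed, c] = np.nan
    return out


def mar_dropout(
    table: LongTable, spec: MARDropoutSpec, rng: np.random.Generator
) -> LongTable:
    """Absorbing subject-level dropout from observed statics only.

    A subject drops out with logistic probability in sex and parental
    education; a dropout wave is drawn uniformly from waves 2..W and all
    measures from that wave onward are blanked.
    """
    out = table.copy()
    f = out.frame
    statics = f.drop_duplicates("subject_id").set_index("subject_id")
    male = (statics["sex"].to_numpy(dtype=int) == 0).astype(float)
    edu = statics["parental_education"].to_numpy(dtype=float)
    edu = np.where(edu == 777, 1.5, edu)
    p = logistic(spec.intercept + spec.male_coef * male + spec.education_coef * edu)
    drops = rng.uniform(size=len(statics)) < p
    n_waves = int(f["wave_number"].max())
    start_wave = rng.integers(2, n_waves + 1, size=len(statics))
    dropout_wave = pd.Series(
        np.where(drops, start_wave, n_waves + 1), index=statics.index
    )
    row_cut = f["subject_id"].map(dropout_wave).to_numpy()
    mask = f["wave_number"].to_numpy(dtype=int) >= row_cut
    _blank(f, mask, MEASURE_COLUMNS)
    return out


def enforce_missing_cap(
    table: LongTable,
    original: LongTable | None = None,
    cap: float = MISSING_CAP,
    rng: np.random.Generator | None = None,
) -> tuple[LongTable, int]:
    """Restore deleted cells until the missing fraction is within ``cap``.

    Restorations are drawn uniformly (seeded) from the cells that are
    missing in ``table`` but present in ``original``.  Returns the capped
    table and the number of restored cells.  Raises if the cap cannot be
    met without the original values.
    """
    cols = list(MEASURE_COLUMNS)
    values = table.frame.loc[:, cols]
    missing = values.isna().to_numpy()
    total = missing.size
    allowed = int(np.floor(cap * total))
    n_missing = int(missing.sum())
    if n_missing <= allowed:
        return table, 0
    if original is None:
        raise ValueError(
            f"missing fraction {n_missing / total:.3f} exceeds cap {cap:.2f} "
            "and no original table was supplied for restoration"
        )
    orig_vals = original.frame.loc[:, cols]
    restorable = missing & orig_vals.notna().to_numpy()
    idx = np.flatnonzero(restorable.ravel())
    need = n_missing - allowed
    if len(idx) < need:
        raise ValueError("not enough restorable cells to satisfy the cap")
    if rng is None:
        rng = np.random.default_rng(0)
    chosen = rng.choice(idx, size=need, replace=False)
    rows, col_pos = np.unravel_index(chosen, missing.shape)
    out = table.copy()
    arr = values.to_numpy(dtype=float)
    arr_orig = orig_vals.to_numpy(dtype=float)
    arr[rows, col_pos] = arr_orig[rows, col_pos]
    for j, c in enumerate(cols):
        if c in CBCL_COLUMNS:
            out.frame[c] = pd.array(arr[:, j], dtype="Int64")
        else:
            out.frame[c] = arr[:, j]
    return out, int(need)
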