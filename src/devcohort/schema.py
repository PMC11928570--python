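"""Shared data model for simulated developmental cohorts.

All five generative engines emit the same long-format table: one row per
subject per wave, 19 columns, covering demographics, cognition (IQ),
behavior (three CBCL raw subscale scores) and six anatomical MRI-derived
measures.  This module owns the data dictionary (column names, types,
ranges), the wave/age conventions (7 biennial waves spanning 7-20 years of
age, ages recorded in completed chronological months), and CSV round-trip
serialization.

Missing timepoints are represented as rows whose measure columns are blank,
never as deleted rows, so every default-sized table has exactly
``n_subjects * n_waves`` rows.
"""

from __future__ import annotations

import calendar
import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ColumnSpec",
    "DataDictionary",
    "WaveSchedule",
    "LongTable",
    "COLUMN_ORDER",
    "MEASURE_COLUMNS",
    "BRAIN_COLUMNS",
    "CBCL_COLUMNS",
    "default_data_dictionary",
    "compute_age_months",
    "sample_subject_timeline",
    "sample_timelines",
    "assemble_long_table",
    "write_csv",
    "read_csv",
]

# Day-residual threshold for chronological-month rounding: a residual of at
# most 15 days does not advance the month, 16 or more does.
_MONTH_ADVANCE_DAYS = 16

#: The 19 data-dictionary columns, in canonical order.
COLUMN_ORDER = (
    "subject_id",
    "site_id",
    "dob",
    "brain_behavior_measurement_date",
    "wave_number",
    "autism_diagnosis",
    "age",
    "sex",
    "parental_education",
    "cbcl_externalizing_raw_score",
    "cbcl_internalizing_raw_score",
    "cbcl_attentionproblem_raw_score",
    "iq",
    "wm_volume",
    "gm_volume",
    "hippo_volume",
    "amygdala_volume",
    "frontal_lobe_gm_thickness",
    "icv",
)

#: Six anatomical measures (mm^3 for volumes, mm for thickness).
BRAIN_COLUMNS = (
    "wm_volume",
    "gm_volume",
    "hippo_volume",
    "amygdala_volume",
    "frontal_lobe_gm_thickness",
    "icv",
)

#: CBCL raw subscale scores (integer sums with hard ranges).
CBCL_COLUMNS = (
    "cbcl_externalizing_raw_score",
    "cbcl_internalizing_raw_score",
    "cbcl_attentionproblem_raw_score",
)

#: The nullable measure columns — the denominator of every missingness
#: fraction.  Identifiers, dates, demographics and wave_number are never
#: missing.
MEASURE_COLUMNS = CBCL_COLUMNS + ("iq",) + BRAIN_COLUMNS


@dataclass(frozen=True)
class ColumnSpec:
    """Schema entry for one data-dictionary column."""

    name: str
    dtype: str  # one of: integer, real, date, string
    allowed_range: tuple[float, float] | None = None
    allowed_codes: frozenset | None = None
    required: bool = True
    missing_allowed: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        if self.dtype not in ("integer", "real", "date", "string"):
            raise ValueError(f"unknown dtype {self.dtype!r} for {self.name}")

    def value_in_range(self, values: pd.Series) -> pd.Series:
        """Boolean mask of non-missing values satisfying the range/codes."""
        ok = pd.Series(True, index=values.index)
        present = values.notna()
        if self.allowed_codes is not None:
            ok &= ~present | values.isin(list(self.allowed_codes))
        elif self.allowed_range is not None:
            lo, hi = self.allowed_range
            numeric = pd.to_numeric(values, errors="coerce")
            ok &= ~present | ((numeric >= lo) & (numeric <= hi))
        return ok


@dataclass(frozen=True)
class DataDictionary:
    """Ordered collection of the 19 column specs."""

    columns: tuple[ColumnSpec, ...]

    def __post_init__(self) -> None:
        names = tuple(c.name for c in self.columns)
        if len(set(names)) != len(names):
            raise ValueError("duplicate column names in dictionary")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.columns)

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def __len__(self) -> int:
        return len(self.columns)


# Default range bounds for the brain measures.  Table-style dictionary ranges
# exist only for the scored columns; the anatomical bounds below are the
# "realistic values based on the literature" used by the range check, and are
# configurable via the validator.
_BRAIN_RANGES = {
    "wm_volume": (3.0e5, 6.5e5),
    "gm_volume": (4.0e5, 9.0e5),
    "hippo_volume": (2500.0, 5500.0),
    "amygdala_volume": (1800.0, 4500.0),
    "frontal_lobe_gm_thickness": (1.5, 4.5),
    "icv": (1.0e6, 2.0e6),
}


def default_data_dictionary() -> DataDictionary:
    """The 19-column data dictionary shared by every engine.

    Column order, names, types and ranges follow the published dictionary:
    CBCL externalizing 0-70, internalizing 0-64, attention problems 0-20;
    sex 0=male / 1=female; parental education coded 0-3 with 777=refused;
    IQ on the general-population scale (mean 100, sd 15); dates ISO8601.
    """
    cols = [
        ColumnSpec("subject_id", "string", description="Subject Id"),
        ColumnSpec("site_id", "string", description="Site Id"),
        ColumnSpec("dob", "date", description="Date of birth (YYYY-MM-DD)"),
        ColumnSpec(
            "brain_behavior_measurement_date",
            "date",
            description="Measurement date for this wave (YYYY-MM-DD)",
        ),
        ColumnSpec(
            "wave_number",
            "integer",
            allowed_codes=frozenset(range(1, 8)),
            description="Wave number, 1 to 7",
        ),
        ColumnSpec(
            "autism_diagnosis",
            "integer",
            allowed_codes=frozenset({0, 1}),
            description="0: no, 1: yes",
        ),
        ColumnSpec(
            "age",
            "integer",
            allowed_range=(84, 251),
            description="Age in completed chronological months",
        ),
        ColumnSpec(
            "sex",
            "integer",
            allowed_codes=frozenset({0, 1}),
            description="Sex at birth, 0: male, 1: female",
        ),
        ColumnSpec(
            "parental_education",
            "integer",
            allowed_codes=frozenset({0, 1, 2, 3, 777}),
            description=(
                "Highest parental education: 0 <12th grade, 1 high school/GED,"
                " 2 bachelor's, 3 master's or higher, 777 refused"
            ),
        ),
        ColumnSpec(
            "cbcl_externalizing_raw_score",
            "integer",
            allowed_range=(0, 70),
            missing_allowed=True,
            description="CBCL externalizing raw sum, range 0-70",
        ),
        ColumnSpec(
            "cbcl_internalizing_raw_score",
            "integer",
            allowed_range=(0, 64),
            missing_allowed=True,
            description="CBCL internalizing raw sum, range 0-64",
        ),
        ColumnSpec(
            "cbcl_attentionproblem_raw_score",
            "integer",
            allowed_range=(0, 20),
            missing_allowed=True,
            description="CBCL attention problems raw sum, range 0-20",
        ),
        ColumnSpec(
            "iq",
            "real",
            allowed_range=(40.0, 160.0),
            missing_allowed=True,
            description="IQ score, general population mean 100, sd 15",
        ),
    ]
    descr = {
        "wm_volume": "White matter volume, mm^3",
        "gm_volume": "Gray matter volume, mm^3",
        "hippo_volume": "Hippocampal volume, mm^3",
        "amygdala_volume": "Amygdala volume, mm^3",
        "frontal_lobe_gm_thickness": "Frontal lobe cortical thickness, mm",
        "icv": "Intracranial volume, mm^3",
    }
    for name in BRAIN_COLUMNS:
        cols.append(
            ColumnSpec(
                name,
                "real",
                allowed_range=_BRAIN_RANGES[name],
                missing_allowed=True,
                description=descr[name],
            )
        )
    cols = tuple(sorted(cols, key=lambda c: COLUMN_ORDER.index(c.name)))
    return DataDictionary(columns=cols)


@dataclass(frozen=True)
class WaveSchedule:
    """Wave layout: per-wave closed age windows in months.

    Default: 7 biennial waves, wave ``w`` covering ages
    ``[84 + 24*(w-1), 107 + 24*(w-1)]`` months, i.e. 7-8 years at wave 1 up
    to 19-20 years at wave 7 (inclusive of the final chronological month of
    the upper year).
    """

    n_waves: int = 7
    age_window_months: tuple[tuple[int, int], ...] = field(
        default_factory=lambda: tuple(
            (84 + 24 * w, 107 + 24 * w) for w in range(7)
        )
    )
    spacing_jitter_months: float = 2.0

    def __post_init__(self) -> None:
        if self.n_waves != len(self.age_window_months):
            raise ValueError("one age window per wave required")
        if self.spacing_jitter_months < 0:
            raise ValueError("jitter must be non-negative")
        for lo, hi in self.age_window_months:
            if lo > hi:
                raise ValueError(f"empty age window ({lo}, {hi})")


def _add_months(d: dt.date, months: int) -> dt.date:
    """Calendar month addition with day-of-month clamping."""
    m = d.month - 1 + months
    year = d.year + m // 12
    month = m % 12 + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def compute_age_months(dob: dt.date, measurement_date: dt.date) -> int:
    """Age in chronological months at ``measurement_date``.

    Completed months between the dates; a day residual of 15 days or fewer
    does not advance the month, 16 or more does.  A 15-day-old infant is 0
    months, a 16-day-old is 1 month.
    """
    if measurement_date < dob:
        raise ValueError("measurement_date precedes date of birth")
    months = (
        (measurement_date.year - dob.year) * 12
        + measurement_date.month
        - dob.month
    )
    anchor = _add_months(dob, months)
    if anchor > measurement_date:
        months -= 1
        anchor = _add_months(dob, months)
    residual = (measurement_date - anchor).days
    return months + (1 if residual >= _MONTH_ADVANCE_DAYS else 0)


def sample_subject_timeline(
    rng: np.random.Generator,
    schedule: WaveSchedule = WaveSchedule(),
    study_start_window: tuple[dt.date, dt.date] = (
        dt.date(2008, 1, 1),
        dt.date(2012, 12, 31),
    ),
) -> tuple[dt.date, list[dt.date], list[int]]:
    """Draw one subject's dob, per-wave measurement dates and ages.

    Wave-1 age is uniform over the wave-1 window; later waves are spaced
    about 24 months apart with Gaussian jitter, clipped into each wave's
    window.  Ages are exact under :func:`compute_age_months` by
    construction.
    """
    dobs, dates, ages = sample_timelines(rng, 1, schedule, study_start_window)
    return dobs[0], list(dates[0]), [int(a) for a in ages[0]]


def sample_timelines(
    rng: np.random.Generator,
    n: int,
    schedule: WaveSchedule = WaveSchedule(),
    study_start_window: tuple[dt.date, dt.date] = (
        dt.date(2008, 1, 1),
        dt.date(2012, 12, 31),
    ),
) -> tuple[list[dt.date], list[list[dt.date]], np.ndarray]:
    """Vectorized subject timelines: dobs, dates (n x waves), ages (months)."""
    start, end = study_start_window
    span = (end - start).days
    if span < 0:
        raise ValueError("empty study start window")
    w = schedule.n_waves
    lo = np.array([win[0] for win in schedule.age_window_months])
    hi = np.array([win[1] for win in schedule.age_window_months])

    # Target integer ages: wave-1 uniform in its window, then ~24-month steps
    # with jitter, clipped into each window and kept strictly increasing.
    ages = np.empty((n, w), dtype=np.int64)
    ages[:, 0] = rng.integers(lo[0], hi[0] + 1, size=n)
    for j in range(1, w):
        step = 24 + np.rint(
            rng.normal(0.0, schedule.spacing_jitter_months, size=n)
        ).astype(np.int64)
        a = np.clip(ages[:, j - 1] + step, lo[j], hi[j])
        a = np.maximum(a, ages[:, j - 1] + 1)  # dates must advance
        ages[:, j] = np.minimum(a, hi[j])

    wave1_offsets = rng.integers(0, span + 1, size=n)
    extra_days = rng.integers(0, _MONTH_ADVANCE_DAYS, size=(n, w))

    dobs: list[dt.date] = []
    dates: list[list[dt.date]] = []
    for i in range(n):
        wave1 = start + dt.timedelta(days=int(wave1_offsets[i]))
        dob = wave1 - dt.timedelta(days=round(int(ages[i, 0]) * 30.4375))
        if dob.day > 28:  # keep month addition free of day clamping
            dob = dob.replace(day=28)
        dobs.append(dob)
        row = [
            _add_months(dob, int(ages[i, j]))
            + dt.timedelta(days=int(extra_days[i, j]))
            for j in range(w)
        ]
        dates.append(row)
    return dobs, dates, ages


class LongTable:
    """In-memory long-format dataset: one row per subject-wave, 19 columns."""

    def __init__(self, frame: pd.DataFrame, check: bool = True):
        if check:
            missing = [c for c in COLUMN_ORDER if c not in frame.columns]
            if missing:
                raise ValueError(f"missing columns: {missing}")
            dup = frame.duplicated(subset=["subject_id", "wave_number"])
            if dup.any():
                raise ValueError(
                    f"{int(dup.sum())} duplicate (subject_id, wave_number) pairs"
                )
        self.frame = frame.loc[:, list(COLUMN_ORDER)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    def missing_fraction(
        self, columns: Sequence[str] = MEASURE_COLUMNS
    ) -> float:
        """Fraction of missing cells over the nullable measure columns."""
        sub = self.frame.loc[:, list(columns)]
        return float(sub.isna().to_numpy().mean())

    def copy(self) -> "LongTable":
        return LongTable(self.frame.copy(), check=False)


def assemble_long_table(
    statics: pd.DataFrame, observations: pd.DataFrame
) -> LongTable:
    """Join per-subject statics with per-wave observations.

    ``statics`` carries one row per subject (subject_id, site_id, dob, sex,
    parental_education, autism_diagnosis); ``observations`` one row per
    subject-wave with the remaining dictionary columns.
    """
    static_cols = {
        "subject_id",
        "site_id",
        "dob",
        "sex",
        "parental_education",
        "autism_diagnosis",
    }
    if statics["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_id in statics")
    need = static_cols - set(statics.columns)
    if need:
        raise ValueError(f"statics missing {sorted(need)}")
    merged = observations.merge(statics, on="subject_id", how="left", validate="many_to_one")
    return LongTable(merged)


def _round_values(frame: pd.DataFrame) -> pd.DataFrame:
    """Apply the declared numeric precision used for CSV serialization."""
    out = frame.copy()
    for c in CBCL_COLUMNS:
        out[c] = pd.array(np.round(pd.to_numeric(out[c]).to_numpy(dtype=float)), dtype="Int64")
    out["iq"] = pd.to_numeric(out["iq"]).round(1)
    for c in ("wm_volume", "gm_volume", "hippo_volume", "amygdala_volume", "icv"):
        out[c] = pd.to_numeric(out[c]).round(1)
    out["frontal_lobe_gm_thickness"] = pd.to_numeric(
        out["frontal_lobe_gm_thickness"]
    ).round(3)
    return out


def write_csv(table: LongTable, path, missing_token: str = "") -> None:
    """Serialize to CSV: 19-column header, ISO8601 dates, blank missing."""
    frame = _round_values(table.frame)
    for c in ("dob", "brain_behavior_measurement_date"):
        frame[c] = pd.to_datetime(frame[c]).dt.strftime("%Y-%m-%d")
    frame.to_csv(path, index=False, na_rep=missing_token)


def read_csv(path) -> LongTable:
    """Read a dictionary-conforming CSV; blank and ``NA`` mean missing."""
    header = pd.read_csv(path, nrows=0)
    absent = [c for c in COLUMN_ORDER if c not in header.columns]
    if absent:
        raise ValueError(f"file lacks required columns: {absent}")
    unknown = [c for c in header.columns if c not in COLUMN_ORDER]
    if unknown:
        raise ValueError(f"file has unknown columns: {unknown}")
    frame = pd.read_csv(
        path,
        na_values=["", "NA"],
        keep_default_na=False,
        dtype={"subject_id": str, "site_id": str},
    )
    for c in ("dob", "brain_behavior_measurement_date"):
        frame[c] = pd.to_datetime(frame[c], format="%Y-%m-%d")
    for c in ("wave_number", "autism_diagnosis", "age", "sex", "parental_education"):
        frame[c] = pd.to_numeric(frame[c]).astype(np.int64)
    for c in CBCL_COLUMNS:
        frame[c] = pd.array(pd.to_numeric(frame[c]), dtype="Int64")
    for c in ("iq",) + tuple(b for b in BRAIN_COLUMNS):
        frame[c] = pd.to_numeric(frame[c]).astype(float)
    return LongTable(frame)
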