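"""Quality checks applied to every generated dataset.

Four checks mirror the submission gate the simulated cohorts must pass:
every required column present with parseable values of the declared type,
the expected row count, all non-missing values within their allowed ranges,
and no more than 20% missing cells over the nullable measure columns.
Failures are reported, not raised, so a report can list every problem at
once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schema import (
    COLUMN_ORDER,
    MEASURE_COLUMNS,
    DataDictionary,
    LongTable,
    default_data_dictionary,
    read_csv,
)

__all__ = [
    "CheckResult",
    "ValidationReport",
    "check_columns",
    "check_row_count",
    "check_ranges",
    "check_missingness",
    "validate_dataset",
    "MISSING_CAP",
]

#: Global cap on the fraction of missing measure cells.
MISSING_CAP = 0.20


@dataclass(frozen=True)
class CheckResult:
    check_name: str
    passed: bool
    detail: str = ""
    offending_columns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.passed and not self.detail:
            raise ValueError("failed checks must carry a detail message")


@dataclass(frozen=True)
class ValidationReport:
    results: tuple[CheckResult, ...]

    @property
    def overall_pass(self) -> bool:
        return all(r.passed for r in self.results)

    def failures(self) -> tuple[CheckResult, ...]:
        return tuple(r for r in self.results if not r.passed)

    def to_text(self) -> str:
        lines = []
        for r in self.results:
            status = "PASS" if r.passed else "FAIL"
            line = f"[{status}] {r.check_name}"
            if r.detail:
                line += f": {r.detail}"
            lines.append(line)
        lines.append(
            "overall: " + ("PASS" if self.overall_pass else "FAIL")
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "overall_pass": self.overall_pass,
            "checks": [
                {
                    "check_name": r.check_name,
                    "passed": r.passed,
                    "detail": r.detail,
                    "offending_columns": list(r.offending_columns),
                }
                for r in self.results
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _parseable(values: pd.Series, dtype: str) -> bool:
    present = values.dropna()
    if dtype == "string":
        return True
    if dtype == "date":
        if pd.api.types.is_datetime64_any_dtype(values):
            return True
        try:
            pd.to_datetime(present, format="%Y-%m-%d")
            return True
        except (ValueError, TypeError):
            return False
    numeric = pd.to_numeric(present, errors="coerce")
    if numeric.isna().any():
        return False
    if dtype == "integer":
        return bool(np.allclose(numeric.to_numpy(dtype=float) % 1.0, 0.0))
    return True


def check_columns(
    frame: pd.DataFrame, dictionary: DataDictionary | None = None
) -> CheckResult:
    """Every required column present and parseable as its declared type."""
    dictionary = dictionary or default_data_dictionary()
    absent = [c.name for c in dictionary.columns if c.name not in frame.columns]
    bad_type = [
        c.name
        for c in dictionary.columns
        if c.name in frame.columns and not _parseable(frame[c.name], c.dtype)
    ]
    offending = absent + bad_type
    if offending:
        parts = []
        if absent:
            parts.append(f"missing columns: {absent}")
        if bad_type:
            parts.append(f"unparseable as declared type: {bad_type}")
        return CheckResult("columns", False, "; ".join(parts), tuple(offending))
    return CheckResult("columns", True)


def check_row_count(frame: pd.DataFrame, expected: int) -> CheckResult:
    """Row count equals the expected n_subjects * n_waves."""
    if expected <= 0:
        raise ValueError("expected row count must be positive")
    n = len(frame)
    if n != expected:
        return CheckResult(
            "row_count", False, f"found {n} rows, expected {expected}"
        )
    return CheckResult("row_count", True)


def check_ranges(
    frame: pd.DataFrame, dictionary: DataDictionary | None = None
) -> CheckResult:
    """No non-missing value outside its allowed range or code set."""
    dictionary = dictionary or default_data_dictionary()
    offending: list[str] = []
    details: list[str] = []
    for col in dictionary.columns:
        if col.name not in frame.columns:
            continue
        if col.allowed_range is None and col.allowed_codes is None:
            continue
        ok = col.value_in_range(frame[col.name])
        bad = int((~ok).sum())
        if bad:
            offending.append(col.name)
            details.append(f"{col.name}: {bad} out-of-range values")
    if offending:
        return CheckResult("ranges", False, "; ".join(details), tuple(offending))
    return CheckResult("ranges", True)


def check_missingness(frame: pd.DataFrame, cap: float = MISSING_CAP) -> CheckResult:
    """Missing fraction over nullable measure columns at most ``cap``."""
    cols = [c for c in MEASURE_COLUMNS if c in frame.columns]
    if not cols:
        return CheckResult("missingness", False, "no measure columns present")
    frac = float(frame.loc[:, cols].isna().to_numpy().mean())
    if frac > cap:
        return CheckResult(
            "missingness",
            False,
            f"missing fraction {frac:.4f} exceeds cap {cap:.2f}",
            tuple(cols),
        )
    return CheckResult("missingness", True, f"missing fraction {frac:.4f}")


def validate_dataset(
    table,
    dictionary: DataDictionary | None = None,
    expected_rows: int | None = None,
) -> ValidationReport:
    """Run all checks on a table, LongTable, or CSV path."""
    dictionary = dictionary or default_data_dictionary()
    if isinstance(table, LongTable):
        frame = table.frame
    elif isinstance(table, pd.DataFrame):
        frame = table
    else:  # path-like
        try:
            frame = read_csv(table).frame
        except ValueError as exc:
            # structurally unreadable: report column failure plus row count
            results = [
                CheckResult("columns", False, str(exc)),
            ]
            if expected_rows is not None:
                try:
                    n = len(pd.read_csv(table))
                except Exception:
                    n = 0
                results.append(check_row_count(pd.DataFrame(index=range(n)), expected_rows))
            return ValidationReport(tuple(results))
    results = [check_columns(frame, dictionary)]
    if expected_rows is not None:
        results.append(check_row_count(frame, expected_rows))
    results.append(check_ranges(frame, dictionary))
    results.append(check_missingness(frame))
    return ValidationReport(tuple(results))
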