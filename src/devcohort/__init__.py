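"""devcohort: simulated longitudinal brain-behavior-cognition cohorts.

Five independent generative engines produce datasets with a shared
19-column data dictionary — 10,000 children followed over 7 biennial
waves from ages 7 to 20 — with configurable missingness mechanisms,
embedded ground-truth signals, and a technical-validation checker.
"""

__version__ = "0.1.0"

from .schema import (  # noqa: F401
    BRAIN_COLUMNS,
    CBCL_COLUMNS,
    COLUMN_ORDER,
    MEASURE_COLUMNS,
    LongTable,
    WaveSchedule,
    compute_age_months,
    default_data_dictionary,
    read_csv,
    write_csv,
)
from .validation import validate_dataset, ValidationReport  # noqa: F401
from .reports import summarize  # noqa: F401

__all__ = [
    "__version__",
    "BRAIN_COLUMNS",
    "CBCL_COLUMNS",
    "COLUMN_ORDER",
    "MEASURE_COLUMNS",
    "LongTable",
    "WaveSchedule",
    "compute_age_months",
    "default_data_dictionary",
    "read_csv",
    "write_csv",
    "validate_dataset",
    "ValidationReport",
    "summarize",
    "EngineConfig",
    "generate",
    "load_parameter_catalog",
]


def __getattr__(name):
    # lazy to keep `import devcohort` light and avoid circular imports
    if name in ("EngineConfig", "generate", "load_parameter_catalog"):
        from . import config

        return getattr(config, name)
    raise AttributeError(name)
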