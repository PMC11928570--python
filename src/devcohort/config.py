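"""Run configuration, engine dispatch, parameter catalogs and manifests."""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .schema import LongTable, WaveSchedule, write_csv
from .seeding import derive_rng, derive_seeds
from .validation import ValidationReport, validate_dataset
from .engines.dpn import AutismModel, DPNParams, PhenotypeCorrelationModel, ZTrajectoryRange
from .engines.leer import LeerParams
from .engines.osa import CrossSectionSpec, OSAParams
from .engines.paint import PaintParams
from .engines.site4802 import Site4802Params, StaticSamplingSpec
from .engines import dpn, leer, osa, paint, site4802
from .missingness import MCARSpec

__all__ = [
    "ENGINES",
    "EngineConfig",
    "RunManifest",
    "generate",
    "load_parameter_catalog",
    "derive_seeds",
]

#: Engine name -> end-to-end generator.
ENGINES = {
    "dpn": dpn.generate_dpn_dataset,
    "leer": leer.generate_leer_dataset,
    "osa": osa.generate_osa_dataset,
    "paint": paint.generate_paint_dataset,
    "site4802": site4802.generate_site4802_dataset,
}


@dataclass(frozen=True)
class EngineConfig:
    """One generation run: engine, variant, cohort size and seed."""

    engine: str
    variant: int = 1
    n_subjects: int = 10_000
    n_waves: int = 7
    master_seed: int = 0
    parameter_set: str = "default"
    out: str | None = None

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(
                f"unknown engine {self.engine!r}; choose from {sorted(ENGINES)}"
            )
        if self.variant not in (1, 2, 3):
            raise ValueError("variant must be 1, 2 or 3")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


@dataclass(frozen=True)
class RunManifest:
    """Everything needed to reproduce a run bit-for-bit."""

    config: dict
    artifact_version: str
    generated_at: str
    validation: dict

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @staticmethod
    def from_json(text: str) -> "RunManifest":
        data = json.loads(text)
        return RunManifest(**data)


def _engine_params(catalog: dict, engine: str):
    """Materialize one engine's parameter object from catalog overrides."""
    spec = catalog.get("engines", {}).get(engine, {}) or {}

    def unknown(keys, allowed):
        extra = set(keys) - set(allowed)
        if extra:
            raise ValueError(f"unknown {engine} catalog keys: {sorted(extra)}")

    if engine == "dpn":
        unknown(spec, {"z_bound", "noise_sd", "prevalence_male", "prevalence_female", "correlation_matrix"})
        params = DPNParams()
        if "correlation_matrix" in spec and spec["correlation_matrix"] is not None:
            params = dataclasses.replace(
                params,
                correlation=PhenotypeCorrelationModel(
                    R=np.asarray(spec["correlation_matrix"], dtype=float)
                ),
            )
        if "z_bound" in spec:
            params = dataclasses.replace(
                params,
                trajectory=dataclasses.replace(
                    params.trajectory, z_bound=float(spec["z_bound"])
                ),
            )
        if "prevalence_male" in spec or "prevalence_female" in spec:
            params = dataclasses.replace(
                params,
                autism=dataclasses.replace(
                    params.autism,
                    prevalence_male=float(
                        spec.get("prevalence_male", params.autism.prevalence_male)
                    ),
                    prevalence_female=float(
                        spec.get("prevalence_female", params.autism.prevalence_female)
                    ),
                ),
            )
        return params
    if engine == "leer":
        unknown(spec, set())
        return LeerParams()
    if engine == "osa":
        unknown(spec, {"autism_prevalence_male", "autism_prevalence_female"})
        params = OSAParams()
        if spec:
            params = dataclasses.replace(
                params,
                cross_section=dataclasses.replace(
                    params.cross_section,
                    autism_prevalence_male=float(
                        spec.get(
                            "autism_prevalence_male",
                            params.cross_section.autism_prevalence_male,
                        )
                    ),
                    autism_prevalence_female=float(
                        spec.get(
                            "autism_prevalence_female",
                            params.cross_section.autism_prevalence_female,
                        )
                    ),
                ),
            )
        return params
    if engine == "paint":
        unknown(spec, {"autism_prevalence", "mcar_rate"})
        params = PaintParams()
        if "autism_prevalence" in spec:
            params = dataclasses.replace(
                params, autism_prevalence=float(spec["autism_prevalence"])
            )
        if "mcar_rate" in spec:
            params = dataclasses.replace(
                params, mcar=MCARSpec(rate=float(spec["mcar_rate"]))
            )
        return params
    if engine == "site4802":
        unknown(spec, {"autism_probability"})
        params = Site4802Params()
        if "autism_probability" in spec:
            params = dataclasses.replace(
                params,
                statics=dataclasses.replace(
                    params.statics,
                    autism_probability=float(spec["autism_probability"]),
                ),
            )
        return params
    raise ValueError(f"unknown engine {engine!r}")


def load_parameter_catalog(name_or_path: str = "default") -> dict:
    """Load and invariant-check a parameter catalog.

    Returns ``{engine: params-object}``; every parameter object's own
    validation (PSD matrices, probability sums, sign constraints) runs
    during construction, so an invalid catalog fails at load time.
    """
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") or path.exists():
        text = path.read_text()
    else:
        ref = resources.files("devcohort.catalogs") / f"{name_or_path}.yaml"
        if not ref.is_file():
            raise FileNotFoundError(f"no bundled catalog named {name_or_path!r}")
        text = ref.read_text()
    catalog = yaml.safe_load(text) or {}
    known = set(ENGINES) | {None}
    for engine in catalog.get("engines", {}) or {}:
        if engine not in known:
            raise ValueError(f"catalog refers to unknown engine {engine!r}")
    return {engine: _engine_params(catalog, engine) for engine in ENGINES}


def generate(
    config: EngineConfig,
) -> tuple[LongTable, ValidationReport, RunManifest]:
    """Dispatch to the engine, validate, and optionally write CSV+manifest.

    Raises ``RuntimeError`` if the generated table fails validation.
    """
    params = load_parameter_catalog(config.parameter_set)[config.engine]
    schedule = WaveSchedule() if config.n_waves == 7 else WaveSchedule(
        n_waves=config.n_waves,
        age_window_months=tuple(
            (84 + 24 * w, 107 + 24 * w) for w in range(config.n_waves)
        ),
    )
    table = ENGINES[config.engine](
        seed=config.master_seed,
        n_subjects=config.n_subjects,
        variant=config.variant,
        params=params,
        schedule=schedule,
    )
    expected = config.n_subjects * config.n_waves
    report = validate_dataset(table, expected_rows=expected)
    manifest = RunManifest(
        config=dataclasses.asdict(config),
        artifact_version=__version__,
        generated_at=dt.datetime.now(dt.timezone.utc).isoformat(),
        validation=report.to_dict(),
    )
    if config.out is not None:
        out = Path(config.out)
        out.parent.mkdir(parents=True, exist_ok=True)
        write_csv(table, out)
        out.with_suffix(".manifest.json").write_text(manifest.to_json())
    if not report.overall_pass:
        raise RuntimeError("generated dataset failed validation:\n" + report.to_text())
    return table, report, manifest
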