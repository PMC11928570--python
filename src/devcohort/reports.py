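"""Descriptive summaries of generated datasets for human QC.

The validator gates outputs; these summaries are advisory — they let a
human check distributions, correlations, missingness patterns and
trajectory shapes against expectations.  Everything is computed from the
table alone, with no access to generator internals.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import BRAIN_COLUMNS, MEASURE_COLUMNS, LongTable

__all__ = ["SummaryReport", "summarize", "save_figures"]


@dataclass(frozen=True)
class SummaryReport:
    variable_summary: pd.DataFrame  # per measure: moments, range, missing
    per_wave_means: pd.DataFrame  # wave x measure
    sex_trajectories: pd.DataFrame  # (sex, wave) x measure
    missingness: pd.DataFrame  # wave x measure missing fraction
    correlations: pd.DataFrame  # measure x measure (pairwise complete)

    def to_text(self) -> str:
        parts = [
            "== variable summary ==",
            self.variable_summary.round(3).to_string(),
            "\n== per-wave means ==",
            self.per_wave_means.round(2).to_string(),
            "\n== missing fraction by wave ==",
            self.missingness.round(3).to_string(),
        ]
        return "\n".join(parts)


def summarize(table: LongTable) -> SummaryReport:
    """Deterministic descriptive summary of a long-format dataset."""
    f = table.frame
    cols = list(MEASURE_COLUMNS)
    numeric = f[cols].astype("float64")  # nullable ints -> float with NaN

    variable_summary = pd.DataFrame(
        {
            "mean": numeric.mean(),
            "sd": numeric.std(),
            "min": numeric.min(),
            "max": numeric.max(),
            "n_missing": numeric.isna().sum(),
            "missing_frac": numeric.isna().mean(),
        }
    )
    per_wave_means = numeric.groupby(f["wave_number"]).mean()
    sex_trajectories = numeric.groupby([f["sex"], f["wave_number"]]).mean()
    missingness = numeric.isna().groupby(f["wave_number"]).mean()
    correlations = numeric.corr()
    return SummaryReport(
        variable_summary=variable_summary,
        per_wave_means=per_wave_means,
        sex_trajectories=sex_trajectories,
        missingness=missingness,
        correlations=correlations,
    )


def save_figures(report: SummaryReport, out_dir) -> list[Path]:
    """Write trajectory, missingness and correlation figures as PNGs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    fig, axes = plt.subplots(2, 3, figsize=(12, 7))
    for ax, name in zip(axes.ravel(), BRAIN_COLUMNS):
        for sex, label in ((0, "male"), (1, "female")):
            try:
                series = report.sex_trajectories.loc[sex][name]
            except KeyError:
                continue
            ax.plot(series.index, series.values, marker="o", label=label)
        ax.set_title(name, fontsize=9)
        ax.set_xlabel("wave")
    axes[0, 0].legend(fontsize=8)
    fig.tight_layout()
    p = out / "trajectories.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(7, 4))
    report.missingness.plot(ax=ax, legend=False)
    ax.set_ylabel("missing fraction")
    ax.set_xlabel("wave")
    fig.tight_layout()
    p = out / "missingness.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(report.correlations.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(report.correlations)))
    ax.set_xticklabels(report.correlations.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(report.correlations)))
    ax.set_yticklabels(report.correlations.index, fontsize=7)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    p = out / "correlations.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
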