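"""Developmental curve primitives shared by the engines.

Three curve families cover every engine's needs: polynomial normative
trajectories (up to 4th order, in age-months or log-age), B-spline growth
curves, and per-wave basis loadings for latent growth curve models.  A
:class:`NormativeModel` bundles per-phenotype mean and spread curves with
multiplicative sex adjustments and provides the z-score <-> raw-measurement
transforms.

The default normative catalog is a stylized, versioned fixture with
plausible magnitudes (ICV plateauing near 1.5e6 mm^3, slow subcortical
growth, monotone frontal thinning from ~3.2 mm).  It stands in for
population reference charts whose coefficients are not published, and makes
no claim about any deposited dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.interpolate import BSpline

from .schema import BRAIN_COLUMNS

__all__ = [
    "AGE_SUPPORT",
    "PolynomialTrajectory",
    "SplineTrajectory",
    "BasisLoadings",
    "SexAdjustment",
    "NormativeModel",
    "eval_polynomial",
    "fit_polynomial",
    "eval_spline",
    "z_to_raw",
    "raw_to_z",
    "default_normative_model",
]

#: Supported age range in months (7y0m .. 20y11m); no extrapolation.
AGE_SUPPORT = (84.0, 251.0)


def _predictor(x, predictor: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if predictor == "age_months":
        return x
    if predictor == "log_age":
        return np.log(x / 12.0)  # log of age in years
    raise ValueError(f"unknown predictor {predictor!r}")


def _check_support(age_months) -> None:
    a = np.asarray(age_months, dtype=float)
    if np.any(a < AGE_SUPPORT[0]) or np.any(a > AGE_SUPPORT[1]):
        raise ValueError(
            f"age outside supported range {AGE_SUPPORT}; no extrapolation"
        )


@dataclass(frozen=True)
class PolynomialTrajectory:
    """Polynomial curve ``sum_k a_k x^k`` with degree at most 4.

    ``predictor`` selects the x convention: raw age in months, or the log of
    age in years.
    """

    coefficients: tuple[float, ...]
    predictor: str = "age_months"

    def __post_init__(self) -> None:
        if len(self.coefficients) > 5:
            raise ValueError("degree at most 4 supported")
        _predictor(100.0, self.predictor)  # validates the name

    def __call__(self, age_months) -> np.ndarray:
        return eval_polynomial(self, age_months)

    def scaled(self, factor: float) -> "PolynomialTrajectory":
        return PolynomialTrajectory(
            tuple(factor * c for c in self.coefficients), self.predictor
        )


def eval_polynomial(traj: PolynomialTrajectory, age_months) -> np.ndarray:
    """Evaluate a polynomial trajectory at ages within the support."""
    _check_support(age_months)
    x = _predictor(age_months, traj.predictor)
    return npoly.polyval(x, np.asarray(traj.coefficients, dtype=float))


def fit_polynomial(
    age, value, degree: int = 4, predictor: str = "age_months"
) -> PolynomialTrajectory:
    """Least-squares polynomial fit of ``value`` on ``age`` (degree <= 4)."""
    if degree > 4:
        raise ValueError("degree at most 4 supported")
    age = np.asarray(age, dtype=float)
    value = np.asarray(value, dtype=float)
    if len(np.unique(age)) < degree + 1:
        raise ValueError("need at least degree+1 distinct ages")
    x = _predictor(age, predictor)
    # Fit in a shifted/scaled basis for conditioning, then expand back.
    series = np.polynomial.Polynomial.fit(x, value, deg=degree)
    coef = series.convert().coef
    return PolynomialTrajectory(tuple(float(c) for c in coef), predictor)


@dataclass(frozen=True)
class SplineTrajectory:
    """B-spline curve over age in months.

    ``knots`` are the distinct interior+boundary knot ages (strictly
    increasing, spanning the age support); boundary knots are clamped
    (repeated ``degree+1`` times) internally.  ``coefficients`` has length
    ``len(knots) + degree - 1``.
    """

    knots: tuple[float, ...]
    coefficients: tuple[float, ...]
    degree: int = 3

    def __post_init__(self) -> None:
        k = np.asarray(self.knots, dtype=float)
        if np.any(np.diff(k) <= 0):
            raise ValueError("knots must be strictly increasing")
        n_basis = len(self.knots) + self.degree - 1
        if len(self.coefficients) != n_basis:
            raise ValueError(
                f"expected {n_basis} coefficients for {len(self.knots)} knots "
                f"at degree {self.degree}"
            )

    def _bspline(self) -> BSpline:
        k = np.asarray(self.knots, dtype=float)
        t = np.concatenate(
            [np.repeat(k[0], self.degree), k, np.repeat(k[-1], self.degree)]
        )
        return BSpline(t, np.asarray(self.coefficients, dtype=float), self.degree)

    def __call__(self, age_months) -> np.ndarray:
        return eval_spline(self, age_months)


def eval_spline(traj: SplineTrajectory, age_months) -> np.ndarray:
    """Evaluate a spline trajectory within its knot span."""
    a = np.asarray(age_months, dtype=float)
    if np.any(a < traj.knots[0]) or np.any(a > traj.knots[-1]):
        raise ValueError("age outside the spline knot span")
    return traj._bspline()(a)


@dataclass(frozen=True)
class BasisLoadings:
    """Per-wave factor loadings for a basis-style latent growth model.

    Identification: the first loading is 0 and the last is 1, so the slope
    factor is the total wave-1 to final-wave change.
    """

    loadings: tuple[float, ...]

    def __post_init__(self) -> None:
        lam = np.asarray(self.loadings, dtype=float)
        if lam.size < 2:
            raise ValueError("need at least two waves of loadings")
        if not (abs(lam[0]) < 1e-12 and abs(lam[-1] - 1.0) < 1e-12):
            raise ValueError("identification requires first=0, last=1")

    def __len__(self) -> int:
        return len(self.loadings)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.loadings, dtype=float)


@dataclass(frozen=True)
class SexAdjustment:
    """Multiplicative adjustment applied to female raw values."""

    ratio: float = 1.0

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("ratio must be positive")


@dataclass(frozen=True)
class NormativeModel:
    """Per-phenotype normative mean/sd curves plus sex ratios.

    ``raw = (mean(age) + z * sd(age)) * ratio(sex)`` with ratio 1 for males
    and the configured multiplier for females.
    """

    mean_curves: dict[str, PolynomialTrajectory]
    sd_curves: dict[str, PolynomialTrajectory]
    sex_adjustments: dict[str, SexAdjustment] = field(default_factory=dict)

    def phenotypes(self) -> tuple[str, ...]:
        return tuple(self.mean_curves)

    def ratio(self, phenotype: str, sex) -> np.ndarray:
        adj = self.sex_adjustments.get(phenotype, SexAdjustment())
        sex = np.asarray(sex)
        return np.where(sex == 1, adj.ratio, 1.0)


def z_to_raw(
    z, model: NormativeModel, phenotype: str, age_months, sex
) -> np.ndarray:
    """Deviation score to raw measurement via the normative curves."""
    mean = eval_polynomial(model.mean_curves[phenotype], age_months)
    sd = eval_polynomial(model.sd_curves[phenotype], age_months)
    if np.any(sd <= 0):
        raise ValueError(f"non-positive normative sd for {phenotype}")
    return (mean + np.asarray(z, dtype=float) * sd) * model.ratio(phenotype, sex)


def raw_to_z(
    raw, model: NormativeModel, phenotype: str, age_months, sex
) -> np.ndarray:
    """Raw measurement to normative deviation score (inverse of z_to_raw)."""
    mean = eval_polynomial(model.mean_curves[phenotype], age_months)
    sd = eval_polynomial(model.sd_curves[phenotype], age_months)
    if np.any(sd <= 0):
        raise ValueError(f"non-positive normative sd for {phenotype}")
    return (np.asarray(raw, dtype=float) / model.ratio(phenotype, sex) - mean) / sd


# --- default catalog ------------------------------------------------------

# Anchor points (age months -> male reference value) for the stylized
# normative curves; quartic interpolation through five anchors per
# phenotype.  Volumes in mm^3, thickness in mm.
_ANCHOR_AGES = (84.0, 120.0, 156.0, 200.0, 251.0)
_ANCHOR_VALUES = {
    "icv": (1.30e6, 1.40e6, 1.46e6, 1.49e6, 1.50e6),
    "gm_volume": (6.60e5, 7.05e5, 7.20e5, 7.25e5, 7.26e5),
    "wm_volume": (3.80e5, 4.30e5, 4.65e5, 4.90e5, 5.00e5),
    "hippo_volume": (3600.0, 3800.0, 3950.0, 4050.0, 4100.0),
    "amygdala_volume": (2800.0, 2950.0, 3070.0, 3150.0, 3200.0),
    "frontal_lobe_gm_thickness": (3.20, 3.05, 2.92, 2.80, 2.70),
}

#: Female/male ratios; thickness shows no volumetric scaling.
_SEX_RATIOS = {
    "icv": 0.91,
    "gm_volume": 0.92,
    "wm_volume": 0.92,
    "hippo_volume": 0.94,
    "amygdala_volume": 0.93,
    "frontal_lobe_gm_thickness": 1.00,
}

#: Normative spread as a fraction of the mean curve.
DEFAULT_SD_FRACTION = 0.06


def default_normative_model(sd_fraction: float = DEFAULT_SD_FRACTION) -> NormativeModel:
    """The bundled stylized normative catalog for the six brain measures."""
    means: dict[str, PolynomialTrajectory] = {}
    sds: dict[str, PolynomialTrajectory] = {}
    adjustments: dict[str, SexAdjustment] = {}
    for name in BRAIN_COLUMNS:
        mean = fit_polynomial(_ANCHOR_AGES, _ANCHOR_VALUES[name], degree=4)
        means[name] = mean
        sds[name] = mean.scaled(sd_fraction)
        adjustments[name] = SexAdjustment(_SEX_RATIOS[name])
    return NormativeModel(means, sds, adjustments)
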