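"""Shared statistical primitives used by the generative engines.

Multivariate-normal sampling goes through an explicit Cholesky path so that
identical seeds give identical draws independent of BLAS internals: columns
of the standard-normal matrix are consumed in phenotype order and mixed by
the lower-triangular factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats as sps

__all__ = [
    "cholesky_factor",
    "mvn_sample",
    "logistic",
    "nearest_psd",
    "BoundedScoreMap",
    "latent_to_bounded",
    "sample_truncated_normal",
    "check_correlation_matrix",
]

_PSD_TOL = 1e-8


def check_correlation_matrix(R: np.ndarray, name: str = "R") -> np.ndarray:
    """Validate symmetry, unit diagonal and positive semidefiniteness."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError(f"{name} is not symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError(f"{name} does not have a unit diagonal")
    w = np.linalg.eigvalsh(R)
    if w.min() < -_PSD_TOL:
        raise ValueError(
            f"{name} is not positive semidefinite (smallest eigenvalue {w.min():.3e})"
        )
    return R


def cholesky_factor(R: np.ndarray) -> np.ndarray:
    """Lower-triangular L with ``L @ L.T == R`` (tolerance-checked PSD).

    Exactly singular but PSD inputs are handled by a tiny diagonal ridge;
    the reconstruction error stays far below 1e-10.
    """
    R = np.asarray(R, dtype=float)
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("matrix is not symmetric")
    try:
        return np.linalg.cholesky(R)
    except np.linalg.LinAlgError:
        w = np.linalg.eigvalsh(R)
        if w.min() < -_PSD_TOL * max(1.0, float(w.max())):
            raise ValueError(
                "matrix is not positive semidefinite "
                f"(smallest eigenvalue {w.min():.3e})"
            ) from None
        ridge = 1e-12 * max(1.0, float(np.trace(R)) / R.shape[0])
        return np.linalg.cholesky(R + ridge * np.eye(R.shape[0]))


def mvn_sample(
    mean: np.ndarray,
    covariance: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """n draws from N(mean, covariance) via the canonical Cholesky path."""
    mean = np.asarray(mean, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    p = mean.shape[0]
    if covariance.shape != (p, p):
        raise ValueError("covariance shape does not match mean")
    if np.allclose(covariance, 0.0):
        return np.tile(mean, (n, 1))
    L = cholesky_factor(covariance)
    z = rng.standard_normal((n, p))
    return mean + z @ L.T


def logistic(x) -> np.ndarray:
    """Log-odds to probability: 1 / (1 + exp(-x))."""
    return special.expit(x)


def nearest_psd(matrix: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped PSD repair of a symmetric matrix.

    Clips negative eigenvalues at zero and re-symmetrizes; idempotent on PSD
    inputs and Frobenius-nearest among eigenvalue-clipped repairs.
    """
    M = np.asarray(matrix, dtype=float)
    if not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("input must be symmetric")
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w.min() >= 0:
        return M
    out = (V * np.clip(w, 0.0, None)) @ V.T
    return 0.5 * (out + out.T)


@dataclass(frozen=True)
class BoundedScoreMap:
    """Monotone map from a latent standard-normal scale to a bounded score.

    ``score = lo + (hi - lo) * expit((latent - loc) / scale)``, optionally
    rounded half-up to an integer.  ``loc > 0`` puts the population median
    in the lower part of the range, giving the right-skewed shape typical
    of symptom checklists.
    """

    lo: float
    hi: float
    loc: float = 0.0
    scale: float = 1.0
    round_to_int: bool = True

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("need hi > lo")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def __call__(self, latent) -> np.ndarray:
        return latent_to_bounded(latent, self)

    def inverse(self, score) -> np.ndarray:
        """Latent value mapping to ``score`` (before rounding)."""
        score = np.asarray(score, dtype=float)
        u = np.clip((score - self.lo) / (self.hi - self.lo), 1e-12, 1 - 1e-12)
        return self.loc + self.scale * special.logit(u)


def latent_to_bounded(latent, score_map: BoundedScoreMap) -> np.ndarray:
    """Apply a :class:`BoundedScoreMap`; output always within [lo, hi]."""
    latent = np.asarray(latent, dtype=float)
    raw = score_map.lo + (score_map.hi - score_map.lo) * special.expit(
        (latent - score_map.loc) / score_map.scale
    )
    if score_map.round_to_int:
        raw = np.floor(raw + 0.5)
    return np.clip(raw, score_map.lo, score_map.hi)


def sample_truncated_normal(
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draws from a normal truncated to [lo, hi] (inverse-CDF sampling)."""
    if not lo < hi:
        raise ValueError("need lo < hi")
    a, b = (lo - mean) / sd, (hi - mean) / sd
    u = rng.uniform(size=n)
    return sps.truncnorm.ppf(u, a, b, loc=mean, scale=sd)
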