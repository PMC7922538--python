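"""PCA calibration projection and the Global-H (GH) applicability distance.

The applicability domain of a spectral prediction equation is summarized by a
principal-component model of the calibration set's derivative spectra.  A new
spectrum is projected onto the calibration eigenvectors and its Global-H
distance is the squared Mahalanobis distance of the resulting score vector to
the calibration score centroid, divided by the number of components:

    GH = (x - mu)' S^-1 (x - mu) / nPC

where ``mu`` is the mean calibration score vector (zero by construction),
``S`` the sample covariance of the calibration scores and ``nPC`` the number
of components retained to cover the configured fraction of spectral variance
(default 95%).  No small-sample n/(n-1) inflation factor is applied: the
intended use is calibration sets of hundreds to thousands of spectra where
the factor is indistinguishable from 1.

For a multivariate-normal population, ``nPC * GH`` is approximately
chi-square with ``nPC`` degrees of freedom, which is what makes fixed GH
cut-offs (3, 5, ...) interpretable as population coverage levels.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .errors import (
    DegenerateInputError,
    DimensionError,
    FitError,
    NearSingularCovarianceError,
)
from .spectra import DerivativeSpectra

#: relative eigenvalue floor below which components are dropped before inversion
EIGENVALUE_RTOL = 1e-10
#: condition-number ceiling for the score covariance
MAX_CONDITION = 1e12


@dataclass(frozen=True)
class CalibrationProjection:
    """Fitted PC model of a calibration set's derivative spectra.

    This is everything a laboratory needs to score new spectra against a
    calibration set — the mean derivative spectrum, the eigenvectors, the
    score covariance — without access to the calibration data themselves.
    """

    mean_deriv: np.ndarray          # (n_features,)
    eigenvectors: np.ndarray        # (n_features, n_pc), orthonormal columns
    eigenvalues: np.ndarray         # (n_pc,) PC variances
    score_mean: np.ndarray          # (n_pc,) ~ 0 by construction
    score_cov: np.ndarray           # (n_pc, n_pc) sample covariance, ddof=1
    n_pc: int
    variance_covered: float
    variance_target: float
    gap: int
    n_samples: int

    def __post_init__(self) -> None:
        v = np.asarray(self.eigenvectors, dtype=float)
        gram = v.T @ v
        if not np.allclose(gram, np.eye(v.shape[1]), atol=1e-8):
            raise FitError("eigenvectors are not orthonormal")
        s = np.asarray(self.score_cov, dtype=float)
        if not np.allclose(s, s.T, atol=1e-8):
            raise FitError("score covariance is not symmetric")


@dataclass(frozen=True)
class GHResult:
    """GH distances for a set of samples (unitless, >= 0)."""

    sample_ids: np.ndarray
    gh: np.ndarray
    n_pc: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.sample_ids, dtype=str)
        gh = np.asarray(self.gh, dtype=float)
        if ids.shape[0] != gh.shape[0]:
            raise DimensionError("ids and GH values differ in length")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "gh", gh)


def fit_calibration_projection(
    deriv: DerivativeSpectra, variance_target: float = 0.95
) -> CalibrationProjection:
    """Fit the PC model of a calibration set.

    Columns are mean-centered, the covariance eigendecomposition is obtained
    through a thin SVD, and ``n_pc`` is the smallest number of leading
    components whose cumulative explained variance reaches
    ``variance_target``.  Components with an eigenvalue below
    ``EIGENVALUE_RTOL`` times the largest are dropped for numerical safety.
    """
    if not 0.0 < variance_target <= 1.0:
        raise FitError(f"variance_target must be in (0, 1], got {variance_target}")
    x = deriv.values
    n = x.shape[0]
    if n < 3:
        raise FitError(f"at least 3 calibration samples required, got {n}")
    mean = x.mean(axis=0)
    xc = x - mean
    # thin SVD: singular values give PC variances, right vectors the loadings
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    variances = s**2 / (n - 1)
    total = variances.sum()
    if total <= 0.0:
        raise DegenerateInputError("calibration spectra have zero total variance")
    cum = np.cumsum(variances) / total
    n_pc = int(np.searchsorted(cum, variance_target - 1e-12) + 1)
    # numerical floor: never invert along a direction with negligible variance
    keep = variances[:n_pc] >= EIGENVALUE_RTOL * variances[0]
    n_pc = int(keep.sum())
    if n_pc == 0:
        raise DegenerateInputError("no component above the eigenvalue floor")
    eigenvectors = vt[:n_pc].T
    scores = xc @ eigenvectors
    score_mean = scores.mean(axis=0)
    score_cov = np.atleast_2d(np.cov(scores, rowvar=False, ddof=1))
    return CalibrationProjection(
        mean_deriv=mean,
        eigenvectors=eigenvectors,
        eigenvalues=variances[:n_pc],
        score_mean=score_mean,
        score_cov=score_cov,
        n_pc=n_pc,
        variance_covered=float(cum[n_pc - 1]),
        variance_target=float(variance_target),
        gap=deriv.gap,
        n_samples=n,
    )


def project_spectra(
    deriv: DerivativeSpectra, proj: CalibrationProjection
) -> np.ndarray:
    """Project derivative spectra onto the calibration eigenvectors.

    Returns the score matrix ``(deriv - mean_deriv) @ eigenvectors``.
    """
    if deriv.n_features != proj.mean_deriv.shape[0]:
        raise DimensionError(
            f"spectra have {deriv.n_features} derivative features but the "
            f"projection expects {proj.mean_deriv.shape[0]}"
        )
    return (deriv.values - proj.mean_deriv) @ proj.eigenvectors


def gh_distance(
    scores: np.ndarray,
    proj: CalibrationProjection,
    sample_ids: np.ndarray | None = None,
) -> GHResult:
    """GH of each score vector: Mahalanobis^2 to the centroid over n_pc.

    Uses a Cholesky solve of the score covariance; a condition number above
    ``MAX_CONDITION`` raises :class:`NearSingularCovarianceError` advising a
    lower variance target (fewer, better-determined components).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != proj.n_pc:
        raise DimensionError(
            f"scores have {scores.shape[1]} components, projection has {proj.n_pc}"
        )
    eigvals = np.linalg.eigvalsh(proj.score_cov)
    if eigvals[0] <= 0 or eigvals[-1] / eigvals[0] > MAX_CONDITION:
        raise NearSingularCovarianceError(
            "score covariance is numerically singular "
            f"(condition number ~ {eigvals[-1] / max(eigvals[0], 1e-300):.2e}); "
            "refit with a lower variance_target"
        )
    dev = scores - proj.score_mean
    cho = sla.cho_factor(proj.score_cov, lower=True)
    solved = sla.cho_solve(cho, dev.T)
    gh = np.einsum("ij,ji->i", dev, solved) / proj.n_pc
    gh = np.maximum(gh, 0.0)  # guard against -1e-17 round-off
    if sample_ids is None:
        sample_ids = np.array([f"s{i}" for i in range(scores.shape[0])])
    return GHResult(sample_ids=sample_ids, gh=gh, n_pc=proj.n_pc)


def gh_of_spectra(
    deriv: DerivativeSpectra, proj: CalibrationProjection
) -> GHResult:
    """Convenience: project derivative spectra and compute their GH."""
    scores = project_spectra(deriv, proj)
    return gh_distance(scores, proj, sample_ids=deriv.sample_ids)
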