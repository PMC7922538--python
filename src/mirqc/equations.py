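"""Surrogate spectral prediction equations.

Real external prediction equations are proprietary PLS models; for an
end-to-end runnable pipeline this module builds a principal-component
regression surrogate: the trait is regressed on the leading PC scores of the
gap-derivative spectra and the fitted model is folded back into a single
coefficient vector over derivative features, so applying an equation is just
``deriv @ coefficients + intercept``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, FitError
from .preprocessing import first_derivative
from .spectra import SpectrumSet

RANK_RTOL = 1e-10


@dataclass(frozen=True)
class PredictionEquation:
    """Linear equation over gap-derivative features, predicting g/dL."""

    trait: str
    intercept: float
    coefficients: np.ndarray        # (n_wavelengths - gap,)
    gap: int
    n_wavelengths: int
    insample_rmse: float = float("nan")
    insample_r2: float = float("nan")

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        expected = self.n_wavelengths - self.gap
        if coef.shape != (expected,):
            raise DimensionError(
                f"coefficient length {coef.shape[0]} does not match the "
                f"derivative feature length {expected}"
            )
        object.__setattr__(self, "coefficients", coef)

    def predict(self, spectra: SpectrumSet) -> np.ndarray:
        """Predict the trait (g/dL) for each spectrum."""
        if spectra.n_points != self.n_wavelengths:
            raise DimensionError(
                f"equation expects {self.n_wavelengths} spectral points, "
                f"got {spectra.n_points}"
            )
        deriv = first_derivative(spectra, self.gap)
        return deriv.values @ self.coefficients + self.intercept


def build_prediction_equation(
    calset: SpectrumSet,
    values: np.ndarray,
    trait: str = "trait",
    gap: int = 5,
    n_components: int = 15,
) -> PredictionEquation:
    """Principal-component regression of a trait on derivative spectra.

    The trait is regressed by least squares on the first ``n_components``
    PC scores of the gap-derivative spectra; the result is folded back to a
    coefficient vector in derivative-feature space.  Raises
    :class:`FitError` when fewer than ``n_components + 2`` samples are
    available or the derivative spectra do not span ``n_components``
    directions (relative singular-value tolerance ``RANK_RTOL``).
    """
    y = np.asarray(values, dtype=float)
    n = calset.n_samples
    if y.shape != (n,):
        raise DimensionError("one trait value per calibration spectrum required")
    if n < n_components + 2:
        raise FitError(
            f"need at least {n_components + 2} samples to fit "
            f"{n_components} components, got {n}"
        )
    deriv = first_derivative(calset, gap)
    x = deriv.values
    x_mean = x.mean(axis=0)
    xc = x - x_mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    if s.size < n_components or s[n_components - 1] < RANK_RTOL * s[0]:
        raise FitError(
            f"derivative spectra are rank deficient: cannot support "
            f"{n_components} components"
        )
    v = vt[:n_components].T
    scores = xc @ v                      # centered by construction
    y_mean = y.mean()
    yc = y - y_mean
    # PC scores are orthogonal, so the LS solution is a per-component ratio
    coef_pc = (scores.T @ yc) / (s[:n_components] ** 2)
    beta = v @ coef_pc
    intercept = float(y_mean - x_mean @ beta)
    fitted = x @ beta + intercept
    resid = y - fitted
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum(yc**2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else float("nan")
    return PredictionEquation(
        trait=trait,
        intercept=intercept,
        coefficients=beta,
        gap=gap,
        n_wavelengths=calset.n_points,
        insample_rmse=rmse,
        insample_r2=r2,
    )
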