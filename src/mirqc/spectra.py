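"""In-memory containers for spectral data.

A :class:`SpectrumSet` is a wide matrix of absorbance values on a fixed
spectral grid (rows = milk samples, columns = spectral points), the raw
material every other stage consumes.  :class:`DerivativeSpectra` holds the
gap first-derivative features derived from it; the two are kept distinct so
dimension mismatches (raw vs. derivative space) fail loudly.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError


@dataclass(frozen=True)
class SpectrumSet:
    """Absorbance matrix on a fixed spectral grid.

    Parameters
    ----------
    sample_ids : array-like of str
        Unique identifier per sample (row).
    grid : array-like of float
        Spectral-point positions (abstract indices or wavenumbers, cm^-1);
        strictly increasing.
    absorbance : ndarray, shape (n_samples, n_points)
        Absorbance values, arbitrary units; finite, no missing values.
    """

    sample_ids: np.ndarray
    grid: np.ndarray
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.sample_ids, dtype=str)
        grid = np.asarray(self.grid, dtype=float)
        absorb = np.asarray(self.absorbance, dtype=float)
        if absorb.ndim != 2:
            raise DimensionError("absorbance must be a 2-D matrix")
        if ids.shape[0] != absorb.shape[0]:
            raise DimensionError(
                f"{ids.shape[0]} sample ids for {absorb.shape[0]} spectra"
            )
        if grid.shape[0] != absorb.shape[1]:
            raise DimensionError(
                f"grid has {grid.shape[0]} points but spectra have "
                f"{absorb.shape[1]} columns"
            )
        if len(np.unique(ids)) != len(ids):
            raise DimensionError("sample ids must be unique")
        if grid.size > 1 and not np.all(np.diff(grid) > 0):
            raise DimensionError("grid must be strictly increasing")
        if not np.all(np.isfinite(absorb)):
            raise DimensionError("absorbance contains non-finite values")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "absorbance", absorb)

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    @property
    def n_points(self) -> int:
        return self.absorbance.shape[1]


@dataclass(frozen=True)
class DerivativeSpectra:
    """Gap first-derivative features of a :class:`SpectrumSet`.

    ``values[:, i] = absorbance[:, i + gap] - absorbance[:, i]``; the feature
    space is shortened by ``gap`` points relative to the raw grid.
    """

    sample_ids: np.ndarray
    gap: int
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = np.asarray(self.sample_ids, dtype=str)
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise DimensionError("derivative values must be a 2-D matrix")
        if int(self.gap) < 1:
            raise DimensionError("gap must be >= 1")
        if ids.shape[0] != values.shape[0]:
            raise DimensionError("sample id count does not match rows")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "gap", int(self.gap))
        object.__setattr__(self, "values", values)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]
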