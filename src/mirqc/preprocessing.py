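"""Spectral preprocessing: piecewise standardization and the gap derivative.

Standardization maps raw instrument absorbances onto a common (master)
response through per-segment linear transforms whose coefficients are
supplied externally (e.g. estimated during a standardization exercise); this
module only *applies* them.  The gap first derivative removes additive
baseline drift and is the feature space in which the calibration projection
and prediction equations operate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import CoverageError, DimensionError
from .spectra import DerivativeSpectra, SpectrumSet

DEFAULT_GAP = 5


@dataclass(frozen=True)
class Segment:
    """One piece of a piecewise standardization: indices [start, end] inclusive."""

    start: int
    end: int
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CoverageError(f"segment end {self.end} before start {self.start}")
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise CoverageError("segment coefficients must be finite")


@dataclass(frozen=True)
class PiecewiseStandardization:
    """Ordered, contiguous, non-overlapping segments covering the whole grid."""

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(
            s if isinstance(s, Segment) else Segment(*s) for s in self.segments
        )
        if not segs:
            raise CoverageError("at least one segment is required")
        for prev, nxt in zip(segs, segs[1:]):
            if nxt.start != prev.end + 1:
                raise CoverageError(
                    f"segments not contiguous: {prev.end} followed by {nxt.start}"
                )
        object.__setattr__(self, "segments", segs)

    @classmethod
    def identity(cls, n_points: int) -> "PiecewiseStandardization":
        return cls((Segment(0, n_points - 1, 1.0, 0.0),))

    def validate_coverage(self, n_points: int) -> None:
        if self.segments[0].start != 0 or self.segments[-1].end != n_points - 1:
            raise CoverageError(
                f"segments cover [{self.segments[0].start}, {self.segments[-1].end}] "
                f"but the grid has points [0, {n_points - 1}]"
            )


def apply_standardization(
    spectra: SpectrumSet, std: PiecewiseStandardization
) -> SpectrumSet:
    """Apply per-segment linear transforms: x -> slope * x + intercept.

    The grid is unchanged; only absorbances are rescaled.
    """
    std.validate_coverage(spectra.n_points)
    out = np.empty_like(spectra.absorbance)
    for seg in std.segments:
        sl = slice(seg.start, seg.end + 1)
        out[:, sl] = seg.slope * spectra.absorbance[:, sl] + seg.intercept
    return SpectrumSet(spectra.sample_ids, spectra.grid, out)


def first_derivative(spectra: SpectrumSet, gap: int = DEFAULT_GAP) -> DerivativeSpectra:
    """Unnormalized forward gap difference: d[i] = a[i+gap] - a[i].

    Any constant (baseline) offset added to a spectrum vanishes; the output is
    shortened by ``gap`` points.  The difference is deliberately not divided
    by the grid spacing — downstream PCA and regression absorb any affine
    rescaling of the feature space.
    """
    gap = int(gap)
    if gap < 1:
        raise DimensionError("gap must be >= 1")
    if gap >= spectra.n_points:
        raise DimensionError(
            f"gap {gap} must be smaller than the number of spectral points "
            f"({spectra.n_points})"
        )
    a = spectra.absorbance
    values = a[:, gap:] - a[:, :-gap]
    return DerivativeSpectra(spectra.sample_ids, gap, values)


def derivative_matrix(matrix: np.ndarray, gap: int = DEFAULT_GAP) -> np.ndarray:
    """Gap derivative of a bare matrix (rows = samples); used by equations."""
    gap = int(gap)
    if gap < 1 or gap >= matrix.shape[1]:
        raise DimensionError("gap out of range for matrix width")
    return matrix[:, gap:] - matrix[:, :-gap]


def segments_from_tuples(
    tuples: Sequence[tuple[int, int, float, float]]
) -> PiecewiseStandardization:
    return PiecewiseStandardization(tuple(Segment(*t) for t in tuples))
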