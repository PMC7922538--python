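"""File formats: wide spectra CSV, record CSV, JSON model files.

All files are comma-separated UTF-8 with '.' decimal separator and a
mandatory header row.  Spectra are wide CSV (first column = sample id,
remaining header cells = grid positions).  Calibration projections,
prediction equations and standardization coefficients are JSON with an
explicit format-version field so they can circulate between laboratories
without the underlying calibration data.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cleaning import RuleThresholds
from .equations import PredictionEquation
from .errors import ParseError, SchemaError
from .preprocessing import PiecewiseStandardization, Segment
from .projection import CalibrationProjection
from .records import ID_COLUMN, PhenotypeTable, ext_col, int_col
from .spectra import SpectrumSet

FORMAT_VERSION = 1
_FLOAT_FMT = "%.17g"  # lossless round trip for float64


# ------------------------------------------------------------ pipeline config
@dataclass(frozen=True)
class PipelineConfig:
    """File-based pipeline configuration; any field can be overridden by a
    command-line flag."""

    records: str | None = None
    spectra: str | None = None
    output_dir: str = "."
    traits: tuple[str, ...] = ("fat",)
    gap: int = 5
    variance_target: float = 0.95
    seed: int = 0
    log_level: str = "info"
    thresholds: RuleThresholds = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.thresholds is None:
            object.__setattr__(self, "thresholds", RuleThresholds())

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        thr = payload.pop("thresholds", None)
        if thr is not None:
            for key in ("fat_range", "protein_range", "dim_range"):
                if key in thr:
                    thr[key] = tuple(thr[key])
            thr = RuleThresholds(**thr)
        if "traits" in payload:
            payload["traits"] = tuple(payload["traits"])
        return cls(thresholds=thr, **payload)


# ----------------------------------------------------------------- spectra
def write_spectra(spectra: SpectrumSet, path: str | Path) -> None:
    df = pd.DataFrame(
        spectra.absorbance,
        columns=[_FLOAT_FMT % g for g in spectra.grid],
    )
    df.insert(0, ID_COLUMN, spectra.sample_ids)
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_spectra(path: str | Path) -> SpectrumSet:
    """Read a wide spectra CSV; malformed cells fail with their location."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a sample-id column plus spectral points")
    ids = df.iloc[:, 0].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ParseError(
            f"{path}: duplicate sample id '{dup.iloc[0]}' "
            f"(line {dup.index[0] + 2})"
        )
    try:
        grid = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric grid header: {exc}") from exc
    values = np.empty((len(df), df.shape[1] - 1))
    for j, col in enumerate(df.columns[1:]):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
            raise ParseError(
                f"{path}: non-numeric value in column '{col}', line {line}"
            )
        values[:, j] = converted.to_numpy()
    return SpectrumSet(ids.to_numpy(), grid, values)


# ----------------------------------------------------------------- records
def write_records(table: PhenotypeTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_records(path: str | Path, traits: list[str]) -> PhenotypeTable:
    df = pd.read_csv(path)
    missing = [
        c for t in traits for c in (int_col(t), ext_col(t)) if c not in df.columns
    ]
    if missing:
        raise SchemaError(f"{path}: missing trait columns: {', '.join(missing)}")
    for col in ("days_in_milk", "lactation_number"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return PhenotypeTable(df, traits)


# ------------------------------------------------------------- projections
def write_projection(proj: CalibrationProjection, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "calibration_projection",
        "mean_deriv": proj.mean_deriv.tolist(),
        "eigenvectors": proj.eigenvectors.tolist(),
        "eigenvalues": proj.eigenvalues.tolist(),
        "score_mean": proj.score_mean.tolist(),
        "score_cov": proj.score_cov.tolist(),
        "n_pc": proj.n_pc,
        "variance_covered": proj.variance_covered,
        "variance_target": proj.variance_target,
        "gap": proj.gap,
        "n_samples": proj.n_samples,
    }
    Path(path).write_text(json.dumps(payload))


def read_projection(path: str | Path) -> CalibrationProjection:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "calibration_projection":
        raise ParseError(f"{path}: not a calibration-projection file")
    return CalibrationProjection(
        mean_deriv=np.array(payload["mean_deriv"]),
        eigenvectors=np.array(payload["eigenvectors"]),
        eigenvalues=np.array(payload["eigenvalues"]),
        score_mean=np.array(payload["score_mean"]),
        score_cov=np.array(payload["score_cov"]),
        n_pc=int(payload["n_pc"]),
        variance_covered=float(payload["variance_covered"]),
        variance_target=float(payload["variance_target"]),
        gap=int(payload["gap"]),
        n_samples=int(payload["n_samples"]),
    )


# --------------------------------------------------------------- equations
def write_equation(eq: PredictionEquation, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "prediction_equation",
        "trait": eq.trait,
        "intercept": eq.intercept,
        "coefficients": eq.coefficients.tolist(),
        "gap": eq.gap,
        "n_wavelengths": eq.n_wavelengths,
        "insample_rmse": eq.insample_rmse,
        "insample_r2": eq.insample_r2,
    }
    Path(path).write_text(json.dumps(payload))


def read_equation(path: str | Path) -> PredictionEquation:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "prediction_equation":
        raise ParseError(f"{path}: not a prediction-equation file")
    return PredictionEquation(
        trait=payload["trait"],
        intercept=float(payload["intercept"]),
        coefficients=np.array(payload["coefficients"]),
        gap=int(payload["gap"]),
        n_wavelengths=int(payload["n_wavelengths"]),
        insample_rmse=float(payload["insample_rmse"]),
        insample_r2=float(payload["insample_r2"]),
    )


# --------------------------------------------------------- standardization
def write_standardization(std: PiecewiseStandardization, path: str | Path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "kind": "piecewise_standardization",
        "segments": [
            [s.start, s.end, s.slope, s.intercept] for s in std.segments
        ],
    }
    Path(path).write_text(json.dumps(payload))


def read_standardization(path: str | Path) -> PiecewiseStandardization:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "piecewise_standardization":
        raise ParseError(f"{path}: not a standardization file")
    return PiecewiseStandardization(
        tuple(Segment(int(a), int(b), float(c), float(d))
              for a, b, c, d in payload["segments"])
    )
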