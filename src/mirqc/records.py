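"""The per-record phenotype table.

Each row is one milk sample with the manufacturer's (internal, ring-test
corrected) prediction ``INT_<trait>`` and the external-equation prediction
``EXT_<trait>`` in g/dL, plus recording metadata (cow id, days in milk,
lactation number).  Synthetic populations additionally carry ``true_class``
(clean / extrapolated / degraded / mismatched) and ``TRUE_<trait>`` columns,
and the pipeline appends ``GH_<trait>`` applicability scores.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError

ID_COLUMN = "sample_id"
CLASS_COLUMN = "true_class"


def int_col(trait: str) -> str:
    return f"INT_{trait}"


def ext_col(trait: str) -> str:
    return f"EXT_{trait}"


def gh_col(trait: str) -> str:
    return f"GH_{trait}"


def true_col(trait: str) -> str:
    return f"TRUE_{trait}"


class PhenotypeTable:
    """Validated wrapper around a pandas DataFrame of phenotype records."""

    def __init__(self, data: pd.DataFrame, traits: Sequence[str]):
        traits = tuple(traits)
        if ID_COLUMN not in data.columns:
            raise SchemaError(f"missing required column '{ID_COLUMN}'")
        missing = [
            c
            for t in traits
            for c in (int_col(t), ext_col(t))
            if c not in data.columns
        ]
        if missing:
            raise SchemaError(f"missing trait columns: {', '.join(missing)}")
        ids = data[ID_COLUMN].astype(str)
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise SchemaError(f"duplicate sample id '{dup}'")
        self._data = data.reset_index(drop=True)
        self._traits = traits

    # ------------------------------------------------------------------ access
    @property
    def data(self) -> pd.DataFrame:
        return self._data

    @property
    def traits(self) -> tuple[str, ...]:
        return self._traits

    @property
    def n_records(self) -> int:
        return len(self._data)

    @property
    def sample_ids(self) -> np.ndarray:
        return self._data[ID_COLUMN].to_numpy(dtype=str)

    def int_values(self, trait: str) -> np.ndarray:
        return self._data[int_col(trait)].to_numpy(dtype=float)

    def ext_values(self, trait: str) -> np.ndarray:
        return self._data[ext_col(trait)].to_numpy(dtype=float)

    def residuals(self, trait: str) -> np.ndarray:
        """EXT - INT per record, g/dL."""
        return self.ext_values(trait) - self.int_values(trait)

    def squared_differences(self, trait: str) -> np.ndarray:
        d = self.residuals(trait)
        return d * d

    def gh_values(self, trait: str) -> np.ndarray:
        col = gh_col(trait)
        if col not in self._data.columns:
            raise SchemaError(
                f"no '{col}' column; compute GH with a calibration projection "
                "(fit-projection + gh) before GH-based cleaning"
            )
        return self._data[col].to_numpy(dtype=float)

    def has_column(self, name: str) -> bool:
        return name in self._data.columns

    # --------------------------------------------------------------- mutation
    def with_column(self, name: str, values: np.ndarray) -> "PhenotypeTable":
        df = self._data.copy()
        df[name] = np.asarray(values)
        return PhenotypeTable(df, self._traits)

    def subset(self, keep: np.ndarray) -> "PhenotypeTable":
        """Rows where ``keep`` is True; schema and column order preserved."""
        keep = np.asarray(keep, dtype=bool)
        if keep.shape[0] != self.n_records:
            raise SchemaError("boolean selector length does not match table")
        return PhenotypeTable(self._data.loc[keep].reset_index(drop=True), self._traits)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"PhenotypeTable(n_records={self.n_records}, "
            f"traits={list(self._traits)})"
        )
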