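"""Record-level cleaning rules and their combinations.

Three screening rules target different failure modes of MIR-predicted
phenotypes:

* **M1** — extreme externally-predicted values: delete records outside the
  empirical 1%/99% quantiles of the trait's external prediction.
* **M2** — spectral extrapolation: delete records whose Global-H distance to
  the trait's calibration set exceeds a limit (default 5).
* **M3** — poor-quality spectra / sample-record mismatch: delete records
  whose absolute fat residual |EXT_fat - INT_fat| exceeds a limit
  (default 0.30 g/dL), the manufacturer's ring-test-corrected fat content
  acting as a control value.

An ICAR-style plausibility prefilter (fat 1.5-9.0 g/dL, protein 1.0-7.0
g/dL, days in milk 5-365) runs before any rule.  Rules combine by
intersection ("and": delete only records extreme by *every* rule) or union
("or": delete records extreme by *any* rule).

Boundary convention: equality with a threshold keeps the record; all flags
are strict inequalities.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import AlignmentError, ConfigurationError, SchemaError
from .projection import GHResult
from .records import PhenotypeTable, ext_col, int_col

logger = logging.getLogger(__name__)

M1_WARN_N = 100


@dataclass(frozen=True)
class RuleThresholds:
    """All tunable cut-offs of the cleaning stage, with field defaults."""

    m1_p_low: float = 0.01
    m1_p_high: float = 0.99
    m2_gh_limit: float = 5.0
    m3_fat_limit: float = 0.30          # g/dL
    fat_range: tuple[float, float] = (1.5, 9.0)      # g/dL, ICAR
    protein_range: tuple[float, float] = (1.0, 7.0)  # g/dL, ICAR
    dim_range: tuple[int, int] = (5, 365)            # days in milk

    def __post_init__(self) -> None:
        if not 0.0 <= self.m1_p_low < self.m1_p_high <= 1.0:
            raise ConfigurationError(
                f"need 0 <= p_low < p_high <= 1, got ({self.m1_p_low}, {self.m1_p_high})"
            )
        if self.m2_gh_limit <= 0 or self.m3_fat_limit <= 0:
            raise ConfigurationError("GH and fat-residual limits must be > 0")
        for lo, hi in (self.fat_range, self.protein_range, self.dim_range):
            if lo >= hi:
                raise ConfigurationError(f"invalid range ({lo}, {hi})")


@dataclass(frozen=True)
class CleaningMask:
    """Boolean delete-flags plus provenance (rule name and thresholds used)."""

    sample_ids: np.ndarray
    flagged: np.ndarray
    rule: str
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = np.asarray(self.sample_ids, dtype=str)
        flagged = np.asarray(self.flagged, dtype=bool)
        if ids.shape[0] != flagged.shape[0]:
            raise AlignmentError("ids and flags differ in length")
        if not self.rule:
            raise ConfigurationError("mask provenance (rule) must be non-empty")
        object.__setattr__(self, "sample_ids", ids)
        object.__setattr__(self, "flagged", flagged)

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())

    @property
    def flagged_fraction(self) -> float:
        return float(self.flagged.mean()) if len(self.flagged) else 0.0

    def flagged_ids(self) -> np.ndarray:
        return self.sample_ids[self.flagged]


# --------------------------------------------------------------------- rules
def icar_prefilter(
    table: PhenotypeTable, thresholds: RuleThresholds | None = None
) -> CleaningMask:
    """Plausibility prefilter on manufacturer fat/protein and days in milk.

    Flags records outside any of the closed intervals; applied to the
    ring-test-corrected (internal) contents, which are the values these
    plausibility ranges were defined for.
    """
    thresholds = thresholds or RuleThresholds()
    required = [int_col("fat"), int_col("protein"), "days_in_milk"]
    missing = [c for c in required if not table.has_column(c)]
    if missing:
        raise SchemaError(f"prefilter needs columns: {', '.join(missing)}")
    fat = table.int_values("fat")
    protein = table.int_values("protein")
    dim = table.data["days_in_milk"].to_numpy(dtype=float)
    flo, fhi = thresholds.fat_range
    plo, phi = thresholds.protein_range
    dlo, dhi = thresholds.dim_range
    flagged = (
        (fat < flo) | (fat > fhi)
        | (protein < plo) | (protein > phi)
        | (dim < dlo) | (dim > dhi)
    )
    mask = CleaningMask(
        table.sample_ids,
        flagged,
        rule="prefilter",
        thresholds={
            "fat_range": thresholds.fat_range,
            "protein_range": thresholds.protein_range,
            "dim_range": thresholds.dim_range,
        },
    )
    logger.info("prefilter: %d of %d records flagged", mask.n_flagged, table.n_records)
    return mask


def m1_quantile_rule(
    table: PhenotypeTable,
    trait: str,
    p_low: float = 0.01,
    p_high: float = 0.99,
    fixed_thresholds: tuple[float, float] | None = None,
) -> tuple[CleaningMask, tuple[float, float]]:
    """M1: flag records with an external prediction outside the empirical
    (p_low, p_high) quantiles of the trait.

    Quantiles use linear interpolation between order statistics.  Passing
    ``fixed_thresholds`` re-applies previously computed cut-offs, which is
    how M1 behaves inside combinations (thresholds computed once on the raw
    post-prefilter dataset, then treated as fixed).
    """
    values = table.ext_values(trait)
    n = len(values)
    if n < M1_WARN_N:
        warnings.warn(
            f"M1 quantile thresholds estimated from only {n} values",
            stacklevel=2,
        )
    if fixed_thresholds is None:
        q_low, q_high = np.quantile(values, [p_low, p_high])
    else:
        q_low, q_high = fixed_thresholds
    if q_low == q_high:
        warnings.warn(
            "M1 thresholds coincide (constant values); nothing flagged",
            stacklevel=2,
        )
    flagged = (values < q_low) | (values > q_high)
    mask = CleaningMask(
        table.sample_ids,
        flagged,
        rule=f"M1[{trait}]",
        thresholds={"p_low": p_low, "p_high": p_high,
                    "q_low": float(q_low), "q_high": float(q_high)},
    )
    logger.info(
        "M1[%s]: thresholds (%.4g, %.4g), %d of %d flagged",
        trait, q_low, q_high, mask.n_flagged, n,
    )
    return mask, (float(q_low), float(q_high))


def m2_gh_rule(gh: GHResult, limit: float = 5.0) -> CleaningMask:
    """M2: flag records with GH strictly above ``limit``."""
    flagged = gh.gh > limit
    mask = CleaningMask(
        gh.sample_ids, flagged, rule="M2", thresholds={"gh_limit": float(limit)}
    )
    logger.info("M2: GH > %g, %d of %d flagged", limit, mask.n_flagged, len(gh.gh))
    return mask


def m3_fat_residual_rule(
    table: PhenotypeTable, limit: float = 0.30
) -> CleaningMask:
    """M3: flag records with |EXT_fat - INT_fat| strictly above ``limit`` g/dL."""
    for col in (int_col("fat"), ext_col("fat")):
        if not table.has_column(col):
            raise SchemaError(f"M3 needs column '{col}'")
    resid = np.abs(table.residuals("fat"))
    flagged = resid > limit
    mask = CleaningMask(
        table.sample_ids, flagged, rule="M3", thresholds={"fat_limit": float(limit)}
    )
    logger.info(
        "M3: |fat residual| > %g g/dL, %d of %d flagged",
        limit, mask.n_flagged, table.n_records,
    )
    return mask


# --------------------------------------------------------------- combinators
def combine_masks(masks: Sequence[CleaningMask], mode: str) -> CleaningMask:
    """Combine masks over identical sample sets.

    ``mode="and"``: flag where ALL inputs flag (intersection of deletions —
    delete only records extreme by every rule).  ``mode="or"``: flag where
    ANY input flags (union).
    """
    if mode not in ("and", "or"):
        raise ConfigurationError(f"mode must be 'and' or 'or', got {mode!r}")
    if not masks:
        raise ConfigurationError("no masks to combine")
    ids = masks[0].sample_ids
    for m in masks[1:]:
        if m.sample_ids.shape != ids.shape or not np.array_equal(m.sample_ids, ids):
            raise AlignmentError("masks cover different sample id sets")
    stack = np.vstack([m.flagged for m in masks])
    flagged = stack.all(axis=0) if mode == "and" else stack.any(axis=0)
    rule = f" {mode} ".join(m.rule for m in masks)
    thresholds: dict = {}
    for m in masks:
        thresholds[m.rule] = m.thresholds
    return CleaningMask(ids, flagged, rule=rule, thresholds=thresholds)


def apply_mask(table: PhenotypeTable, mask: CleaningMask) -> PhenotypeTable:
    """Return the table restricted to unflagged records; input untouched."""
    if mask.sample_ids.shape[0] != table.n_records or not np.array_equal(
        mask.sample_ids, table.sample_ids
    ):
        raise AlignmentError("mask does not align with the table's sample ids")
    kept = table.subset(~mask.flagged)
    logger.info(
        "apply_mask[%s]: kept %d, removed %d",
        mask.rule, kept.n_records, mask.n_flagged,
    )
    return kept
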