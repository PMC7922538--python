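"""Comparison statistics for cleaning procedures.

The yardstick throughout is the root mean square difference (RMSD) between
the externally predicted and the manufacturer's (internal) phenotype values,

    RMSD = sqrt( sum_i (EXT_i - INT_i)^2 / n ),

in g/dL.  A cleaning rule is judged by the *gain* it buys — the percentage
by which it shrinks the RMSD, expressed relative to the post-cleaning RMSD,
gain = (RMSD_before / RMSD_after - 1) * 100 — against the percentage of
records it discards (N loss).  Their ratio (gain:loss) is the parsimony
criterion used to pick a combination of rules.

Threshold sweeps compare the squared differences of the cleaned sets with a
Kruskal-Wallis omnibus rank test and pairwise two-sample Wilcoxon rank-sum
tests (tie-corrected normal approximation), since squared differences are
far from normal.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cleaning import CleaningMask, apply_mask, combine_masks
from .errors import EmptyInputError, UndefinedStatisticError
from .projection import GHResult
from .records import PhenotypeTable

#: the eleven rule rows of a combination report: the three single rules,
#: every pairwise/triple intersection and every pairwise/triple union
RULE_COMBINATIONS: tuple[tuple[str, tuple[str, ...], str | None], ...] = (
    ("M1", ("M1",), None),
    ("M2", ("M2",), None),
    ("M3", ("M3",), None),
    ("M1 and M2", ("M1", "M2"), "and"),
    ("M1 and M3", ("M1", "M3"), "and"),
    ("M2 and M3", ("M2", "M3"), "and"),
    ("M1 and M2 and M3", ("M1", "M2", "M3"), "and"),
    ("M1 or M2", ("M1", "M2"), "or"),
    ("M1 or M3", ("M1", "M3"), "or"),
    ("M2 or M3", ("M2", "M3"), "or"),
    ("M1 or M2 or M3", ("M1", "M2", "M3"), "or"),
)


# ------------------------------------------------------------- scalar stats
def rmsd(ext: np.ndarray, int_: np.ndarray) -> float:
    """Root mean square difference between two aligned prediction vectors."""
    ext = np.asarray(ext, dtype=float)
    int_ = np.asarray(int_, dtype=float)
    if ext.shape != int_.shape:
        raise UndefinedStatisticError("inputs must have equal length")
    if ext.size == 0:
        raise EmptyInputError("RMSD of zero records is undefined")
    d = ext - int_
    return float(np.sqrt(np.mean(d * d)))


def rmsd_gain(rmsd_before: float, rmsd_after: float) -> float:
    """Percentage RMSD reduction, relative to the post-cleaning value."""
    if rmsd_before <= 0 or rmsd_after < 0:
        raise UndefinedStatisticError("RMSDs must be positive")
    if rmsd_after == 0:
        raise UndefinedStatisticError("gain undefined: post-cleaning RMSD is 0")
    return (rmsd_before / rmsd_after - 1.0) * 100.0


def data_loss(mask: CleaningMask) -> float:
    """Percentage of records the mask discards."""
    if len(mask.flagged) == 0:
        raise EmptyInputError("data loss of an empty mask is undefined")
    return 100.0 * mask.flagged_fraction


def gain_loss_ratio(gain_pct: float, n_loss_pct: float) -> float:
    """Parsimony criterion: RMSD gain % per % of records discarded."""
    if n_loss_pct <= 0:
        raise UndefinedStatisticError("gain:loss undefined at zero data loss")
    return gain_pct / n_loss_pct


@dataclass(frozen=True)
class DescriptiveStats:
    """Moments of a trait distribution as reported in routine summaries."""

    n: int
    mean: float
    sd: float
    cv: float            # percent, 100 * sd / mean
    minimum: float
    maximum: float
    skewness: float      # population (biased) standardized third moment
    kurtosis: float      # excess by default (0 for a normal)
    excess: bool = True


def descriptive_stats(values: np.ndarray, excess_kurtosis: bool = True) -> DescriptiveStats:
    """Mean, SD (ddof=1), CV%, range and population skewness/kurtosis.

    Constant input yields SD = 0 and NaN markers for skewness and kurtosis.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise EmptyInputError("need at least 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    cv = 100.0 * sd / mean if mean != 0 else float("nan")
    if sd == 0:
        skew = kurt = float("nan")
    else:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, fisher=excess_kurtosis, bias=True))
    return DescriptiveStats(
        n=int(x.size), mean=mean, sd=sd, cv=cv,
        minimum=float(np.min(x)), maximum=float(np.max(x)),
        skewness=skew, kurtosis=kurt, excess=excess_kurtosis,
    )


def gh_error_correlation(
    gh: GHResult | np.ndarray, ext: np.ndarray, int_: np.ndarray
) -> float:
    """Pearson r between GH and the squared prediction difference.

    A moderately positive value indicates that spectral extrapolation drives
    prediction error for the trait; NaN if either side has zero variance.
    """
    g = gh.gh if isinstance(gh, GHResult) else np.asarray(gh, dtype=float)
    e2 = (np.asarray(ext, float) - np.asarray(int_, float)) ** 2
    if g.shape != e2.shape:
        raise UndefinedStatisticError("GH and prediction vectors differ in length")
    if g.size < 3:
        raise EmptyInputError("need at least 3 records")
    if np.std(g) == 0 or np.std(e2) == 0:
        return float("nan")
    return float(stats.pearsonr(g, e2)[0])


# ----------------------------------------------------------- threshold sweep
@dataclass(frozen=True)
class SweepResult:
    """Per-threshold loss/RMSD/gain plus rank tests across the cleaned sets."""

    trait: str
    thresholds: np.ndarray
    table: pd.DataFrame                 # threshold, n_kept, n_loss_pct, rmsd, gain_pct
    kw_statistic: float
    kw_pvalue: float
    pairwise_pvalues: pd.DataFrame      # thresholds x thresholds, NaN diagonal

    def pairwise_bonferroni(self) -> pd.DataFrame:
        k = len(self.thresholds)
        m = k * (k - 1) / 2
        return (self.pairwise_pvalues * m).clip(upper=1.0)


def threshold_sweep(
    table: PhenotypeTable,
    trait: str,
    criterion: np.ndarray,
    thresholds: Sequence[float],
) -> SweepResult:
    """Sweep a cleaning criterion over thresholds (keep records <= threshold).

    For each threshold the cleaned-set size, RMSD and gain are computed; the
    squared differences of the cleaned sets are compared with a
    Kruskal-Wallis omnibus test and all pairwise two-sample Wilcoxon
    rank-sum tests (asymptotic, tie-corrected).  A threshold that empties
    the cleaned set yields NaN entries.
    """
    thresholds = np.sort(np.asarray(list(thresholds), dtype=float))
    if thresholds.size < 2:
        raise UndefinedStatisticError("need at least 2 thresholds to sweep")
    criterion = np.asarray(criterion, dtype=float)
    if criterion.shape[0] != table.n_records:
        raise UndefinedStatisticError("criterion does not align with the table")
    e2_all = table.squared_differences(trait)
    base = rmsd(table.ext_values(trait), table.int_values(trait))
    n = table.n_records
    rows = []
    groups: list[np.ndarray] = []
    for t in thresholds:
        kept = criterion <= t
        nk = int(kept.sum())
        groups.append(e2_all[kept])
        if nk == 0:
            rows.append((t, 0, 100.0, np.nan, np.nan))
            continue
        r = float(np.sqrt(e2_all[kept].mean()))
        gain = rmsd_gain(base, r) if r > 0 else np.nan
        rows.append((t, nk, 100.0 * (n - nk) / n, r, gain))
    df = pd.DataFrame(
        rows, columns=["threshold", "n_kept", "n_loss_pct", "rmsd", "gain_pct"]
    )
    nonempty = [g for g in groups if g.size > 0]
    if len(nonempty) < 2:
        kw_stat, kw_p = float("nan"), float("nan")
    else:
        try:
            kw_stat, kw_p = stats.kruskal(*nonempty)
        except ValueError:  # all values identical across groups
            kw_stat, kw_p = float("nan"), float("nan")
    k = thresholds.size
    pmat = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        if groups[i].size == 0 or groups[j].size == 0:
            continue
        res = stats.mannwhitneyu(
            groups[i], groups[j], alternative="two-sided", method="asymptotic"
        )
        pmat[i, j] = pmat[j, i] = res.pvalue
    pdf = pd.DataFrame(pmat, index=thresholds, columns=thresholds)
    return SweepResult(
        trait=trait,
        thresholds=thresholds,
        table=df,
        kw_statistic=float(kw_stat),
        kw_pvalue=float(kw_p),
        pairwise_pvalues=pdf,
    )


# ------------------------------------------------------------ method overlap
def method_overlap(masks: Sequence[CleaningMask]) -> pd.DataFrame:
    """Directed overlap of discarded records between rules.

    Entry (A, B) is 100 * |flagged(A) & flagged(B)| / |flagged(A)|; NaN when
    A flags nothing.
    """
    ids = masks[0].sample_ids
    for m in masks[1:]:
        if not np.array_equal(m.sample_ids, ids):
            raise UndefinedStatisticError("masks cover different sample sets")
    names = [m.rule for m in masks]
    out = np.full((len(masks), len(masks)), np.nan)
    for i, a in enumerate(masks):
        na = a.n_flagged
        if na == 0:
            continue
        for j, b in enumerate(masks):
            out[i, j] = 100.0 * np.logical_and(a.flagged, b.flagged).sum() / na
    return pd.DataFrame(out, index=names, columns=names)


def contamination_recovery(
    table: PhenotypeTable, mask: CleaningMask
) -> dict[str, float]:
    """Flagged fraction per true contamination class (synthetic tables only)."""
    if not table.has_column("true_class"):
        raise UndefinedStatisticError("table has no 'true_class' labels")
    labels = table.data["true_class"].to_numpy(dtype=str)
    out = {}
    for cls in np.unique(labels):
        in_cls = labels == cls
        out[str(cls)] = float(mask.flagged[in_cls].mean())
    return out


# -------------------------------------------------------- combination report
@dataclass(frozen=True)
class EvaluationReport:
    """Gain / loss / gain:loss for every rule combination and trait.

    ``table`` is tidy (one row per trait x rule); ``summary()`` renders the
    familiar wide layout with one block per trait.
    """

    table: pd.DataFrame
    best_gain: dict[str, str] = field(default_factory=dict)
    best_ratio: dict[str, str] = field(default_factory=dict)

    def row(self, trait: str, rule: str) -> pd.Series:
        sel = (self.table["trait"] == trait) & (self.table["rule"] == rule)
        return self.table.loc[sel].iloc[0]

    def summary(self) -> str:
        lines = []
        for trait, sub in self.table.groupby("trait", sort=False):
            wide = sub.set_index("rule")[
                ["gain_pct", "n_loss_pct", "gain_loss_ratio"]
            ].T
            wide.index = ["Gain_RMSD (%)", "N loss (%)", "Gain:loss"]
            lines.append(f"=== {trait} "
                         f"(RMSD before cleaning: {sub['rmsd_before'].iloc[0]:.4g} g/dL)")
            lines.append(wide.round(2).to_string())
            lines.append(
                f"best gain: {self.best_gain.get(trait)}   "
                f"best gain:loss: {self.best_ratio.get(trait)}"
            )
            lines.append("")
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def evaluate_cleaning(
    table: PhenotypeTable,
    masks: Mapping[str, Mapping[str, CleaningMask]],
) -> EvaluationReport:
    """Assess every rule combination per trait.

    ``masks[trait]`` maps rule names ("M1", "M2", "M3") to their masks
    computed on ``table``.  For each of the eleven combinations the report
    carries RMSD before/after, gain %, N loss %, gain:loss, the SD of the
    kept external predictions and the INT/EXT Pearson correlation.
    """
    rows = []
    best_gain: dict[str, str] = {}
    best_ratio: dict[str, str] = {}
    for trait in table.traits:
        trait_masks = masks[trait]
        base = rmsd(table.ext_values(trait), table.int_values(trait))
        n = table.n_records
        gains: dict[str, float] = {}
        ratios: dict[str, float] = {}
        for name, components, mode in RULE_COMBINATIONS:
            parts = [trait_masks[c] for c in components]
            mask = parts[0] if mode is None else combine_masks(parts, mode)
            kept = apply_mask(table, mask)
            loss = data_loss(mask)
            if kept.n_records == 0:
                after = gain = ratio = sd_after = r = float("nan")
            else:
                after = rmsd(kept.ext_values(trait), kept.int_values(trait))
                gain = rmsd_gain(base, after) if after > 0 else float("nan")
                ratio = gain / loss if loss > 0 else float("nan")
                ext = kept.ext_values(trait)
                sd_after = float(np.std(ext, ddof=1)) if kept.n_records > 1 else float("nan")
                r = (
                    float(stats.pearsonr(ext, kept.int_values(trait))[0])
                    if kept.n_records > 2 and np.std(ext) > 0
                    else float("nan")
                )
            rows.append(
                {
                    "trait": trait,
                    "rule": name,
                    "n_before": n,
                    "n_after": kept.n_records,
                    "rmsd_before": base,
                    "rmsd_after": after,
                    "gain_pct": gain,
                    "n_loss_pct": loss,
                    "gain_loss_ratio": ratio,
                    "sd_after": sd_after,
                    "r_int_ext": r,
                }
            )
            if np.isfinite(gain):
                gains[name] = gain
            if np.isfinite(ratio):
                ratios[name] = ratio
        if gains:
            best_gain[trait] = max(gains, key=gains.get)
        if ratios:
            best_ratio[trait] = max(ratios, key=ratios.get)
    return EvaluationReport(
        table=pd.DataFrame(rows), best_gain=best_gain, best_ratio=best_ratio
    )
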