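"""End-to-end QC study on a synthetic population.

Glues the stages together the way the procedure runs in practice: build (or
receive) one calibration projection and one prediction equation per trait,
predict the field population, score every spectrum's GH against every
trait's calibration set, prefilter, compute the cleaning masks and assemble
the combination report.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cleaning import (
    CleaningMask,
    RuleThresholds,
    apply_mask,
    icar_prefilter,
    m1_quantile_rule,
    m2_gh_rule,
    m3_fat_residual_rule,
)
from .equations import PredictionEquation, build_prediction_equation
from .evaluation import EvaluationReport, contamination_recovery, evaluate_cleaning
from .preprocessing import first_derivative
from .projection import (
    CalibrationProjection,
    GHResult,
    fit_calibration_projection,
    gh_of_spectra,
)
from .records import PhenotypeTable, gh_col
from .spectra import SpectrumSet
from .synthetic import SyntheticConfig, SyntheticGenerator

logger = logging.getLogger(__name__)


@dataclass
class StudyResult:
    """Everything a QC study produces, from raw population to report."""

    cfg: SyntheticConfig
    thresholds: RuleThresholds
    equations: dict[str, PredictionEquation]
    projections: dict[str, CalibrationProjection]
    spectra: SpectrumSet
    population: PhenotypeTable          # full field population with GH columns
    prefilter_mask: CleaningMask
    base_table: PhenotypeTable          # post-prefilter analysis table
    masks: dict[str, dict[str, CleaningMask]]
    m1_thresholds: dict[str, tuple[float, float]]
    report: EvaluationReport

    def summary(self) -> str:
        return self.report.summary()

    def recovery(self, trait: str, rule: str) -> dict[str, float]:
        """Flagged fraction per true contamination class for one rule."""
        return contamination_recovery(self.base_table, self.masks[trait][rule])


def attach_gh_columns(
    table: PhenotypeTable,
    spectra: SpectrumSet,
    projections: dict[str, CalibrationProjection],
    gap: int,
) -> PhenotypeTable:
    """Score every spectrum against every trait's calibration projection."""
    deriv = first_derivative(spectra, gap)
    for trait, proj in projections.items():
        gh = gh_of_spectra(deriv, proj)
        table = table.with_column(gh_col(trait), gh.gh)
    return table


def compute_rule_masks(
    table: PhenotypeTable, thresholds: RuleThresholds
) -> tuple[dict[str, dict[str, CleaningMask]], dict[str, tuple[float, float]]]:
    """M1/M2/M3 masks per trait on one analysis table.

    M1 thresholds are estimated here (once, on this table) and returned so
    they can be re-applied as fixed cut-offs elsewhere.  M3 is fat-based and
    therefore identical across traits.
    """
    m3 = m3_fat_residual_rule(table, limit=thresholds.m3_fat_limit)
    masks: dict[str, dict[str, CleaningMask]] = {}
    m1_cuts: dict[str, tuple[float, float]] = {}
    for trait in table.traits:
        m1, cuts = m1_quantile_rule(
            table, trait, thresholds.m1_p_low, thresholds.m1_p_high
        )
        gh = GHResult(table.sample_ids, table.gh_values(trait), n_pc=0)
        m2 = m2_gh_rule(gh, limit=thresholds.m2_gh_limit)
        masks[trait] = {"M1": m1, "M2": m2, "M3": m3}
        m1_cuts[trait] = cuts
    return masks, m1_cuts


def run_qc_study(
    cfg: SyntheticConfig | None = None,
    thresholds: RuleThresholds | None = None,
    prefilter: bool = True,
) -> StudyResult:
    """Run the full synthetic QC study under one configuration and seed."""
    cfg = cfg or SyntheticConfig()
    thresholds = thresholds or RuleThresholds()
    gen = SyntheticGenerator(cfg)

    equations: dict[str, PredictionEquation] = {}
    projections: dict[str, CalibrationProjection] = {}
    for spec in cfg.traits:
        calset, values = gen.calibration_set(spec.name)
        equations[spec.name] = build_prediction_equation(
            calset,
            values,
            trait=spec.name,
            gap=cfg.gap,
            n_components=cfg.equation_components,
        )
        deriv = first_derivative(calset, cfg.gap)
        projections[spec.name] = fit_calibration_projection(
            deriv, variance_target=cfg.variance_target
        )
        logger.info(
            "trait %s: equation R^2 %.4f, projection nPC=%d (%.1f%% variance)",
            spec.name,
            equations[spec.name].insample_r2,
            projections[spec.name].n_pc,
            100 * projections[spec.name].variance_covered,
        )

    spectra, population = gen.field_records(equations)
    population = attach_gh_columns(population, spectra, projections, cfg.gap)

    if prefilter:
        pre_mask = icar_prefilter(population, thresholds)
        base = apply_mask(population, pre_mask)
    else:
        pre_mask = CleaningMask(
            population.sample_ids,
            np.zeros(population.n_records, dtype=bool),
            rule="prefilter(disabled)",
        )
        base = population

    masks, m1_cuts = compute_rule_masks(base, thresholds)
    report = evaluate_cleaning(base, masks)
    return StudyResult(
        cfg=cfg,
        thresholds=thresholds,
        equations=equations,
        projections=projections,
        spectra=spectra,
        population=population,
        prefilter_mask=pre_mask,
        base_table=base,
        masks=masks,
        m1_thresholds=m1_cuts,
        report=report,
    )
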