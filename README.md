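# mirqc — quality assurance for milk MIR-predicted phenotypes

Dairy herd improvement (DHI) organizations increasingly predict milk traits —
fat, protein, fatty-acid groups, and many newer phenotypes — from the milk
mid-infrared (MIR) spectrum, applying their own *external* prediction
equations to spectra recorded during routine milk testing. Unlike the
spectrometer's built-in fat and protein predictions, which are slope/bias
corrected through inter-laboratory ring tests, these external predictions
have no routine quality control: a record can be wrong because the milk's
spectrum lies outside the equation's calibration span (spectral
extrapolation), because the spectrum itself is degraded (instrument or
handling failure), or because a spectrum was associated with the wrong
sample. `mirqc` implements the statistical screening rules a DHI
organization can run at database scale to catch these records, and the
evaluation framework to decide which rules are worth their data loss.

## The statistics at the core

**Global-H (GH) applicability distance.** A PCA is fitted to the gap
first-derivative spectra of the equation's calibration set (gap 5 by
default; the number of components `nPC` covers 95% of spectral variance).
A new spectrum with PC score vector x̄ gets

    GH = (x̄ − μ̄)ᵀ S⁻¹ (x̄ − μ̄) / nPC

where μ̄ and S are the mean and covariance of the calibration scores. For a
well-behaved population, `nPC·GH ~ χ²(nPC)`, so GH thresholds translate
into coverage levels. Only the mean derivative spectrum, the eigenvectors
and S need to circulate — never the calibration data.

**Cleaning rules.**

* **M1** deletes records whose external prediction falls outside the
  empirical 1%/99% quantiles of the trait;
* **M2** deletes records with GH above a limit (default 5);
* **M3** deletes records whose absolute fat residual |EXT_fat − INT_fat|
  exceeds a limit (default 0.30 g/dL), the ring-test-corrected internal fat
  content serving as a control value;
* rules combine by intersection (`and`) or union (`or`), after an
  ICAR-style plausibility prefilter (fat 1.5–9.0 g/dL, protein 1.0–7.0
  g/dL, days in milk 5–365).

**Evaluation.** Each strategy is scored by the root mean square difference
`RMSD = sqrt(mean (EXT − INT)²)` between external and internal predictions,
the gain it buys — `gain = (RMSD_before / RMSD_after − 1) · 100` — the
percentage of records lost, and the gain:loss ratio. Threshold sweeps
compare squared differences across cleaned sets with Kruskal–Wallis and
pairwise Wilcoxon rank-sum tests.

Because no public dataset pairs internal and external MIR predictions at
DHI scale, the package ships a fully specified synthetic generator
(`mirqc.synthetic`): low-rank-plus-noise spectra, surrogate
principal-component-regression prediction equations, and field populations
contaminated by the three mechanisms above with known labels, so every
claim about rule behaviour is testable end to end.

## Worked example

```python
from mirqc import SyntheticConfig, RuleThresholds, run_qc_study

study = run_qc_study(SyntheticConfig(seed=7, field_size=5000), RuleThresholds())
fat = study.report.table.query("trait == 'fat'")
cols = ["rule", "rmsd_before", "rmsd_after", "gain_pct", "n_loss_pct", "gain_loss_ratio"]
print(fat[cols].round(3).to_string(index=False))
print("best gain:", study.report.best_gain["fat"])
print("M2 recovery by class:", study.recovery("fat", "M2"))
```

prints

```
            rule  rmsd_before  rmsd_after  gain_pct  n_loss_pct  gain_loss_ratio
              M1        1.667       0.450   270.389       2.006          134.808
              M2        1.667       0.236   605.093       6.713           90.137
              M3        1.667       0.025  6547.502       5.874         1114.672
       M1 and M2        1.667       0.450   270.389       2.006          134.808
       M1 and M3        1.667       0.450   270.389       2.006          134.808
       M2 and M3        1.667       0.233   614.035       4.175          147.067
M1 and M2 and M3        1.667       0.450   270.389       2.006          134.808
        M1 or M2        1.667       0.236   605.093       6.713           90.137
        M1 or M3        1.667       0.025  6547.502       5.874         1114.672
        M2 or M3        1.667       0.024  6988.574       8.412          830.807
  M1 or M2 or M3        1.667       0.024  6988.574       8.412          830.807
best gain: M2 or M3
M2 recovery by class: {'clean': 0.0, 'degraded': 1.0, 'extrapolated': 0.861, 'mismatched': 0.0}
```

Reading the table: the raw population's fat RMSD of 1.667 g/dL is dominated
by the injected contamination. The GH rule (M2) removes extrapolated and
degraded spectra (85–100% of them, no clean records), the fat-residual rule
(M3) additionally removes mismatched records, and their union achieves the
largest gain — the qualitative ranking the framework is built to expose.
Because this synthetic population's outlier tails are dominated by grossly
degraded spectra, M1's 2% trim here coincides with a subset of the other
rules' flags (hence equal "and" rows); on tamer populations M1 trims
ordinary extremes instead. Gains are far larger than on routine field data,
where contamination is milder; magnitudes are population-specific, the
ranking and the gain/loss bookkeeping are what carry over.

The same pipeline is scriptable from the shell: `mirqc simulate`,
`mirqc fit-projection`, `mirqc gh`, `mirqc clean`, `mirqc sweep`,
`mirqc evaluate` (see `mirqc --help`).

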