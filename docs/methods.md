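# Methods

This note documents the statistical procedures implemented in `mirqc`, the
synthetic study population they are exercised on, the defaults and the
reasoning behind them, and what the test suite does and does not establish
about real data.

## 1. The screening problem

Two predictions exist for every milk sample: the spectrometer's internal
prediction `INT` (slope/bias corrected via ring tests, treated as a control
value for fat and protein) and an external prediction `EXT` obtained by
applying a prediction equation to the recorded, standardized spectrum.
Their root mean square difference,

    RMSD = sqrt( mean (EXT − INT)² )        [g/dL],

measures how much the external pipeline disagrees with the controlled one.
Screening rules delete records so that the remaining RMSD drops; each rule
is judged by its RMSD gain, its data loss, and the gain:loss ratio.

**Gain convention.** Gain is the RMSD reduction expressed relative to the
*post-cleaning* value, `gain = (RMSD_before/RMSD_after − 1)·100`. The two
candidate conventions differ materially for strong cleanings; the test
suite pins the convention with reference arithmetic that only the
after-denominator reproduces.

## 2. Preprocessing

* **Piecewise standardization** applies externally supplied per-segment
  linear maps `x → a·x + b` over contiguous index ranges covering the whole
  grid. Only application is implemented; estimating coefficients across
  instruments is a separate (ring-test) exercise out of scope here.
* **Gap first derivative**: `d[i] = a[i+gap] − a[i]`, default gap 5,
  unnormalized, output shortened by `gap` points. It removes additive
  baseline drift exactly (a property the suite tests). Whether one divides
  by the grid spacing is immaterial downstream: PCA directions, regression
  fits and all rank-based statistics are invariant to a fixed affine
  rescaling of the feature space.

## 3. The Global-H distance

A PCA is fitted to the calibration set's derivative spectra (mean-centered
columns, eigendecomposition via thin SVD). `nPC` is the smallest number of
leading components covering `variance_target` (default 0.95) of total
variance; components below 1e−10 of the leading eigenvalue are dropped
before any inversion. For a spectrum with score vector x̄,

    GH = (x̄ − μ̄)ᵀ S⁻¹ (x̄ − μ̄) / nPC ,

with μ̄ the calibration score mean (zero by construction) and S the sample
covariance (denominator n−1) of the calibration scores. Deliberately **no**
n/(n−1) finite-sample inflation is applied: intended calibration sets have
n in the hundreds to thousands, where the factor is ≈ 1. Numerical notes:

* S of PCA scores is diagonal up to round-off and equals the eigenvalues;
  the implementation nevertheless stores and inverts the full S (Cholesky
  solve) so the object stays correct if scores are post-processed. The
  equality is asserted in the tests.
* A condition number of S above 1e12 raises an error advising a lower
  variance target rather than returning unstable distances.
* Two algebraic identities anchor correctness: mean GH of the calibration
  samples over themselves is exactly (n−1)/n, and GH scales quadratically
  when a deviation from the centroid is scaled.
* For multivariate-normal populations `nPC·GH ~ χ²(nPC)`; with nPC = 10 a
  GH limit of 3 covers ≈ 99.91% of the population (the χ²₁₀ CDF at 30), so
  "GH ≤ 3 captures less than 99%" is true only in other settings — smaller
  nPC·limit products, estimated-parameter effects, or non-normality. The
  suite verifies the coverage empirically to ±0.003.

One projection (and one equation) is kept **per trait**, since real
equations come from different calibration sets with different spans.

## 4. Cleaning rules

* Prefilter: keep fat ∈ [1.5, 9.0] g/dL, protein ∈ [1.0, 7.0] g/dL, days in
  milk ∈ [5, 365] (closed intervals), applied to the internal values.
* M1: delete `EXT` outside the empirical (1%, 99%) quantiles (linear
  interpolation between order statistics). Quantiles are computed once on
  the post-prefilter table and treated as fixed thresholds when M1 enters
  combinations; consequently M1 is *not* idempotent if re-estimated on its
  own output (the suite asserts both behaviours).
* M2: delete GH > 5. M3: delete |EXT_fat − INT_fat| > 0.30 g/dL.
* Boundary convention everywhere: equality keeps the record (flags are
  strict inequalities); ties are measure-zero in practice.
* `and` = intersection of deletions (delete only records extreme by every
  rule); `or` = union. Losses therefore order as and ≤ singles ≤ or, which
  the report checks row by row.

## 5. Evaluation

Descriptive statistics report SD with denominator n−1, CV = 100·SD/mean,
and population (biased) standardized third/fourth moments; kurtosis is
excess by default with a raw-moment option, since reporting conventions
differ between software traditions. Threshold sweeps compare squared
differences of the cleaned sets with the Kruskal–Wallis omnibus test and
all pairwise two-sample Wilcoxon rank-sum tests in the tie-corrected normal
approximation (appropriate at the intended n of 10³–10⁵; exact small-sample
tables are not implemented). Pairwise p-values are reported unadjusted with
an optional Bonferroni view. The GH–error association is the Pearson
correlation between GH and (EXT − INT)².

## 6. The synthetic study population

Real paired INT/EXT databases are proprietary, so the generator emulates
the features the screening rules rely on. All randomness descends from one
seed through per-purpose streams (structure, calibration, field factors,
each contamination class, internal predictions, metadata), so changing one
contamination fraction does not perturb the other classes' draws.

**Spectra.** 899 abstract grid points (a standardized-format width; the
grid is abstract because no instrument range is being copied). A fixed
smooth mean curve plus `n_latent = 10` smooth sinusoidal loadings with
geometrically decaying amplitudes (`0.08 · 0.8^k`) times standard-normal
factors z, plus white noise (SD 2e−4). Low-rank-plus-noise structure is
what gives the channels the correlations a Mahalanobis geometry needs; with
these defaults the 95% projection retains ≈ 9–12 components.

**Traits.** Defaults are five traits with population means/SDs (g/dL):
fat 3.93/1.10, protein 3.41/0.42, MFA 0.85/0.32, SFA 2.58/0.76,
UFA 0.92/0.38 — near-normal field distributions with CVs from ≈ 12%
(protein) to ≈ 41% (UFA). Truth for trait t is

    truth = mean_t + sd_t · ( w_t·z + γ·h(u_t·z) ) / scale ,

with w_t a unit vector, h the signed hinge `sign(s)·max(0, |s|−c)²`
(onset c = 3 latent SDs, amplitude γ = 0.15), and `scale` normalizing the
variance analytically. The hinge encodes the applicability-domain premise:
a linear equation fitted on calibration data is essentially exact inside
the calibration span and errs, increasingly, outside it. Its direction u_t
lies in the latent subspace **orthogonal** to all trait vectors w_t, so for
clean records prediction error is independent of the trait level — an
extreme-but-valid cow is not an erroneous one, which is exactly why the
"extreme prediction AND extreme GH" intersection logic can afford to keep
extreme-but-plausible records.

**Surrogate equations.** Principal-component regression (15 components) of
observed calibration values (truth + 0.05 g/dL reference noise) on
derivative spectra of a 1,800-sample calibration set per trait, folded back
to one coefficient vector over derivative features. In-sample R² at the
defaults is ≈ 0.98–0.998, mimicking the very accurate major-component
equations in routine use. Internal predictions are
`INT = slope·(truth + ε) + bias` with ε of SD 0.02 g/dL and slope 1,
bias 0 — a spectrometer kept well calibrated by ring tests.

**Contamination classes** (default 90/5/3/2%):

* *extrapolated* — latent factors drawn with SD multiplied by 5, but only
  in the off-trait subspace: milk whose spectrum is far outside the
  calibration span while its composition stays population-plausible. Such
  records have high GH (≈ 80–88% exceed GH 5 at the defaults) and hinge-
  driven prediction errors, but ordinary trait values.
* *degraded* — the spectrum (not the truth) is corrupted by a structured
  artifact (a spurious smooth signal of 8 latent SDs in the loadings'
  function space), plus white noise (SD 0.2) and a random baseline offset
  (±0.1, invisible after the derivative by design). Structured artifacts
  are what failed instruments produce, and they are what projection-based
  screens can see: white noise alone is nearly orthogonal to smooth
  eigenvectors and would leave GH unmoved — an attenuation effect worth
  remembering when interpreting GH on real noisy spectra. Grossly failed
  spectra are far outside the applicability domain, so the degraded class
  sits essentially entirely above the GH limit and produces large fat
  residuals.
* *mismatched* — spectra are swapped among the mismatched records while
  INT keeps following each record's own truth: a sample/record association
  error. Detectable only through the fat-residual control (≈ 85% at
  0.30 g/dL; the rest are pairs whose true fat contents happen to agree).

**What the generator does not emulate.** Real instrument physics and water
bands; lactation-stage and herd structure in the traits; drift between
standardizations; a *continuum* of spectral quality (classes are discrete);
correlated trait errors from shared chemistry beyond the shared latent
factors. Consequently, passing tests establish that the rules recover the
failure mechanisms they target under controlled conditions — not that
real-world gains will match in magnitude. Contamination here is severe and
discrete, so RMSD gains run to hundreds of percent, far above anything
expected on routine field data; the meaningful outputs are the ranking of
rule combinations, the recovery rates per failure class, and the gain/loss
bookkeeping. With the default conditions, the union "M2 or M3" attains the
best fat gain (it is the only pair covering all three failure mechanisms),
while intersections are the parsimony options; the two largest unions can
differ by well under 1% relative gain, a near-tie that mirrors how close
these options are in practice.

## 7. Problem sizes and determinism

Default study sizes — calibration 1,800 per trait, field population 20,000,
chi-square coverage check 100,000 scores of dimension 10 — were chosen so
that Monte-Carlo error is small against every margin of interest (class
recovery rates have SEs well under 2 percentage points) while a full study
runs in seconds. Identical configurations (including the seed) reproduce
spectra, tables and every downstream file byte for byte; CSV writers use
repr-precision floats so round trips are lossless at 1e−12.

## 8. Known limitations

* M1's behaviour depends on how heavy the population's outlier tails are:
  when gross contamination exceeds ~2%, the 1%/99% quantiles sit inside the
  contaminated cloud and M1 trims only the worst offenders (as in the
  worked example); on mild populations it trims ordinary extremes. Both
  regimes are legitimate; thresholds should be reviewed against the
  population they were estimated from.
* The fat-residual rule inherits the quality of the internal fat value; a
  miscalibrated spectrometer (slope ≠ 1) shifts its operating point.
* GH screens only directions represented in the calibration projection;
  artifacts orthogonal to the retained components (including white noise)
  pass unseen — one reason M2 and M3 are complements, not substitutes.
* The per-trait projection assumes the equation's calibration set is
  available to fit; when only summary objects (mean spectrum, eigenvectors,
  covariance) are provided, they can be loaded directly via the JSON model
  files without refitting.
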