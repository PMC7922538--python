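"""Synthetic milk MIR populations with controlled outlier contamination.

No public dataset pairs manufacturer and external MIR predictions at DHI
scale, so this module generates populations with the statistical structure
the QC analysis assumes, making every downstream stage testable end to end:

* spectra are low-rank-plus-noise: a smooth mean curve plus a smooth latent
  loading matrix times standard-normal factors plus white noise, giving the
  correlated channels a Mahalanobis geometry needs;
* trait truths are a linear combination of the latent factors plus a small
  hinge-shaped nonlinearity that only activates beyond ``nonlinear_onset``
  latent SDs, rescaled to the configured population mean/SD (defaults: fat
  3.93/1.10, protein 3.41/0.42, MFA 0.85/0.32, SFA 2.58/0.76, UFA 0.92/0.38
  g/dL).  The hinge is what makes a linear prediction equation accurate
  inside the calibration span yet degrade outside it — without it the
  surrogate equation would extrapolate perfectly and applicability
  screening would have nothing to find;
* field records are contaminated by three mechanisms: **extrapolated**
  (latent factors drawn with an inflated SD in the subspace orthogonal to
  the traits' linear directions — milk whose spectrum lies outside the
  calibration span while its composition stays plausible), **degraded**
  (a structured spectral artifact plus heavy white noise and a random
  baseline offset — instrument or handling failure that moves the spectrum
  away from the milk actually in the vial) and **mismatched** (the record
  keeps its own truth-based internal values while its spectrum is another
  sample's — a sample/record association error).

The model-error direction of each trait also lives in that orthogonal
subspace, so prediction error is independent of the trait level for clean
records (an extreme-but-valid cow is not an erroneous one) and grows
quadratically with the extrapolation amplitude for extrapolated ones.

Random streams are split per purpose (structure, calibration, field latent
factors, each contamination class, internal predictions, metadata) so that
changing one contamination fraction does not perturb the draws of the other
classes at the same seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate

from .equations import PredictionEquation, build_prediction_equation
from .errors import ConfigurationError
from .records import (
    CLASS_COLUMN,
    ID_COLUMN,
    PhenotypeTable,
    ext_col,
    int_col,
    true_col,
)
from .spectra import SpectrumSet

CLASS_NAMES = ("clean", "extrapolated", "degraded", "mismatched")


@dataclass(frozen=True)
class TraitSpec:
    """Population mean and SD of one trait, g/dL."""

    name: str
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ConfigurationError(f"trait {self.name}: SD must be >= 0")


#: default field-population trait distributions (g/dL)
DEFAULT_TRAITS: tuple[TraitSpec, ...] = (
    TraitSpec("fat", 3.93, 1.10),
    TraitSpec("protein", 3.41, 0.42),
    TraitSpec("mfa", 0.85, 0.32),
    TraitSpec("sfa", 2.58, 0.76),
    TraitSpec("ufa", 0.92, 0.38),
)


@dataclass(frozen=True)
class ContaminationFractions:
    clean: float = 0.90
    extrapolated: float = 0.05
    degraded: float = 0.03
    mismatched: float = 0.02

    def __post_init__(self) -> None:
        probs = self.as_array()
        if np.any(probs < 0) or np.any(probs > 1):
            raise ConfigurationError("contamination fractions must be in [0, 1]")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"contamination fractions must sum to 1, got {probs.sum():.6f}"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.clean, self.extrapolated, self.degraded, self.mismatched]
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the synthetic study population.

    Absorbance-scale parameters (loading_scale, noise SDs) are in arbitrary
    absorbance units on a mean curve of order 1; trait-scale parameters are
    in g/dL.
    """

    n_wavelengths: int = 899
    n_latent: int = 10
    calib_size: int = 1800
    field_size: int = 20000
    traits: tuple[TraitSpec, ...] = DEFAULT_TRAITS
    contamination: ContaminationFractions = field(
        default_factory=ContaminationFractions
    )
    spectral_noise_sd: float = 2e-4       # white noise on every spectrum
    trait_noise_sd: float = 0.05          # g/dL, calibration reference error
    instrument_noise_sd: float = 0.02     # g/dL, internal-prediction error
    degraded_noise_sd: float = 0.2        # white detector noise on degraded spectra
    degraded_artifact_sd: float = 8.0     # structured artifact, latent-score SDs
    degraded_baseline_range: float = 0.1  # uniform baseline offset half-width
    extrapolation_shift: float = 5.0      # latent-SD multiplier (off-trait dims)
    nonlinear_coef: float = 0.15          # hinge model-error amplitude
    nonlinear_onset: float = 3.0          # latent SDs at which the hinge starts
    slope: float = 1.0                    # internal-prediction correction pair
    bias: float = 0.0
    loading_scale: float = 0.08           # leading latent loading amplitude
    loading_decay: float = 0.8            # geometric decay of loading norms
    gap: int = 5
    variance_target: float = 0.95
    equation_components: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_wavelengths", "n_latent", "calib_size", "field_size"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be a positive count")
        for name in (
            "spectral_noise_sd",
            "trait_noise_sd",
            "instrument_noise_sd",
            "degraded_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not self.traits:
            raise ConfigurationError("at least one trait must be configured")
        if not 0 < self.variance_target <= 1:
            raise ConfigurationError("variance_target must be in (0, 1]")

    def trait_names(self) -> tuple[str, ...]:
        return tuple(t.name for t in self.traits)


def simulate_internal_prediction(
    true_values: np.ndarray,
    noise_sd: float,
    slope: float = 1.0,
    bias: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Emulate the spectrometer's ring-test-corrected prediction.

    INT = slope * (true + instrument noise) + bias.
    """
    if noise_sd < 0:
        raise ConfigurationError("noise SD must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    true_values = np.asarray(true_values, dtype=float)
    noise = rng.normal(0.0, noise_sd, size=true_values.shape) if noise_sd > 0 else 0.0
    return slope * (true_values + noise) + bias


class SyntheticGenerator:
    """Deterministic generator of calibration sets and field populations.

    The latent structure (mean curve, loadings, per-trait weights) is drawn
    once from the structure stream of ``cfg.seed``, so calibration sets and
    field records share a single spectral world.
    """

    def __init__(self, cfg: SyntheticConfig):
        self.cfg = cfg
        ss = np.random.SeedSequence(cfg.seed)
        (
            self._ss_structure,
            self._ss_calibration,
            self._ss_field_clean,
            self._ss_extrapolated,
            self._ss_degraded,
            self._ss_mismatched,
            self._ss_internal,
            self._ss_meta,
        ) = ss.spawn(8)
        self._build_structure()

    # ------------------------------------------------------------- structure
    def _build_structure(self) -> None:
        cfg = self.cfg
        rng = np.random.default_rng(self._ss_structure)
        n, k = cfg.n_wavelengths, cfg.n_latent
        x = np.linspace(0.0, 1.0, n)
        # fixed smooth mean curve: broad baseline plus absorption-like bumps
        self.mean_curve = (
            0.5
            + 1.2 * np.exp(-(((x - 0.25) / 0.05) ** 2))
            + 0.8 * np.exp(-(((x - 0.55) / 0.08) ** 2))
            + 0.5 * np.exp(-(((x - 0.8) / 0.04) ** 2))
        )
        # smooth loadings: sinusoids with distinct frequencies, geometric decay
        freqs = np.arange(1, k + 1) + rng.uniform(-0.3, 0.3, size=k)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
        amps = cfg.loading_scale * cfg.loading_decay ** np.arange(k)
        self.loadings = np.stack(
            [
                amps[j] * np.sin(2.0 * np.pi * freqs[j] * x + phases[j])
                for j in range(k)
            ],
            axis=1,
        )  # (n_wavelengths, n_latent)
        # per-trait unit weight vectors (linear part)
        self.trait_weights: dict[str, np.ndarray] = {}
        for spec in cfg.traits:
            w = rng.normal(size=k)
            w /= np.linalg.norm(w)
            self.trait_weights[spec.name] = w
        # orthocomplement of the trait directions: the "off-trait" latent
        # subspace in which spectra can wander without moving composition
        w_mat = np.stack(list(self.trait_weights.values()), axis=1)
        q, _ = np.linalg.qr(w_mat)
        self._p_par = q @ q.T
        self._p_perp = np.eye(k) - self._p_par
        perp_degenerate = np.trace(self._p_perp) < 1.0 - 1e-9
        if perp_degenerate and (
            cfg.nonlinear_coef > 0 or cfg.contamination.extrapolated > 0
        ):
            raise ConfigurationError(
                "n_latent must exceed the number of traits so that an "
                "off-trait spectral subspace exists for extrapolation and "
                "model error"
            )
        # model-error directions: unit vectors in the off-trait subspace, so
        # clean prediction error is independent of trait level
        self.trait_quad: dict[str, np.ndarray] = {}
        for spec in cfg.traits:
            if perp_degenerate:
                self.trait_quad[spec.name] = np.zeros(k)
                continue
            u = self._p_perp @ rng.normal(size=k)
            u /= np.linalg.norm(u)
            self.trait_quad[spec.name] = u
        # Var of the signed hinge for a standard-normal latent coordinate:
        # 2 * int_c^inf (t - c)^4 phi(t) dt, used to normalize trait SDs
        c = cfg.nonlinear_onset
        self._hinge_var = float(
            2.0 * integrate.quad(
                lambda t: (t - c) ** 4 * np.exp(-t * t / 2.0) / np.sqrt(2 * np.pi),
                c, np.inf,
            )[0]
        )
        self.grid = np.arange(n, dtype=float)

    # ------------------------------------------------------------- internals
    def _spectra_from_latent(
        self, z: np.ndarray, rng: np.random.Generator, prefix: str
    ) -> SpectrumSet:
        cfg = self.cfg
        a = self.mean_curve + z @ self.loadings.T
        if cfg.spectral_noise_sd > 0:
            a = a + rng.normal(0.0, cfg.spectral_noise_sd, size=a.shape)
        ids = np.array([f"{prefix}{i:06d}" for i in range(z.shape[0])])
        return SpectrumSet(ids, self.grid, a)

    def _true_trait(self, spec: TraitSpec, z: np.ndarray) -> np.ndarray:
        """Latent signal rescaled to the configured population mean/SD.

        The hinge term sign(t) * max(0, |t| - onset)^2 in the off-trait
        direction u is zero-mean by symmetry and negligible inside the
        calibration span, so a linear equation fits calibration data almost
        perfectly while erring quadratically on extrapolated samples.
        """
        g = self.cfg.nonlinear_coef
        w = self.trait_weights[spec.name]
        u = self.trait_quad[spec.name]
        t = z @ u
        hinge = np.sign(t) * np.maximum(0.0, np.abs(t) - self.cfg.nonlinear_onset) ** 2
        raw = z @ w + g * hinge
        scale = np.sqrt(1.0 + g * g * self._hinge_var)
        return spec.mean + spec.sd * raw / scale

    # ----------------------------------------------------------- public API
    def calibration_set(self, trait: str) -> tuple[SpectrumSet, np.ndarray]:
        """Spectra and observed trait values of the trait's calibration set.

        Each trait gets its own calibration draw (real equations are built
        from different sets), but all share the latent structure.  Observed
        values are truth plus reference-method measurement noise.
        """
        cfg = self.cfg
        spec = self._trait_spec(trait)
        idx = cfg.trait_names().index(trait)
        child = np.random.SeedSequence(
            entropy=self._ss_calibration.entropy,
            spawn_key=self._ss_calibration.spawn_key + (idx,),
        )
        rng = np.random.default_rng(child)
        z = rng.normal(size=(cfg.calib_size, cfg.n_latent))
        spectra = self._spectra_from_latent(z, rng, prefix=f"cal_{trait}_")
        truth = self._true_trait(spec, z)
        if cfg.trait_noise_sd > 0:
            truth = truth + rng.normal(0.0, cfg.trait_noise_sd, size=truth.shape)
        return spectra, truth

    def build_equations(self) -> dict[str, PredictionEquation]:
        """Fit one surrogate prediction equation per configured trait."""
        eqs = {}
        for spec in self.cfg.traits:
            calset, values = self.calibration_set(spec.name)
            eqs[spec.name] = build_prediction_equation(
                calset,
                values,
                trait=spec.name,
                gap=self.cfg.gap,
                n_components=self.cfg.equation_components,
            )
        return eqs

    def field_records(
        self, equations: dict[str, PredictionEquation]
    ) -> tuple[SpectrumSet, PhenotypeTable]:
        """Generate the contaminated field population.

        Per record a contamination class is drawn; spectra are corrupted
        accordingly; EXT values come from applying the equations to the
        (possibly corrupted) spectrum while INT values stay tied to the
        record's own truth.
        """
        cfg = self.cfg
        missing = [t for t in cfg.trait_names() if t not in equations]
        if missing:
            raise ConfigurationError(
                f"no prediction equation for traits: {', '.join(missing)}"
            )
        n = cfg.field_size
        rng_meta = np.random.default_rng(self._ss_meta)
        classes = rng_meta.choice(
            len(CLASS_NAMES), size=n, p=cfg.contamination.as_array()
        )
        labels = np.array(CLASS_NAMES)[classes]

        rng_clean = np.random.default_rng(self._ss_field_clean)
        z = rng_clean.normal(size=(n, cfg.n_latent))
        extr = classes == 1
        if extr.any():
            rng_e = np.random.default_rng(self._ss_extrapolated)
            eps = rng_e.normal(size=(int(extr.sum()), cfg.n_latent))
            # inflate only the off-trait subspace: unusual spectra whose
            # composition remains population-plausible
            z[extr] = eps @ (
                self._p_par + cfg.extrapolation_shift * self._p_perp
            ).T
        spectra = self._spectra_from_latent(z, rng_clean, prefix="fld_")
        absorb = spectra.absorbance.copy()

        degr = classes == 2
        if degr.any():
            rng_d = np.random.default_rng(self._ss_degraded)
            nd = int(degr.sum())
            # structured artifact: a smooth spurious signal in the same
            # function space as genuine spectral variation, so it perturbs
            # the spectrum in directions prediction equations respond to
            artifact = rng_d.normal(
                0.0, cfg.degraded_artifact_sd, size=(nd, cfg.n_latent)
            )
            absorb[degr] += artifact @ self.loadings.T
            absorb[degr] += rng_d.normal(
                0.0, cfg.degraded_noise_sd, size=(nd, cfg.n_wavelengths)
            )
            offsets = rng_d.uniform(
                -cfg.degraded_baseline_range, cfg.degraded_baseline_range, size=nd
            )
            absorb[degr] += offsets[:, None]

        mism = np.flatnonzero(classes == 3)
        if mism.size == 1:
            # lone mismatch: borrow a random other record's spectrum
            rng_m = np.random.default_rng(self._ss_mismatched)
            other = int(rng_m.integers(n - 1))
            if other >= mism[0]:
                other += 1
            absorb[mism[0]] = absorb[other]
        elif mism.size > 1:
            absorb[mism] = absorb[np.roll(mism, 1)]  # cyclic derangement

        spectra = SpectrumSet(spectra.sample_ids, self.grid, absorb)

        rng_int = np.random.default_rng(self._ss_internal)
        data: dict[str, np.ndarray] = {ID_COLUMN: spectra.sample_ids}
        data["cow_id"] = np.array(
            [f"cow{c:05d}" for c in rng_meta.integers(0, max(n // 7, 1), size=n)]
        )
        data["days_in_milk"] = rng_meta.integers(5, 366, size=n)
        data["lactation_number"] = 1 + rng_meta.geometric(0.45, size=n).clip(max=12)
        for spec in cfg.traits:
            truth = self._true_trait(spec, z)
            data[true_col(spec.name)] = truth
            data[int_col(spec.name)] = simulate_internal_prediction(
                truth, cfg.instrument_noise_sd, cfg.slope, cfg.bias, rng_int
            )
            data[ext_col(spec.name)] = equations[spec.name].predict(spectra)
        data[CLASS_COLUMN] = labels
        table = PhenotypeTable(pd.DataFrame(data), cfg.trait_names())
        return spectra, table

    def _trait_spec(self, trait: str) -> TraitSpec:
        for spec in self.cfg.traits:
            if spec.name == trait:
                return spec
        raise ConfigurationError(f"unknown trait '{trait}'")


# --------------------------------------------------- module-level operations
def generate_calibration_set(
    cfg: SyntheticConfig, trait: str
) -> tuple[SpectrumSet, np.ndarray]:
    """Calibration spectra and observed trait values for one trait."""
    return SyntheticGenerator(cfg).calibration_set(trait)


def generate_field_records(
    cfg: SyntheticConfig, equations: dict[str, PredictionEquation]
) -> tuple[SpectrumSet, PhenotypeTable]:
    """Contaminated field population under ``cfg``, predicted by ``equations``."""
    return SyntheticGenerator(cfg).field_records(equations)
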