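"""Synthetic cohorts of serum-fingerprint spectra with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a few hundred metabolite peaks in the 100–1000 Da range, two
clinical groups (EC / NonEC) differing in a small set of planted features
(some up-, some down-regulated on a log2 scale), ~10% per-feature technical
CV, an exponentially decaying low-mass baseline, additive detector noise,
per-sample relative m/z jitter, and random per-sample peak dropout.  A
calibration-series generator supports linearity / limit-of-detection QC.

Every generator is deterministic given its config (which embeds the seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .preprocess import FeatureMatrix, Spectrum, write_spectrum
from .utils import EC, NON_EC

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "CalibrationSeriesConfig",
    "CalibrationSeries",
    "generate_cohort",
    "generate_calibration_series",
    "generate_binormal_panel",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic two-group cohort.

    Defaults reflect the study conditions this package targets: 272 features
    over 100–1000 Da, 3 differential metabolites (two up, one down, |log2
    effect| = 1), 10% technical CV, and a smooth exponential baseline.
    """

    n_per_group: int = 100
    n_features: int = 272
    mz_range: tuple[float, float] = (100.0, 1000.0)
    n_differential: int = 3
    log2_effect_sizes: tuple[float, ...] | None = None  # default: +1, +1, −1 pattern
    technical_cv: float = 0.10
    baseline_amplitude: float = 100.0
    baseline_decay: float = 0.01
    noise_sd: float = 1.0
    mz_jitter_ppm: float = 0.0
    peak_width_sigma: float = 0.25
    grid_step: float = 0.05
    dropout_prob: float = 0.0
    intensity_range: tuple[float, float] = (50.0, 2000.0)
    differential_intensity_min: float = 300.0
    differential_mzs: tuple[float, ...] | None = None  # plant markers at these m/z
    sample_scale_sd: float = 0.0
    confound_age: bool = False
    seed: int = 0

    def effects(self) -> np.ndarray:
        if self.log2_effect_sizes is not None:
            eff = np.asarray(self.log2_effect_sizes, dtype=float)
            if eff.size != self.n_differential:
                raise ConfigurationError(
                    "log2_effect_sizes: length must equal n_differential"
                )
            return eff
        # two up-regulated for every down-regulated marker
        return np.array([1.0 if i % 3 != 2 else -1.0
                         for i in range(self.n_differential)])

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group: must be ≥ 2")
        if self.n_features < 1:
            raise ConfigurationError("n_features: must be ≥ 1")
        if self.n_differential < 0 or self.n_differential > self.n_features:
            raise ConfigurationError(
                "n_differential: must be in [0, n_features]"
            )
        if self.technical_cv < 0:
            raise ConfigurationError("technical_cv: must be ≥ 0")
        if not self.mz_range[0] < self.mz_range[1]:
            raise ConfigurationError("mz_range: lower bound must be < upper")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be ≥ 0")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigurationError("dropout_prob: must be in [0, 1]")
        if self.peak_width_sigma <= 0:
            raise ConfigurationError("peak_width_sigma: must be > 0")
        if self.grid_step <= 0:
            raise ConfigurationError("grid_step: must be > 0")
        if self.mz_jitter_ppm < 0:
            raise ConfigurationError("mz_jitter_ppm: must be ≥ 0")
        if self.baseline_amplitude < 0:
            raise ConfigurationError("baseline_amplitude: must be ≥ 0")
        if self.differential_mzs is not None:
            dm = np.asarray(self.differential_mzs, dtype=float)
            if dm.size != self.n_differential:
                raise ConfigurationError(
                    "differential_mzs: length must equal n_differential"
                )
            lo, hi = self.mz_range
            if np.any(dm <= lo) or np.any(dm >= hi):
                raise ConfigurationError("differential_mzs: must lie inside mz_range")
        self.effects()


@dataclass
class GroundTruth:
    """Everything the generator knows, for parameter-recovery oracles."""

    true_feature_mzs: np.ndarray
    differential_indices: np.ndarray
    class_means: dict[str, np.ndarray]  # group → per-feature mean apex intensity
    sample_scales: np.ndarray  # per-sample multiplicative factor
    true_intensities: np.ndarray  # realized apex intensities, (2n) × n_features
    manifest: pd.DataFrame  # sample_id, group, age, bmi, ca125, menopause, diabetes, stage

    def to_feature_matrix(self) -> FeatureMatrix:
        """The noiseless-alignment view: realized apex intensities as a matrix."""
        return FeatureMatrix(
            sample_ids=[str(s) for s in self.manifest["sample_id"]],
            groups=self.manifest["group"].to_numpy(),
            feature_mzs=self.true_feature_mzs.copy(),
            values=self.true_intensities.copy(),
        )

    def to_json(self, path) -> None:
        payload = {
            "true_feature_mzs": self.true_feature_mzs.tolist(),
            "differential_indices": self.differential_indices.tolist(),
            "class_means": {g: v.tolist() for g, v in self.class_means.items()},
            "sample_scales": self.sample_scales.tolist(),
            "true_intensities": self.true_intensities.tolist(),
            "manifest": self.manifest.to_dict(orient="list"),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            true_feature_mzs=np.array(payload["true_feature_mzs"]),
            differential_indices=np.array(payload["differential_indices"], dtype=int),
            class_means={g: np.array(v) for g, v in payload["class_means"].items()},
            sample_scales=np.array(payload["sample_scales"]),
            true_intensities=np.array(payload["true_intensities"]),
            manifest=pd.DataFrame(payload["manifest"]),
        )


def _feature_positions(cfg: CohortConfig, rng: np.random.Generator) -> np.ndarray:
    """Quasi-regular m/z positions: even spacing plus bounded jitter.

    Guarantees a minimum separation of ~0.4 × spacing so neighbouring peaks
    stay resolvable at the configured peak width.
    """
    lo, hi = cfg.mz_range
    spacing = (hi - lo) / (cfg.n_features + 1)
    centers = lo + spacing * (np.arange(cfg.n_features) + 1)
    jitter = rng.uniform(-0.3 * spacing, 0.3 * spacing, size=cfg.n_features)
    return centers + jitter


def generate_cohort(cfg: CohortConfig) -> tuple[list[Spectrum], GroundTruth]:
    """Generate 2·n_per_group profile spectra plus the generating truth.

    Intensity model per sample i and feature j:
        apex_ij = class_mean(group_i, j) · scale_i · lognormal(cv) · dropout_ij
    and the profile is  baseline + Σ_j apex_ij · Gaussian(mz; mz_ij, σ)
    + N(0, noise_sd), clipped at 0, on a fixed dense grid.  m/z jitter is a
    per-sample relative shift applied to every peak centre.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_group
    n_total = 2 * n
    groups = np.array([EC] * n + [NON_EC] * n)
    sample_ids = [f"{g}_{i + 1:03d}" for g in (EC,) for i in range(n)] + [
        f"{g}_{i + 1:03d}" for g in (NON_EC,) for i in range(n)
    ]

    feature_mzs = _feature_positions(cfg, rng)

    lo_i, hi_i = cfg.intensity_range
    base = np.exp(rng.uniform(np.log(lo_i), np.log(hi_i), size=cfg.n_features))
    if cfg.differential_mzs is not None:
        # pin each planted marker to its requested m/z (nearest slot, in the
        # order given, so effect signs stay attached to their metabolites)
        diff_idx = np.zeros(cfg.n_differential, dtype=int)
        taken: set[int] = set()
        for k, target in enumerate(cfg.differential_mzs):
            order = np.argsort(np.abs(feature_mzs - target))
            slot = next(int(i) for i in order if int(i) not in taken)
            taken.add(slot)
            feature_mzs[slot] = target
            diff_idx[k] = slot
    else:
        diff_idx = rng.choice(cfg.n_features, size=cfg.n_differential, replace=False)
        diff_idx.sort()
    # planted markers sit in the upper intensity range so they are screenable
    floor = max(cfg.differential_intensity_min, lo_i)
    if hi_i > floor:
        base[diff_idx] = np.exp(
            rng.uniform(np.log(floor), np.log(hi_i), size=cfg.n_differential)
        )
    effects = cfg.effects()
    mean_nonec = base.copy()
    mean_ec = base.copy()
    mean_ec[diff_idx] = base[diff_idx] * (2.0 ** effects)
    class_means = {EC: mean_ec, NON_EC: mean_nonec}

    # multiplicative log-normal technical factor with sd/mean = technical_cv
    if cfg.technical_cv > 0:
        s = np.sqrt(np.log1p(cfg.technical_cv**2))
        factors = np.exp(
            s * rng.standard_normal((n_total, cfg.n_features)) - 0.5 * s**2
        )
    else:
        factors = np.ones((n_total, cfg.n_features))

    if cfg.sample_scale_sd > 0:
        ss = np.sqrt(np.log1p(cfg.sample_scale_sd**2))
        scales = np.exp(ss * rng.standard_normal(n_total) - 0.5 * ss**2)
    else:
        scales = np.ones(n_total)

    keep = rng.random((n_total, cfg.n_features)) >= cfg.dropout_prob
    means = np.where(groups[:, None] == EC, mean_ec, mean_nonec)
    true_intensities = means * factors * scales[:, None] * keep

    grid = np.arange(cfg.mz_range[0], cfg.mz_range[1] + cfg.grid_step / 2,
                     cfg.grid_step)
    baseline = cfg.baseline_amplitude * np.exp(
        -cfg.baseline_decay * (grid - grid[0])
    )
    shifts_ppm = (
        rng.normal(0.0, cfg.mz_jitter_ppm, size=n_total)
        if cfg.mz_jitter_ppm > 0
        else np.zeros(n_total)
    )

    half_span = 5.0 * cfg.peak_width_sigma
    spectra = []
    for i in range(n_total):
        profile = baseline.copy()
        centers = feature_mzs * (1.0 + shifts_ppm[i] * 1e-6)
        for j in range(cfg.n_features):
            if true_intensities[i, j] <= 0:
                continue
            a = np.searchsorted(grid, centers[j] - half_span)
            b = np.searchsorted(grid, centers[j] + half_span)
            if a >= b:
                continue
            window = grid[a:b]
            profile[a:b] += true_intensities[i, j] * np.exp(
                -0.5 * ((window - centers[j]) / cfg.peak_width_sigma) ** 2
            )
        if cfg.noise_sd > 0:
            profile = profile + rng.normal(0.0, cfg.noise_sd, size=grid.size)
        spectra.append(
            Spectrum(
                sample_id=sample_ids[i],
                mz=grid.copy(),
                intensity=np.clip(profile, 0.0, None),
                group=groups[i],
            )
        )

    manifest = _simulate_covariates(sample_ids, groups, cfg, rng)
    truth = GroundTruth(
        true_feature_mzs=feature_mzs,
        differential_indices=diff_idx,
        class_means=class_means,
        sample_scales=scales,
        true_intensities=true_intensities,
        manifest=manifest,
    )
    return spectra, truth


def _simulate_covariates(sample_ids, groups, cfg: CohortConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Clinical covariates, drawn independently of class unless confounded.

    CA-125 is always mildly class-associated (the clinical baseline marker,
    AUC in the 0.6–0.7 regime); age shifts by ~7 years in the EC group only
    when ``confound_age`` is set.
    """
    n_total = len(sample_ids)
    is_ec = np.asarray(groups) == EC
    age = rng.normal(55.0, 10.0, size=n_total)
    if cfg.confound_age:
        age = age + 7.0 * is_ec
    age = np.clip(age, 30.0, 85.0)
    bmi = np.clip(rng.normal(25.0, 4.0, size=n_total), 16.0, 45.0)
    ca125 = np.exp(rng.normal(np.log(20.0) + 0.45 * is_ec, 0.5 + 0.3 * is_ec))
    menopause = ((age > 50.0) ^ (rng.random(n_total) < 0.1)).astype(int)
    diabetes = (rng.random(n_total) < 0.12).astype(int)
    stage = np.where(
        is_ec,
        rng.choice(["I", "II", "III", "IV"], size=n_total,
                   p=[0.60, 0.15, 0.18, 0.07]),
        "",
    )
    return pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "age": np.round(age, 1),
            "bmi": np.round(bmi, 1),
            "ca125": np.round(ca125, 2),
            "menopause": menopause,
            "diabetes": diabetes,
            "stage": stage,
        }
    )


def write_cohort(spectra: list[Spectrum], truth: GroundTruth, outdir,
                 dialect: str = "tsv") -> pd.DataFrame:
    """Write one spectrum file per sample plus manifest.csv and truth.json."""
    import os

    os.makedirs(outdir, exist_ok=True)
    ext = {"tsv": "txt", "mzml": "mzML"}[dialect]
    for s in spectra:
        write_spectrum(s, os.path.join(outdir, f"{s.sample_id}.{ext}"),
                       dialect=dialect)
    truth.manifest.to_csv(os.path.join(outdir, "manifest.csv"), index=False)
    truth.to_json(os.path.join(outdir, "truth.json"))
    return truth.manifest


# ---------------------------------------------------------------- calibration


@dataclass(frozen=True)
class CalibrationSeriesConfig:
    """Linear calibration series: intensity = slope·conc + intercept + noise."""

    slope: float = 6.0  # intensity per µM
    intercept: float = 0.0
    concentrations: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0)  # µM
    replicate_count: int = 3
    noise_sd: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        if conc.size < 1 or np.any(conc <= 0) or np.any(np.diff(conc) <= 0):
            raise ConfigurationError(
                "concentrations: must be strictly positive and increasing"
            )
        if self.replicate_count < 2:
            raise ConfigurationError("replicate_count: must be ≥ 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd: must be ≥ 0")


@dataclass
class CalibrationSeries:
    concentrations: np.ndarray  # µM, one per level
    intensities: np.ndarray  # levels × replicates
    config: CalibrationSeriesConfig = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"concentration_uM": c, "replicate": r + 1, "intensity": v}
            for c, level in zip(self.concentrations, self.intensities)
            for r, v in enumerate(level)
        ]
        return pd.DataFrame(rows)


def generate_calibration_series(cfg: CalibrationSeriesConfig) -> CalibrationSeries:
    """Replicate intensities with the configured linear mean structure."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    conc = np.asarray(cfg.concentrations, dtype=float)
    mean = cfg.slope * conc + cfg.intercept
    noise = (
        rng.normal(0.0, cfg.noise_sd, size=(conc.size, cfg.replicate_count))
        if cfg.noise_sd > 0
        else np.zeros((conc.size, cfg.replicate_count))
    )
    return CalibrationSeries(
        concentrations=conc, intensities=mean[:, None] + noise, config=cfg
    )


# ---------------------------------------------------------------- panel-level


def generate_binormal_panel(n_per_group: int = 100, target_auc: float = 0.9,
                            n_markers: int = 3, seed: int = 0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Three-marker intensities with a planted combined bi-normal AUC.

    Each marker is unit-variance normal with a per-class mean offset ±d/2
    (the last marker down-regulated); d is chosen so the optimal linear
    combination has AUC = Φ(d·√m / √2) = ``target_auc``.  Returns
    (intensities, labels) with labels 1 = EC.
    """
    from scipy.stats import norm

    if not 0.5 < target_auc < 1.0:
        raise ConfigurationError("target_auc: must be in (0.5, 1)")
    d = norm.ppf(target_auc) * np.sqrt(2.0) / np.sqrt(n_markers)
    signs = np.array([1.0 if k % 3 != 2 else -1.0 for k in range(n_markers)])
    rng = np.random.default_rng(seed)
    n_total = 2 * n_per_group
    labels = np.array([1] * n_per_group + [0] * n_per_group)
    x = rng.standard_normal((n_total, n_markers))
    x += np.outer(labels - 0.5, d * signs)
    return x, labels
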