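"""Reproducibility and detection-limit statistics.

Three quality-control views of a fingerprint dataset:

* per-feature coefficient-of-variation (CV) distributions across technical
  replicates (the 100·sd/mean reproducibility measure),
* the within-group pairwise similarity "blueprint" (adjusted cosine), and
* calibration-curve linearity with the 3σ/S limit of detection.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats

from .exceptions import ParameterError
from .preprocess import FeatureMatrix
from .synth import CalibrationSeries

__all__ = [
    "CVReport",
    "SimilarityReport",
    "CalibrationResult",
    "cv_report",
    "adjusted_cosine",
    "similarity_blueprint",
    "fit_calibration",
]


@dataclass
class CVReport:
    """Per-feature CVs (percent), their median, and tail fractions per bound."""

    per_feature_cv: dict[float, float]  # feature m/z (or index) → CV %
    median_cv: float
    fraction_within: dict[float, float]  # bound % → fraction of features


@dataclass
class SimilarityReport:
    """Within-group pairwise similarity scores and threshold exceedance."""

    pairwise_scores: dict[tuple[str, str], float]
    frequency_above: dict[str, float]  # group → fraction of pairs > threshold
    threshold: float
    centered: bool


@dataclass
class CalibrationResult:
    """OLS calibration fit: slope S, σ (residual sd), R², and LOD = 3σ/S."""

    slope: float
    intercept: float
    r_squared: float
    sigma: float
    lod: float
    valid: bool


def cv_report(replicate_matrix: np.ndarray, bounds: tuple[float, ...] = (30.0,),
              feature_labels=None) -> CVReport:
    """CV (100·sd/mean, sd with ddof=1) per feature over replicate rows.

    Operates on raw (pre-standardization) intensities.  Features with zero
    mean are excluded with a warning.
    """
    x = np.asarray(replicate_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ParameterError("need a 2-D matrix with ≥ 2 replicate rows")
    if feature_labels is None:
        feature_labels = np.arange(x.shape[1], dtype=float)
    feature_labels = np.asarray(feature_labels, dtype=float)

    mean = x.mean(axis=0)
    ok = mean != 0
    if not ok.all():
        warnings.warn(f"excluding {np.sum(~ok)} zero-mean feature(s) from CV report",
                      stacklevel=2)
    sd = x[:, ok].std(axis=0, ddof=1)
    cvs = 100.0 * sd / mean[ok]
    return CVReport(
        per_feature_cv=dict(zip(feature_labels[ok], cvs)),
        median_cv=float(np.median(cvs)) if cvs.size else float("nan"),
        fraction_within={b: float(np.mean(cvs <= b)) for b in bounds},
    )


def adjusted_cosine(values: np.ndarray, centered: bool = True) -> np.ndarray:
    """Pairwise sample similarity matrix.

    ``centered=True`` is the adjusted cosine: each feature is mean-centered
    across the cohort before row-wise cosine (shift-invariant).  With
    ``centered=False`` the plain cosine of the raw fingerprints is returned,
    in which the shared mean profile dominates.
    """
    x = np.asarray(values, dtype=float)
    if centered:
        x = x - x.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(x, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    sim = (x / safe[:, None]) @ (x / safe[:, None]).T
    sim[norms == 0, :] = np.nan
    sim[:, norms == 0] = np.nan
    return np.clip(sim, -1.0, 1.0)


def similarity_blueprint(m: FeatureMatrix, threshold: float = 0.85,
                         centered: bool = True) -> SimilarityReport:
    """Within-group pairwise similarity with exceedance frequencies.

    Frequencies are over unordered within-group pairs.  Pairs involving a
    sample whose (centered) vector is zero are skipped with a warning.
    """
    groups = np.unique(m.groups)
    for g in groups:
        if np.sum(m.groups == g) < 2:
            raise ParameterError(f"group {g!r} has < 2 samples")
    sim = adjusted_cosine(m.values, centered=centered)
    scores: dict[tuple[str, str], float] = {}
    freq: dict[str, float] = {}
    for g in groups:
        idx = np.flatnonzero(m.groups == g)
        vals = []
        for i, j in itertools.combinations(idx, 2):
            s = sim[i, j]
            if np.isnan(s):
                warnings.warn(
                    f"skipping pair ({m.sample_ids[i]}, {m.sample_ids[j]}): "
                    "zero vector after centering",
                    stacklevel=2,
                )
                continue
            scores[(m.sample_ids[i], m.sample_ids[j])] = float(s)
            vals.append(s)
        freq[str(g)] = float(np.mean(np.asarray(vals) > threshold)) if vals else float("nan")
    return SimilarityReport(pairwise_scores=scores, frequency_above=freq,
                            threshold=threshold, centered=centered)


def fit_calibration(series: CalibrationSeries) -> CalibrationResult:
    """OLS of mean intensity vs concentration; σ = residual sd; LOD = 3σ/S.

    A zero or negative fitted slope flags the result invalid (LOD undefined,
    reported as NaN).
    """
    conc = np.asarray(series.concentrations, dtype=float)
    if conc.size < 3:
        raise ParameterError("need ≥ 3 concentration levels")
    intensities = np.asarray(series.intensities, dtype=float)
    mean_int = intensities.mean(axis=1)
    fit = scipy.stats.linregress(conc, mean_int)
    # σ: method sd — residuals of the individual replicate intensities about
    # the fitted line (not the sd of level means, which would shrink with the
    # replicate count)
    resid = intensities - (fit.intercept + fit.slope * conc)[:, None]
    dof = max(resid.size - 2, 1)
    sigma = float(np.sqrt(np.sum(resid**2) / dof))
    r_squared = float(fit.rvalue**2)
    if fit.slope <= 0:
        return CalibrationResult(slope=float(fit.slope), intercept=float(fit.intercept),
                                 r_squared=r_squared, sigma=sigma,
                                 lod=float("nan"), valid=False)
    return CalibrationResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r_squared,
        sigma=sigma,
        lod=3.0 * sigma / float(fit.slope),
        valid=True,
    )
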