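"""Pilot-based sample-size / power analysis under FDR control.

From a small pilot fingerprint matrix, estimate per-feature standardized
mean differences (Cohen's d, pooled sd) and the proportion of truly null
features; then, for a grid of per-group sample sizes, resimulate cohorts
from the pilot effect model and report the mean Benjamini–Hochberg
true-positive rate among non-null features — "predicted power" at the
target FDR (0.1 by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .exceptions import DataError, ParameterError
from .preprocess import FeatureMatrix
from .utils import binary_labels

__all__ = [
    "PilotSummary",
    "PowerCurve",
    "estimate_effects",
    "predicted_power",
    "two_sample_t_power",
]


@dataclass
class PilotSummary:
    """Per-feature effect sizes from a pilot matrix plus the null proportion."""

    effect_sizes: np.ndarray  # Cohen's d with pooled sd, one per usable feature
    feature_mzs: np.ndarray
    pi0: float  # estimated proportion of truly null features
    n_per_group: tuple[int, int]


@dataclass
class PowerCurve:
    n_grid: np.ndarray  # per-group sample sizes
    predicted_power: np.ndarray  # fraction in [0, 1] per n
    mc_se: np.ndarray  # Monte-Carlo standard error per n
    fdr: float
    pilot: PilotSummary


def estimate_effects(pilot: FeatureMatrix) -> PilotSummary:
    """Cohen's d (pooled sd) per feature plus a conservative null-proportion.

    The null proportion uses the Storey estimator at λ = 0.5 on per-feature
    two-sample t-test p-values, capped at 1.  Features with zero pooled sd
    are excluded with a warning.
    """
    y = binary_labels(pilot.groups)
    n1, n0 = int(y.sum()), int((1 - y).sum())
    if min(n1, n0) < 3:
        raise DataError("pilot needs ≥ 3 samples per group")
    a = pilot.values[y == 1]
    b = pilot.values[y == 0]
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    pooled = np.sqrt(((n1 - 1) * var_a + (n0 - 1) * var_b) / (n1 + n0 - 2))
    ok = pooled > 0
    if not ok.all():
        warnings.warn(
            f"excluding {np.sum(~ok)} zero-variance feature(s) from pilot effects",
            stacklevel=2,
        )
    d = (a.mean(axis=0)[ok] - b.mean(axis=0)[ok]) / pooled[ok]
    pvals = scipy.stats.ttest_ind(a[:, ok], b[:, ok], axis=0).pvalue
    lam = 0.5
    pi0 = min(1.0, float(np.mean(pvals > lam) / (1.0 - lam))) if pvals.size else 1.0
    return PilotSummary(
        effect_sizes=d,
        feature_mzs=pilot.feature_mzs[ok],
        pi0=pi0,
        n_per_group=(n1, n0),
    )


def _partition_effects(summary: PilotSummary, winsorize: bool) -> np.ndarray:
    """Effect vector for resimulation: smallest-|d| pi0-fraction zeroed out.

    Optional winsorizing clips |d| at its 95th percentile to curb pilot
    over-optimism.
    """
    d = summary.effect_sizes.copy()
    m = d.size
    m0 = int(round(summary.pi0 * m))
    order = np.argsort(np.abs(d))
    d[order[:m0]] = 0.0
    if winsorize and np.any(d != 0):
        cap = np.percentile(np.abs(d[d != 0]), 95)
        d = np.clip(d, -cap, cap)
    return d


def predicted_power(summary: PilotSummary, n_grid, fdr: float = 0.1,
                    n_sim: int = 200, seed: int = 0,
                    winsorize: bool = False) -> PowerCurve:
    """Monte-Carlo predicted power across per-group sample sizes.

    For each n: simulate normal cohorts with the pilot effect sizes, run
    per-feature two-sample t-tests, apply Benjamini–Hochberg at the target
    FDR, and average the true-positive rate among non-null features.
    """
    if summary.effect_sizes.size == 0:
        raise ParameterError("pilot summary is empty")
    if not 0 < fdr < 1:
        raise ParameterError("fdr must be in (0, 1)")
    if n_sim < 50:
        warnings.warn("n_sim < 50 gives an unstable power estimate", stacklevel=2)
    d = _partition_effects(summary, winsorize)
    nonnull = d != 0
    n_grid = np.asarray(n_grid, dtype=int)
    if not nonnull.any():
        warnings.warn("no non-null features in pilot; predicted power is 0",
                      stacklevel=2)
        return PowerCurve(
            n_grid=n_grid,
            predicted_power=np.zeros(n_grid.size),
            mc_se=np.zeros(n_grid.size),
            fdr=fdr,
            pilot=summary,
        )

    rng = np.random.default_rng(seed)
    m = d.size
    power = np.zeros(n_grid.size)
    se = np.zeros(n_grid.size)
    for gi, n in enumerate(n_grid):
        tprs = np.zeros(n_sim)
        for s in range(n_sim):
            x1 = rng.standard_normal((n, m)) + d
            x0 = rng.standard_normal((n, m))
            pvals = scipy.stats.ttest_ind(x1, x0, axis=0).pvalue
            reject = multipletests(pvals, alpha=fdr, method="fdr_bh")[0]
            tprs[s] = reject[nonnull].mean()
        power[gi] = tprs.mean()
        se[gi] = tprs.std(ddof=1) / np.sqrt(n_sim)
    return PowerCurve(n_grid=n_grid, predicted_power=power, mc_se=se, fdr=fdr,
                      pilot=summary)


def two_sample_t_power(d: float, n_per_group: int, alpha: float) -> float:
    """Closed-form power of a two-sided two-sample t-test (noncentral t)."""
    df = 2 * n_per_group - 2
    ncp = d * np.sqrt(n_per_group / 2.0)
    crit = scipy.stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        scipy.stats.nct.sf(crit, df, ncp) + scipy.stats.nct.cdf(-crit, df, ncp)
    )
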