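"""Diagnostic model training and evaluation.

Five model families (L1-logistic "LASSO", ridge logistic, PLS-DA, random
forest, decision tree) trained with repeated stratified k-fold
cross-validation, with standardization refit inside every training fold so
no held-out information leaks into the scaling.  ROC machinery includes the
DeLong variance estimate (CIs and the paired two-classifier test), the
Youden operating point, fixed-probability-cutoff operating points, and a
label-permutation test of classifier validity.

The per-feature "LASSO score" used downstream for panel screening is
defined as selection stability × magnitude: the mean absolute standardized
coefficient over all cross-validation fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ConvergenceError, DataError, ParameterError
from .preprocess import FeatureMatrix, apply_standardization, fit_standardization, standardize
from .utils import binary_labels, derive_seed

__all__ = [
    "ModelConfig",
    "ROCCurve",
    "ModelResult",
    "OperatingPoint",
    "roc_auc",
    "delong_variance",
    "delong_ci",
    "delong_test",
    "youden_point",
    "sens_spec_at_cutoff",
    "fit_l1_logistic",
    "repeated_cv",
    "evaluate",
    "permutation_test",
]

ALGORITHMS = ("lasso", "logistic", "plsda", "random_forest", "decision_tree")


@dataclass(frozen=True)
class ModelConfig:
    """One algorithm's training recipe.

    ``l1_penalty`` is the LASSO regularization strength λ (sklearn C = 1/λ);
    0.6 is the operating value this analysis targets.  Five folds repeated
    twenty times is the default cross-validation scheme.
    """

    algorithm: str = "lasso"
    l1_penalty: float = 0.6
    n_folds: int = 5
    n_repeats: int = 20
    seed: int = 0
    probability_cutoff: float = 0.50
    pls_components: int = 2
    n_trees: int = 100

    def validate(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ParameterError(f"unknown algorithm {self.algorithm!r}")
        if self.n_folds < 2:
            raise ParameterError("n_folds must be ≥ 2")
        if self.n_repeats < 1:
            raise ParameterError("n_repeats must be ≥ 1")
        if self.algorithm == "lasso" and self.l1_penalty <= 0:
            raise ParameterError("l1_penalty must be > 0 for lasso")


@dataclass
class ROCCurve:
    """An ROC curve with its AUC and DeLong 95% CI."""

    thresholds: np.ndarray
    sensitivity: np.ndarray  # TPR, fraction in [0, 1]
    specificity: np.ndarray  # TNR, fraction in [0, 1]
    auc: float
    ci95: tuple[float, float]
    degenerate: bool = False
    scores: np.ndarray = field(default=None, repr=False)
    labels: np.ndarray = field(default=None, repr=False)


@dataclass
class OperatingPoint:
    threshold: float
    sensitivity: float  # percent
    specificity: float  # percent
    youden_j: float


@dataclass
class ModelResult:
    """Cross-validated performance plus the final full-data refit."""

    config: ModelConfig
    fold_aucs: np.ndarray  # n_repeats × n_folds
    mean_auc: float
    repeat_mean_aucs: np.ndarray
    final_coefficients: np.ndarray | None
    stability_scores: np.ndarray  # per original feature
    selected_feature_count: int | None
    feature_mzs: np.ndarray
    model: object = field(repr=False, default=None)
    standardization: object = field(repr=False, default=None)


# ---------------------------------------------------------------- ROC / DeLong


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise DataError("need both classes (labels 0 and 1) present")
    return y


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve with midrank-tie AUC (= Mann–Whitney U probability)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise DataError("scores and labels differ in length")
    fpr, tpr, thr = roc_curve(y, s, drop_intermediate=False)
    area = float(roc_auc_score(y, s))
    # trapezoidal area of the stored curve must agree with the rank AUC
    assert abs(_trapezoid_auc(fpr, tpr) - area) < 1e-9
    ci, degen = delong_ci(s, y)
    return ROCCurve(
        thresholds=thr,
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=area,
        ci95=ci,
        degenerate=degen,
        scores=s,
        labels=y,
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, y: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus per-positive (V10) and per-negative (V01) structural parts."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    theta = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n  # one per positive
    v01 = 1.0 - (tz[m:] - ty) / m  # one per negative
    return float(theta), v10, v01


def delong_variance(scores, labels) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    theta, v10, v01 = _delong_components(s, y)
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    return theta, float(var)


def delong_ci(scores, labels, alpha: float = 0.05
              ) -> tuple[tuple[float, float], bool]:
    """Normal-approximation CI from the DeLong variance, clipped to [0, 1].

    Returns ((lo, hi), degenerate); a zero variance with AUC ∈ {0, 1}
    collapses the CI to the point and is flagged degenerate.
    """
    theta, var = delong_variance(scores, labels)
    if var <= 0:
        return (theta, theta), True
    z = scipy.stats.norm.ppf(1.0 - alpha / 2.0)
    half = z * np.sqrt(var)
    return (float(max(theta - half, 0.0)), float(min(theta + half, 1.0))), False


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided paired DeLong test comparing two correlated AUCs."""
    y = _check_binary(labels)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise DataError("paired scores must have identical lengths")
    ta, v10a, v01a = _delong_components(a, y)
    tb, v10b, v01b = _delong_components(b, y)
    m, n = v10a.size, v01a.size
    var = 0.0
    if m > 1:
        c10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (c10[0, 0] + c10[1, 1] - 2 * c10[0, 1]) / m
    if n > 1:
        c01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (c01[0, 0] + c01[1, 1] - 2 * c01[0, 1]) / n
    diff = ta - tb
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * scipy.stats.norm.sf(abs(z)))


def youden_point(r: ROCCurve) -> OperatingPoint:
    """Operating point maximizing J = sens + spec − 1; ties → higher sensitivity."""
    j = r.sensitivity + r.specificity - 1.0
    best = np.flatnonzero(j == j.max())
    k = best[np.argmax(r.sensitivity[best])]
    return OperatingPoint(
        threshold=float(r.thresholds[k]),
        sensitivity=float(100.0 * r.sensitivity[k]),
        specificity=float(100.0 * r.specificity[k]),
        youden_j=float(j[k]),
    )


def sens_spec_at_cutoff(scores, labels, cutoff: float) -> OperatingPoint:
    """Sensitivity/specificity with score ≥ cutoff called positive."""
    y = _check_binary(labels)
    call = np.asarray(scores, dtype=float) >= cutoff
    sens = float(np.mean(call[y == 1])) if np.any(y == 1) else float("nan")
    spec = float(np.mean(~call[y == 0])) if np.any(y == 0) else float("nan")
    return OperatingPoint(
        threshold=float(cutoff),
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        youden_j=sens + spec - 1.0,
    )


# ---------------------------------------------------------------- models


def _make_model(config: ModelConfig, seed: int):
    alg = config.algorithm
    if alg == "lasso":
        return LogisticRegression(l1_ratio=1.0, C=1.0 / config.l1_penalty,
                                  solver="liblinear", max_iter=2000,
                                  random_state=seed)
    if alg == "logistic":
        return LogisticRegression(C=1.0, solver="lbfgs", max_iter=2000)
    if alg == "plsda":
        return PLSRegression(n_components=config.pls_components, scale=False)
    if alg == "random_forest":
        return RandomForestClassifier(n_estimators=config.n_trees,
                                      random_state=seed, n_jobs=1)
    if alg == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ParameterError(f"unknown algorithm {alg!r}")


def _scores_of(model, x: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(x)[:, 1]
    return np.asarray(model.predict(x)).ravel()  # PLS regression response


def _weights_of(model, n_features: int) -> np.ndarray | None:
    if hasattr(model, "coef_"):
        return np.abs(np.asarray(model.coef_)).ravel()[:n_features]
    if hasattr(model, "feature_importances_"):
        return np.abs(model.feature_importances_)
    return None


def fit_l1_logistic(m: FeatureMatrix, l1_penalty: float = 0.6):
    """L1-penalized logistic fit on a standardized matrix.

    Returns (coefficients, intercept); zero-coefficient features are
    "unselected".  Deterministic for fixed data and penalty.
    """
    if l1_penalty <= 0:
        raise ParameterError("l1_penalty must be > 0")
    y = binary_labels(m.groups)
    if len(set(y)) < 2:
        raise DataError("both classes must be present")
    model = LogisticRegression(l1_ratio=1.0, C=1.0 / l1_penalty,
                               solver="liblinear", max_iter=2000, random_state=0)
    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(m.values, y)
        except ConvergenceWarning as exc:
            raise ConvergenceError(
                f"L1 logistic fit did not converge (max_iter=2000): {exc}"
            ) from exc
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def repeated_cv(m: FeatureMatrix, config: ModelConfig) -> ModelResult:
    """Repeated stratified k-fold cross-validation on a raw-intensity matrix.

    Standardization is refit inside each training fold and applied to the
    held-out fold (no leakage).  The final model is refit on the full matrix
    with full-data standardization, for held-out-cohort evaluation.
    """
    config.validate()
    y = binary_labels(m.groups)
    if len(np.unique(y)) < 2:
        raise DataError("both classes must be present in the matrix")

    n_feat = m.n_features
    fold_aucs = np.zeros((config.n_repeats, config.n_folds))
    weight_sum = np.zeros(n_feat)
    n_fits = 0
    for r in range(config.n_repeats):
        skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                              random_state=derive_seed(config.seed, "fold", r))
        for k, (tr, te) in enumerate(skf.split(m.values, y)):
            params, keep = fit_standardization(m.values[tr], m.feature_mzs)
            xtr = (m.values[tr][:, keep] - params.mean) / params.sd
            xte = (m.values[te][:, keep] - params.mean) / params.sd
            model = _make_model(config, derive_seed(config.seed, "fit", r, k))
            model.fit(xtr, y[tr])
            fold_aucs[r, k] = roc_auc_score(y[te], _scores_of(model, xte))
            w = _weights_of(model, int(keep.sum()))
            if w is not None:
                full = np.zeros(n_feat)
                full[keep] = w
                weight_sum += full
                n_fits += 1

    stability = weight_sum / n_fits if n_fits else np.zeros(n_feat)

    m_std = standardize(m)
    final = _make_model(config, derive_seed(config.seed, "final"))
    final.fit(m_std.values, y)
    coef = None
    selected = None
    if hasattr(final, "coef_"):
        coef_kept = np.asarray(final.coef_).ravel()
        coef = np.zeros(n_feat)
        kept_pos = {round(mz, 9): j for j, mz in enumerate(m.feature_mzs)}
        for val, mz in zip(coef_kept, m_std.feature_mzs):
            coef[kept_pos[round(mz, 9)]] = val
        if config.algorithm == "lasso":
            selected = int(np.sum(coef != 0))
    elif hasattr(final, "feature_importances_"):
        coef = np.zeros(n_feat)
        coef[np.isin(np.round(m.feature_mzs, 9), np.round(m_std.feature_mzs, 9))] = (
            final.feature_importances_
        )

    return ModelResult(
        config=config,
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        repeat_mean_aucs=fold_aucs.mean(axis=1),
        final_coefficients=coef,
        stability_scores=stability,
        selected_feature_count=selected,
        feature_mzs=m.feature_mzs.copy(),
        model=final,
        standardization=m_std.standardization,
    )


def evaluate(result: ModelResult, m_validation: FeatureMatrix
             ) -> tuple[np.ndarray, ROCCurve]:
    """Score a held-out raw-intensity matrix with the final refit model."""
    m_std = apply_standardization(m_validation, result.standardization)
    scores = _scores_of(result.model, m_std.values)
    return scores, roc_auc(scores, binary_labels(m_validation.groups))


def permutation_test(m: FeatureMatrix, config: ModelConfig,
                     n_perm: int = 1000, seed: int | None = None) -> float:
    """Label-permutation p-value for the cross-validated mean AUC.

    The full CV pipeline (including in-fold standardization) is rerun for
    every permuted labelling; p = (1 + #{perm ≥ observed}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ParameterError("n_perm must be ≥ 99")
    observed = repeated_cv(m, config).mean_auc
    rng = np.random.default_rng(
        derive_seed(config.seed if seed is None else seed, "perm")
    )
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(m.n_samples)
        m_perm = FeatureMatrix(
            sample_ids=list(m.sample_ids),
            groups=m.groups[perm],
            feature_mzs=m.feature_mzs,
            values=m.values,
        )
        if repeated_cv(m_perm, config).mean_auc >= observed:
            count += 1
    return (1.0 + count) / (n_perm + 1.0)
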