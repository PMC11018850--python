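"""Biomarker-panel selection, accurate-mass annotation, and the Met-score.

Workflow: screen aligned features on three inclusive thresholds (mean raw
intensity Ī ≥ 100, direction-agnostic univariate AUC ≥ 0.70, LASSO
stability score ≥ 0.01); annotate survivors by accurate mass against a
formula table over [M+H]+/[M+Na]+/[M+K]+ adducts within a 3 ppm window;
sum the adduct features per metabolite; fit the Met-score (logistic
probability over the panel metabolites) and its combination with CA-125;
and run the clustering-accuracy and covariate odds-ratio screens.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from pyteomics import mass as pyteomics_mass
from sklearn.cluster import AgglomerativeClustering
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .classify import ModelResult
from .exceptions import DataError, FormulaError, ParameterError
from .preprocess import FeatureMatrix
from .utils import binary_labels

__all__ = [
    "PanelCandidate",
    "Annotation",
    "Panel",
    "PanelLogit",
    "DEFAULT_FORMULA_DB",
    "DEFAULT_ADDUCTS",
    "monoisotopic_mass",
    "adduct_mz",
    "screen_candidates",
    "annotate_by_mass",
    "sum_adducts",
    "fit_met_score",
    "met_score",
    "fit_combined",
    "clustering_accuracy",
    "covariate_screen",
]

ELECTRON_MASS = 5.48579909065e-4  # Da; subtracted so ion masses are exact
_PROTON = 1.007276466621  # H minus one electron

# cation monoisotopic masses net of the electron carried away on ionization
DEFAULT_ADDUCTS: dict[str, float] = {
    "[M+H]+": _PROTON,
    "[M+Na]+": 22.98976928 - ELECTRON_MASS,
    "[M+K]+": 38.9637064864 - ELECTRON_MASS,
}

# Small curated formula table: the three panel metabolites plus common serum
# metabolites acting as decoys.  Users can supply their own (name, formula)
# table; this is not a metabolome database.
DEFAULT_FORMULA_DB: list[tuple[str, str]] = [
    ("glutamine", "C5H10N2O3"),
    ("glucose", "C6H12O6"),
    ("cholesterol linoleate", "C45H76O2"),
    ("alanine", "C3H7NO2"),
    ("proline", "C5H9NO2"),
    ("glutamic acid", "C5H9NO4"),
    ("lactose", "C12H22O11"),
    ("maltotriose", "C18H32O16"),
    ("creatinine", "C4H7N3O"),
    ("urea", "CH4N2O"),
    ("citric acid", "C6H8O7"),
    ("cholesterol", "C27H46O"),
    ("palmitic acid", "C16H32O2"),
    ("oleic acid", "C18H34O2"),
    ("linoleic acid", "C18H32O2"),
    ("tryptophan", "C11H12N2O2"),
    ("phenylalanine", "C9H11NO2"),
    ("leucine", "C6H13NO2"),
    ("arginine", "C6H14N4O2"),
    ("histidine", "C6H9N3O2"),
    ("serine", "C3H7NO3"),
    ("threonine", "C4H9NO3"),
    ("lysine", "C6H14N2O2"),
    ("uric acid", "C5H4N4O3"),
    ("taurine", "C2H7NO3S"),
    ("creatine", "C4H9N3O2"),
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def monoisotopic_mass(formula: str) -> float:
    """Monoisotopic neutral mass of a molecular formula, in Da."""
    pos = 0
    for match in _FORMULA_RE.finditer(formula):
        if match.start() != pos:
            raise FormulaError(
                f"cannot parse formula {formula!r} at {formula[pos:]!r}"
            )
        pos = match.end()
    if pos != len(formula) or not formula:
        raise FormulaError(f"cannot parse formula {formula!r} at {formula[pos:]!r}")
    try:
        return float(pyteomics_mass.calculate_mass(formula=formula))
    except Exception as exc:  # unknown element symbol
        raise FormulaError(f"cannot parse formula {formula!r}: {exc}") from exc


def adduct_mz(formula: str, adduct: str) -> float:
    """Theoretical singly charged adduct m/z (electron mass accounted for)."""
    if adduct not in DEFAULT_ADDUCTS:
        raise ParameterError(f"unknown adduct {adduct!r}")
    return monoisotopic_mass(formula) + DEFAULT_ADDUCTS[adduct]


@dataclass
class Annotation:
    name: str
    formula: str
    adduct: str
    theoretical_mz: float
    ppm_error: float


@dataclass
class PanelCandidate:
    """One screened feature with its selection statistics and annotations."""

    feature_mz: float
    mean_intensity: float  # Ī, raw-intensity units
    univariate_auc: float  # direction-agnostic, in [0.5, 1]
    lasso_score: float
    accurate_mz: float | None = None
    annotations: list[Annotation] = field(default_factory=list)


@dataclass
class PanelLogit:
    """A fitted logistic scorer with its training standardization."""

    coefficients: np.ndarray
    intercept: float
    mean: np.ndarray
    sd: np.ndarray

    def predict(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mean) / self.sd
        eta = z @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class Panel:
    """The metabolite panel: members, summed intensities, and scorers."""

    metabolites: list[tuple[str, str, list[float]]]  # (name, formula, member mzs)
    combined_intensity: np.ndarray  # samples × metabolites
    met_score_model: PanelLogit | None = None
    combined_model: PanelLogit | None = None


def screen_candidates(m: FeatureMatrix, model: ModelResult,
                      i_min: float = 100.0, auc_min: float = 0.70,
                      score_min: float = 0.01) -> list[PanelCandidate]:
    """Screen features on Ī ≥ i_min, AUC ≥ auc_min, LASSO score ≥ score_min.

    ``m`` must be the raw-intensity view (Ī and the univariate AUC are
    computed on raw intensities); the AUC is direction-agnostic
    (max(auc, 1−auc)) so down-regulated markers qualify.  All three
    thresholds are inclusive; results are sorted by LASSO score, descending.
    """
    if i_min <= 0 or auc_min <= 0 or score_min <= 0:
        raise ParameterError("screen thresholds must be positive")
    if model.stability_scores.size != m.n_features:
        raise DataError("model stability scores do not match matrix features")
    y = binary_labels(m.groups)
    out = []
    for j, mz in enumerate(m.feature_mzs):
        col = m.values[:, j]
        if np.all(col == col[0]):
            a = 0.5
        else:
            a = roc_auc_score(y, col)
        a = max(a, 1.0 - a)
        cand = PanelCandidate(
            feature_mz=float(mz),
            mean_intensity=float(col.mean()),
            univariate_auc=float(a),
            lasso_score=float(model.stability_scores[j]),
        )
        if (cand.mean_intensity >= i_min and cand.univariate_auc >= auc_min
                and cand.lasso_score >= score_min):
            out.append(cand)
    out.sort(key=lambda c: c.lasso_score, reverse=True)
    return out


def annotate_by_mass(candidate: PanelCandidate,
                     formula_db: list[tuple[str, str]] | None = None,
                     adducts: list[str] | None = None,
                     ppm_window: float = 3.0) -> PanelCandidate:
    """Attach formula/adduct annotations within ``ppm_window`` of accurate m/z.

    ppm error uses the theoretical m/z in the denominator:
    |observed − theoretical| / theoretical × 1e6.
    """
    if candidate.accurate_mz is None:
        raise ParameterError("candidate has no accurate_mz measurement")
    formula_db = DEFAULT_FORMULA_DB if formula_db is None else formula_db
    adducts = list(DEFAULT_ADDUCTS) if adducts is None else adducts
    observed = candidate.accurate_mz
    annotations = []
    for name, formula in formula_db:
        for adduct in adducts:
            theo = adduct_mz(formula, adduct)
            ppm = abs(observed - theo) / theo * 1e6
            if ppm < ppm_window:
                annotations.append(Annotation(name=name, formula=formula,
                                              adduct=adduct, theoretical_mz=theo,
                                              ppm_error=ppm))
    annotations.sort(key=lambda a: a.ppm_error)
    candidate.annotations = annotations
    return candidate


def sum_adducts(m: FeatureMatrix, member_mzs: list[float]) -> np.ndarray:
    """Per-sample sum of a metabolite's adduct-feature intensities (raw view)."""
    if not member_mzs:
        raise ParameterError("metabolite has no member features")
    pos = {round(mz, 6): j for j, mz in enumerate(m.feature_mzs)}
    try:
        cols = [pos[round(mz, 6)] for mz in member_mzs]
    except KeyError as exc:
        raise DataError(f"member feature {exc.args[0]} not in matrix") from exc
    return m.values[:, cols].sum(axis=1)


def _fit_logit(x: np.ndarray, y: np.ndarray, train: np.ndarray) -> PanelLogit:
    mean = x[train].mean(axis=0)
    sd = x[train].std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (x[train] - mean) / sd
    model = LogisticRegression(C=1e4, solver="lbfgs", max_iter=5000)
    model.fit(z, y[train])
    if model.n_iter_[0] >= 5000:
        raise DataError(f"logistic fit hit the iteration limit ({model.n_iter_[0]})")
    return PanelLogit(coefficients=model.coef_.ravel().copy(),
                      intercept=float(model.intercept_[0]), mean=mean, sd=sd)


def _train_mask(n: int, labels, train_ids, sample_ids) -> np.ndarray:
    if train_ids is None:
        return np.ones(n, dtype=bool)
    idx = [sample_ids.index(s) for s in train_ids]
    mask = np.zeros(n, dtype=bool)
    mask[idx] = True
    return mask


def fit_met_score(panel_intensities: np.ndarray, labels,
                  train_ids=None, sample_ids=None) -> PanelLogit:
    """Logistic model on the panel metabolite intensities.

    Intensities are standardized with training-subset statistics; the
    Met-score of a sample is the model's predicted probability of the
    positive (EC) class.
    """
    x = np.atleast_2d(np.asarray(panel_intensities, dtype=float))
    y = np.asarray(labels).astype(int)
    if x.shape[0] != y.size:
        raise DataError("panel intensities and labels differ in length")
    train = _train_mask(y.size, labels, train_ids, sample_ids)
    return _fit_logit(x, y, train)


def met_score(model: PanelLogit, panel_intensities: np.ndarray) -> np.ndarray:
    """Predicted probability of EC for each sample."""
    return model.predict(np.atleast_2d(np.asarray(panel_intensities, dtype=float)))


def fit_combined(met_scores: np.ndarray, ca125: np.ndarray, labels,
                 train_ids=None, sample_ids=None) -> PanelLogit:
    """Two-covariate logistic model on (Met-score, CA-125).

    The combined diagnostic score is the predicted probability of EC.
    """
    met_scores = np.asarray(met_scores, dtype=float)
    ca125 = np.asarray(ca125, dtype=float)
    if met_scores.shape != ca125.shape:
        raise DataError("met_score and ca125 must be paired (equal length)")
    x = np.column_stack([met_scores, ca125])
    y = np.asarray(labels).astype(int)
    train = _train_mask(y.size, labels, train_ids, sample_ids)
    return _fit_logit(x, y, train)


def clustering_accuracy(panel_intensities: np.ndarray, labels) -> float:
    """Accuracy of 2-group Ward clustering of z-scored panel intensities.

    Clusters are mapped to labels by the better of the two assignments, so
    the result lies in [0.5, 1].
    """
    x = np.atleast_2d(np.asarray(panel_intensities, dtype=float))
    y = np.asarray(labels).astype(int)
    for cls in (0, 1):
        if np.sum(y == cls) < 2:
            raise DataError("need ≥ 2 samples per class")
    if np.all(x == x[0]):
        raise DataError("all samples identical; clustering undefined")
    sd = x.std(axis=0, ddof=0)
    z = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    assign = AgglomerativeClustering(n_clusters=2, linkage="ward").fit_predict(z)
    acc = np.mean(assign == y)
    return float(max(acc, 1.0 - acc))


def _firth_logit(y: np.ndarray, x: np.ndarray, max_iter: int = 100,
                 tol: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Firth bias-reduced logistic regression: (params, covariance).

    Jeffreys-prior penalized Newton iterations; finite estimates and usable
    Wald inference even under (quasi-)separation, where plain ML diverges.
    """
    n, k = x.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = np.clip(x @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        xw = x * w[:, None]
        info = x.T @ xw
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise DataError(f"covariate information matrix singular: {exc}") from exc
        hat = np.einsum("ij,jk,ik->i", x, info_inv, xw)  # leverages
        score = x.T @ (y - p + hat * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = np.clip(x @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv(x.T @ (x * w[:, None]))
    return beta, cov


def covariate_screen(met_scores: np.ndarray, covariates: pd.DataFrame,
                     labels) -> pd.DataFrame:
    """Multivariable logistic odds-ratio screen: label ~ met_score + covariates.

    Continuous covariates are standardized; constant covariates are dropped
    with a warning; collinear covariate pairs raise an error naming them.
    Returns a table with odds_ratio = exp(coef) and Wald p per term.  The
    fit is Firth's bias-reduced logistic regression, so a Met-score that
    separates the classes (common with strong panels) still yields finite
    odds ratios and Wald p-values.
    """
    y = np.asarray(labels).astype(int)
    met_scores = np.asarray(met_scores, dtype=float)
    cols: dict[str, np.ndarray] = {"met_score": met_scores}
    for name in covariates.columns:
        v = covariates[name].to_numpy(dtype=float)
        if np.all(v == v[0]):
            warnings.warn(f"dropping constant covariate {name!r}", stacklevel=2)
            continue
        if set(np.unique(v)) <= {0.0, 1.0}:
            cols[name] = v
        else:
            cols[name] = (v - v.mean()) / v.std(ddof=0)

    names = list(cols)
    xmat = np.column_stack([cols[n] for n in names])
    corr = np.corrcoef(xmat, rowvar=False)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(corr[i, j]) > 0.999:
                raise DataError(
                    f"collinear covariates: {names[i]!r} and {names[j]!r}"
                )

    design = sm.add_constant(xmat)
    params, cov = _firth_logit(y.astype(float), design)
    se = np.sqrt(np.diag(cov))
    z = params / se
    pvals = 2.0 * scipy.stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {
            "term": names,
            "odds_ratio": np.exp(params[1:]),
            "coef": params[1:],
            "p_value": pvals[1:],
        }
    )
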