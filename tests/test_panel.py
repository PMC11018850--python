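"""Panel screening, accurate-mass annotation, Met-score, clustering, covariates."""

import numpy as np
import pandas as pd
import pytest

from smfdx import classify, panel, preprocess, synth
from smfdx.exceptions import DataError, FormulaError, ParameterError
from smfdx.panel import (
    PanelCandidate,
    PanelLogit,
    adduct_mz,
    annotate_by_mass,
    clustering_accuracy,
    covariate_screen,
    fit_combined,
    fit_met_score,
    met_score,
    monoisotopic_mass,
    screen_candidates,
    sum_adducts,
)

from conftest import truth_matrix

# IUPAC monoisotopic atomic masses for the independent summation oracle
ATOMIC = {"C": 12.0, "H": 1.00782503207, "N": 14.0030740048,
          "O": 15.9949146196, "S": 31.97207100}


def oracle_mass(formula):
    import re

    total = 0.0
    for sym, count in re.findall(r"([A-Z][a-z]?)(\d*)", formula):
        if sym:
            total += ATOMIC[sym] * (int(count) if count else 1)
    return total


# ---------------------------------------------------------------- masses


@pytest.mark.parametrize("formula", ["C5H10N2O3", "C6H12O6", "C45H76O2"])
def test_monoisotopic_mass_vs_summation_oracle(formula):
    assert monoisotopic_mass(formula) == pytest.approx(oracle_mass(formula),
                                                       abs=1e-4)


def test_adduct_mass_accounts_for_electron():
    mh = adduct_mz("C6H12O6", "[M+H]+")
    neutral_plus_h = oracle_mass("C6H12O6") + ATOMIC["H"]
    assert mh == pytest.approx(neutral_plus_h - 5.4858e-4, abs=1e-6)


@pytest.mark.parametrize("bad", ["C5H10X2", "c5h10", "C5-H10", ""])
def test_formula_parse_errors(bad):
    with pytest.raises(FormulaError):
        monoisotopic_mass(bad)


def test_unknown_adduct_rejected():
    with pytest.raises(ParameterError):
        adduct_mz("C6H12O6", "[M+NH4]+")


# ---------------------------------------------------------------- annotation


def candidate_at(mz):
    return PanelCandidate(feature_mz=mz, mean_intensity=500.0,
                          univariate_auc=0.9, lasso_score=0.5, accurate_mz=mz)


def test_annotation_exact_match_kept():
    mz = adduct_mz("C5H10N2O3", "[M+H]+")  # glutamine
    cand = annotate_by_mass(candidate_at(mz))
    assert cand.annotations
    best = cand.annotations[0]
    assert best.name == "glutamine"
    assert best.adduct == "[M+H]+"
    assert best.ppm_error == pytest.approx(0.0, abs=1e-9)


def test_annotation_rejects_ten_ppm_offset():
    mz = adduct_mz("C5H10N2O3", "[M+H]+")
    cand = annotate_by_mass(candidate_at(mz * (1 + 10e-6)), ppm_window=3.0)
    assert not any(a.formula == "C5H10N2O3" for a in cand.annotations)


def test_ppm_error_uses_theoretical_denominator():
    """With a 100 ppm offset the observed/theoretical convention matters:
    the error must be |obs − theo| / theo, not / obs."""
    theo = adduct_mz("C6H12O6", "[M+Na]+")
    obs = theo * (1 + 100e-6)
    cand = annotate_by_mass(candidate_at(obs), ppm_window=150.0)
    glucose = [a for a in cand.annotations if a.name == "glucose"
               and a.adduct == "[M+Na]+"][0]
    assert glucose.ppm_error == pytest.approx(abs(obs - theo) / theo * 1e6,
                                              abs=1e-9)
    assert glucose.ppm_error == pytest.approx(100.0, abs=1e-6)


def test_annotation_requires_accurate_mz():
    cand = candidate_at(180.0)
    cand.accurate_mz = None
    with pytest.raises(ParameterError):
        annotate_by_mass(cand)


# ---------------------------------------------------------------- screening


def stub_model(matrix, scores):
    cfg = classify.ModelConfig(n_repeats=1)
    return classify.ModelResult(
        config=cfg, fold_aucs=np.zeros((1, 5)), mean_auc=0.5,
        repeat_mean_aucs=np.zeros(1), final_coefficients=None,
        stability_scores=np.asarray(scores, dtype=float),
        selected_feature_count=None, feature_mzs=matrix.feature_mzs,
    )


def two_feature_matrix(col_a, col_b):
    n = len(col_a)
    return preprocess.FeatureMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        groups=np.array(["EC"] * (n // 2) + ["NonEC"] * (n - n // 2)),
        feature_mzs=np.array([150.0, 250.0]),
        values=np.column_stack([col_a, col_b]),
    )


def test_screen_boundaries_inclusive():
    """Ī = 100, AUC = 0.70 and score = 0.01 all sit exactly on the filter."""
    ec = [110.0] * 7 + [90.0] * 3
    nonec = [90.0] * 7 + [110.0] * 3  # AUC exactly 0.7 either direction
    col_a = np.array(ec + nonec)  # mean exactly 100
    col_b = np.full(20, 1000.0)  # AUC 0.5 → excluded despite intensity
    m = two_feature_matrix(col_a, col_b)
    cands = screen_candidates(m, stub_model(m, [0.01, 5.0]),
                              i_min=100.0, auc_min=0.70, score_min=0.01)
    assert [c.feature_mz for c in cands] == [150.0]
    assert cands[0].mean_intensity == pytest.approx(100.0)
    assert cands[0].univariate_auc == pytest.approx(0.70)
    assert cands[0].lasso_score == pytest.approx(0.01)


def test_screen_direction_agnostic_auc():
    down = np.array([1.0] * 10 + [9.0] * 10) * 100  # down-regulated in EC
    m = two_feature_matrix(down, down[::-1])
    cands = screen_candidates(m, stub_model(m, [1.0, 1.0]))
    assert len(cands) == 2
    assert all(c.univariate_auc >= 0.5 for c in cands)


def test_screen_sorted_by_score_and_validates():
    m = two_feature_matrix(np.array([9.0] * 10 + [1.0] * 10) * 100,
                           np.array([9.0] * 10 + [1.0] * 10) * 100)
    cands = screen_candidates(m, stub_model(m, [0.2, 0.9]))
    assert [c.feature_mz for c in cands] == [250.0, 150.0]
    with pytest.raises(ParameterError):
        screen_candidates(m, stub_model(m, [1, 1]), i_min=0.0)


def test_screen_recovers_planted_panel():
    """Planted markers pass the Ī/AUC/score screen; nulls do not."""
    total_tp = total_kept = 0
    for seed in range(5):
        m, truth = truth_matrix(seed, n_per_group=40, n_features=120,
                                n_differential=3)
        res = classify.repeated_cv(
            m, classify.ModelConfig(algorithm="lasso", n_repeats=3, seed=seed))
        cands = screen_candidates(m, res)
        kept = {c.feature_mz for c in cands}
        planted = set(truth.true_feature_mzs[truth.differential_indices])
        assert planted <= kept  # recall 1 in every seed
        total_tp += len(planted)
        total_kept += len(kept)
    assert total_tp / total_kept >= 0.9


# ---------------------------------------------------------------- adduct sums


def test_sum_adducts_identities(small_matrix):
    one = sum_adducts(small_matrix, [small_matrix.feature_mzs[0]])
    np.testing.assert_allclose(one, small_matrix.values[:, 0])
    m = two_feature_matrix(np.full(6, 3.0), np.full(6, 4.0))
    np.testing.assert_allclose(sum_adducts(m, [150.0, 250.0]), 7.0)
    np.testing.assert_allclose(sum_adducts(m, [250.0, 150.0]),
                               sum_adducts(m, [150.0, 250.0]))
    with pytest.raises(ParameterError):
        sum_adducts(m, [])
    with pytest.raises(DataError):
        sum_adducts(m, [999.0])


# ---------------------------------------------------------------- Met-score


def test_null_logit_scores_one_half():
    model = PanelLogit(coefficients=np.zeros(3), intercept=0.0,
                       mean=np.zeros(3), sd=np.ones(3))
    np.testing.assert_allclose(met_score(model, np.random.rand(5, 3)), 0.5)


def test_met_score_sign_recovery():
    """Fitted coefficient signs match the planted directions (two up, one
    down) in ≥ 95% of seeds."""
    ok = 0
    for seed in range(20):
        x, labels = synth.generate_binormal_panel(n_per_group=60,
                                                  target_auc=0.9, seed=seed)
        model = fit_met_score(x, labels)
        ok += bool(model.coefficients[0] > 0 and model.coefficients[1] > 0
                   and model.coefficients[2] < 0)
    assert ok >= 19


def test_met_score_heldout_auc_matches_design():
    """Panel designed for bi-normal AUC 0.9 scores 0.85–0.95 held out."""
    x_tr, y_tr = synth.generate_binormal_panel(100, target_auc=0.9, seed=0)
    x_te, y_te = synth.generate_binormal_panel(200, target_auc=0.9, seed=1)
    model = fit_met_score(x_tr, y_tr)
    auc = classify.roc_auc(met_score(model, x_te), y_te).auc
    assert 0.85 <= auc <= 0.95


def test_met_score_monotone_in_upregulated_marker():
    x, labels = synth.generate_binormal_panel(80, target_auc=0.9, seed=2)
    model = fit_met_score(x, labels)
    assert model.coefficients[0] > 0
    bumped = x.copy()
    bumped[:, 0] += 1.0
    assert np.all(met_score(model, bumped) >= met_score(model, x))


# ---------------------------------------------------------------- combined


def test_combined_with_uninformative_ca125():
    """Noise CA-125 neither helps nor hurts (±0.03 held-out AUC)."""
    deltas = []
    for seed in range(20):
        rng = np.random.default_rng(seed)
        x_tr, y_tr = synth.generate_binormal_panel(80, 0.9, seed=3 * seed)
        x_te, y_te = synth.generate_binormal_panel(150, 0.9, seed=3 * seed + 1)
        model = fit_met_score(x_tr, y_tr)
        s_tr, s_te = met_score(model, x_tr), met_score(model, x_te)
        ca_tr, ca_te = rng.normal(size=y_tr.size), rng.normal(size=y_te.size)
        comb = fit_combined(s_tr, ca_tr, y_tr)
        auc_alone = classify.roc_auc(s_te, y_te).auc
        auc_comb = classify.roc_auc(
            comb.predict(np.column_stack([s_te, ca_te])), y_te).auc
        deltas.append(auc_comb - auc_alone)
    assert np.mean(np.abs(deltas)) < 0.03


def test_combined_constant_met_score_reduces_to_ca125():
    rng = np.random.default_rng(0)
    labels = np.array([1] * 50 + [0] * 50)
    ca125 = rng.normal(size=100) + labels
    const = np.full(100, 0.7)
    comb = fit_combined(const, ca125, labels)
    auc_comb = classify.roc_auc(
        comb.predict(np.column_stack([const, ca125])), labels).auc
    auc_ca = classify.roc_auc(ca125, labels).auc
    assert auc_comb == pytest.approx(auc_ca, abs=1e-6)


def test_combined_dominates_individual_markers():
    """Two informative independent inputs: combined ≥ max(individual) − 0.01."""
    ok = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        y = np.array([1] * 80 + [0] * 80)
        met = rng.normal(size=160) + 1.2 * y
        ca = rng.normal(size=160) + 0.8 * y
        y_te = np.array([1] * 150 + [0] * 150)
        met_te = rng.normal(size=300) + 1.2 * y_te
        ca_te = rng.normal(size=300) + 0.8 * y_te
        comb = fit_combined(met, ca, y)
        auc_comb = classify.roc_auc(
            comb.predict(np.column_stack([met_te, ca_te])), y_te).auc
        best = max(classify.roc_auc(met_te, y_te).auc,
                   classify.roc_auc(ca_te, y_te).auc)
        ok += auc_comb >= best - 0.01
    assert ok >= 18


# ---------------------------------------------------------------- clustering


def test_clustering_separated_clouds():
    rng = np.random.default_rng(0)
    x = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
    labels = np.array([1] * 20 + [0] * 20)
    assert clustering_accuracy(x, labels) == 1.0


def test_clustering_null_calibration():
    """Labels independent of the data: accuracy stays near chance."""
    accs = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(200, 3))
        labels = np.array([1] * 100 + [0] * 100)
        accs.append(clustering_accuracy(x, labels))
    assert 0.45 <= np.mean(accs) <= 0.62


def test_clustering_planted_panel_separation():
    x, labels = synth.generate_binormal_panel(100, target_auc=0.9, seed=4)
    assert clustering_accuracy(x, labels) >= 0.75


def test_clustering_degenerate_input_rejected():
    with pytest.raises(DataError):
        clustering_accuracy(np.ones((10, 3)), np.array([1] * 5 + [0] * 5))


# ---------------------------------------------------------------- covariates


def covariates_frame(rng, n):
    return pd.DataFrame({
        "age": rng.normal(55, 10, n),
        "bmi": rng.normal(25, 4, n),
        "diabetes": rng.integers(0, 2, n),
        "menopause": rng.integers(0, 2, n),
    })


def test_covariate_screen_constant_dropped():
    rng = np.random.default_rng(0)
    y = np.array([1] * 40 + [0] * 40)
    met = rng.normal(size=80) + y
    covs = covariates_frame(rng, 80)
    covs["diabetes"] = 0
    with pytest.warns(UserWarning, match="diabetes"):
        table = covariate_screen(met, covs, y)
    assert "diabetes" not in set(table.term)
    assert "met_score" in set(table.term)


def test_covariate_screen_null_calibration():
    """Covariates independent of class: ~5% of Wald p-values fall below 0.05."""
    rng = np.random.default_rng(1)
    pvals = []
    for _ in range(200):
        y = np.array([1] * 50 + [0] * 50)
        met = rng.normal(size=100) + 0.8 * y
        covs = covariates_frame(rng, 100)
        table = covariate_screen(met, covs, y)
        pvals.extend(table.loc[table.term != "met_score", "p_value"])
    frac = np.mean(np.asarray(pvals) < 0.05)
    assert 0.01 <= frac <= 0.10


def test_covariate_screen_recovers_age_confounding():
    """With age shifted in the EC group, the age odds ratio is > 1 and
    significant in most seeds."""
    hits = 0
    for seed in range(50):
        # cohort sized near the study scale so the screen has adequate power
        # against the ~7-year planted shift (menopause, derived from age,
        # absorbs part of the signal)
        m, truth = truth_matrix(seed, n_per_group=100, n_features=10,
                                n_differential=3, confound_age=True)
        manifest = truth.manifest
        y = (manifest["group"] == "EC").astype(int).to_numpy()
        rng = np.random.default_rng(seed)
        met = rng.normal(size=y.size) + 1.0 * y
        covs = manifest[["age", "bmi", "diabetes", "menopause"]]
        table = covariate_screen(met, covs, y).set_index("term")
        hits += bool(table.loc["age", "odds_ratio"] > 1
                     and table.loc["age", "p_value"] < 0.05)
    assert hits >= 40


def test_covariate_screen_collinear_rejected():
    rng = np.random.default_rng(0)
    y = np.array([1] * 30 + [0] * 30)
    met = rng.normal(size=60)
    covs = covariates_frame(rng, 60)
    covs["bmi"] = covs["age"] * 2.0 + 1.0
    with pytest.raises(DataError, match="age.*bmi|bmi.*age"):
        covariate_screen(met, covs, y)
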