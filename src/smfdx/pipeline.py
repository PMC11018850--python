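"""End-to-end orchestration: simulate → preprocess → qc → train → evaluate
→ panel → power, driven by one structured config with a single master seed.

Each stage writes its artifacts under the configured output directory and
contributes to a JSON run report; a rerun with the identical config
reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import os
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import classify, panel as panel_mod, power as power_mod, preprocess, qc, synth
from .exceptions import ConfigurationError, DataError
from .utils import EC, NON_EC, binary_labels, derive_seed

log = logging.getLogger("smfdx")

STAGES = ("simulate", "preprocess", "qc", "train", "evaluate", "panel", "power")

# the three panel metabolites, each detected as two adduct forms
PANEL_TARGETS: list[tuple[str, str, tuple[str, str]]] = [
    ("glutamine", "C5H10N2O3", ("[M+H]+", "[M+Na]+")),
    ("glucose", "C6H12O6", ("[M+Na]+", "[M+K]+")),
    ("cholesterol linoleate", "C45H76O2", ("[M+Na]+", "[M+K]+")),
]


def panel_adduct_mzs() -> tuple[list[float], list[float]]:
    """(m/z list, log2 effect list) for the six planted panel adduct features."""
    mzs, effects = [], []
    for name, formula, adducts in PANEL_TARGETS:
        direction = -1.0 if name == "cholesterol linoleate" else 1.0
        for adduct in adducts:
            mzs.append(panel_mod.adduct_mz(formula, adduct))
            effects.append(direction)
    return mzs, effects


@dataclass
class RunConfig:
    """Structured configuration for :func:`run_pipeline`."""

    outdir: str = "smfdx_run"
    master_seed: int = 0
    stages: tuple[str, ...] = STAGES
    spectra_dir: str | None = None  # read spectra instead of simulating
    manifest_path: str | None = None
    spectra_dialect: str = "tsv"
    discovery_fraction: float = 0.6
    simulate: dict = field(default_factory=dict)  # CohortConfig overrides
    preprocess: dict = field(default_factory=dict)
    qc: dict = field(default_factory=dict)
    train: dict = field(default_factory=dict)  # ModelConfig overrides
    panel: dict = field(default_factory=dict)
    power: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigurationError(f"stages: unknown stage(s) {unknown}")
        if not 0 < self.discovery_fraction < 1:
            raise ConfigurationError("discovery_fraction: must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.stages, list):
            cfg.stages = tuple(cfg.stages)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        payload = asdict(self)
        payload["stages"] = list(self.stages)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)


def split_cohort(manifest: pd.DataFrame, discovery_fraction: float, seed: int
                 ) -> tuple[list[str], list[str]]:
    """Stratified discovery/validation split of sample ids."""
    rng = np.random.default_rng(seed)
    discovery, validation = [], []
    for group, sub in manifest.groupby("group"):
        ids = list(sub["sample_id"].astype(str))
        rng.shuffle(ids)
        k = int(round(discovery_fraction * len(ids)))
        discovery.extend(ids[:k])
        validation.extend(ids[k:])
    return sorted(discovery), sorted(validation)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in order; returns the run report."""
    config.validate()
    os.makedirs(config.outdir, exist_ok=True)
    report: dict = {"stages": {}, "master_seed": config.master_seed}
    state: dict = {}

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.time()
        log.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, state, report)
        except Exception as exc:
            raise DataError(f"stage {stage!r} failed: {exc}") from exc
        report["stages"][stage] = report["stages"].get(stage, {})
        report["stages"][stage]["seconds"] = round(time.time() - t0, 2)
        log.info("stage %s: done in %.2fs", stage, time.time() - t0)

    with open(os.path.join(config.outdir, "run_report.json"), "w",
              encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=float)
    return report


def _stage_seed(config: RunConfig, stage: str) -> int:
    return derive_seed(config.master_seed, "stage", stage)


def _simulate(config: RunConfig, state: dict, report: dict) -> None:
    overrides = dict(config.simulate)
    if overrides.pop("plant_panel", True) and "differential_mzs" not in overrides:
        mzs, effects = panel_adduct_mzs()
        overrides.setdefault("n_differential", len(mzs))
        overrides["differential_mzs"] = tuple(mzs)
        overrides.setdefault("log2_effect_sizes", tuple(effects))
    overrides.setdefault("seed", _stage_seed(config, "simulate"))
    overrides.setdefault("mz_jitter_ppm", 50.0)
    overrides.setdefault("dropout_prob", 0.05)
    cfg = synth.CohortConfig(**overrides)
    spectra, truth = synth.generate_cohort(cfg)
    outdir = os.path.join(config.outdir, "spectra")
    synth.write_cohort(spectra, truth, outdir, dialect=config.spectra_dialect)
    state.update(spectra=spectra, truth=truth, manifest=truth.manifest)
    report["stages"]["simulate"] = {
        "n_samples": len(spectra),
        "n_true_features": cfg.n_features,
        "n_differential": cfg.n_differential,
        "spectra_dir": outdir,
    }


def _load_spectra(config: RunConfig, state: dict) -> None:
    manifest = pd.read_csv(config.manifest_path)
    ext = {"tsv": "txt", "mzml": "mzML"}[config.spectra_dialect]
    spectra = []
    for _, row in manifest.iterrows():
        path = os.path.join(config.spectra_dir, f"{row.sample_id}.{ext}")
        spectra.append(preprocess.read_spectrum(
            path, dialect=config.spectra_dialect,
            sample_id=str(row.sample_id), group=row.group))
    state.update(spectra=spectra, manifest=manifest)


def _preprocess(config: RunConfig, state: dict, report: dict) -> None:
    if "spectra" not in state:
        _load_spectra(config, state)
    matrix = preprocess.preprocess_cohort(state["spectra"], state["manifest"],
                                          **config.preprocess)
    matrix.to_csv(os.path.join(config.outdir, "feature_matrix.csv"))
    discovery, validation = split_cohort(
        state["manifest"], config.discovery_fraction,
        _stage_seed(config, "split"))
    state.update(matrix=matrix, discovery_ids=discovery,
                 validation_ids=validation)
    report["stages"]["preprocess"] = {
        "n_samples": matrix.n_samples,
        "n_features": matrix.n_features,
        "n_discovery": len(discovery),
        "n_validation": len(validation),
    }


def _qc(config: RunConfig, state: dict, report: dict) -> None:
    matrix = state["matrix"]
    opts = dict(config.qc)
    # technical-replicate emulation: one pooled sample measured repeatedly
    # (no class signal, no dropout) through the same preprocessing chain
    rep_cfg = synth.CohortConfig(
        n_per_group=opts.get("n_replicates", 10),
        n_features=opts.get("n_features", 272),
        n_differential=0,
        dropout_prob=0.0,
        seed=_stage_seed(config, "qc-replicates"),
    )
    rep_spectra, rep_truth = synth.generate_cohort(rep_cfg)
    rep_matrix = preprocess.preprocess_cohort(rep_spectra, rep_truth.manifest,
                                              **config.preprocess)
    cv = qc.cv_report(rep_matrix.values[rep_matrix.groups == EC], bounds=(30.0,),
                      feature_labels=rep_matrix.feature_mzs)
    sim = qc.similarity_blueprint(matrix, threshold=opts.get("threshold", 0.85),
                                  centered=opts.get("centered", False))
    cal_cfg = synth.CalibrationSeriesConfig(
        seed=_stage_seed(config, "calibration"),
        **opts.get("calibration", {}))
    cal = qc.fit_calibration(synth.generate_calibration_series(cal_cfg))
    pd.DataFrame(
        {"feature_mz": list(cv.per_feature_cv), "cv_percent": list(cv.per_feature_cv.values())}
    ).to_csv(os.path.join(config.outdir, "qc_cv.csv"), index=False)
    report["stages"]["qc"] = {
        "median_cv_percent": cv.median_cv,
        "fraction_cv_within_30pct": cv.fraction_within[30.0],
        "similarity_frequency_above_0.85": sim.frequency_above,
        "calibration_r2": cal.r_squared,
        "lod_uM": cal.lod,
    }
    state["qc"] = report["stages"]["qc"]


def _train(config: RunConfig, state: dict, report: dict) -> None:
    matrix = state["matrix"]
    overrides = dict(config.train)
    algorithms = overrides.pop("algorithms", ["lasso"])
    overrides.setdefault("seed", _stage_seed(config, "train"))
    discovery = matrix.subset(state["discovery_ids"])
    results = {}
    stage_report = {}
    for alg in algorithms:
        mc = classify.ModelConfig(algorithm=alg, **overrides)
        res = classify.repeated_cv(discovery, mc)
        results[alg] = res
        stage_report[alg] = {
            "cv_mean_auc": res.mean_auc,
            "cv_auc_sd_across_repeats": float(res.repeat_mean_aucs.std(ddof=1))
            if res.repeat_mean_aucs.size > 1 else 0.0,
            "selected_feature_count": res.selected_feature_count,
        }
    perm_opts = dict(config.permutation)
    if perm_opts.get("enabled", True):
        perm_cfg = classify.ModelConfig(
            algorithm="lasso",
            l1_penalty=overrides.get("l1_penalty", 0.6),
            n_folds=overrides.get("n_folds", 5),
            n_repeats=perm_opts.get("n_repeats", 1),
            seed=_stage_seed(config, "perm"),
        )
        stage_report["permutation_p"] = classify.permutation_test(
            discovery, perm_cfg, n_perm=perm_opts.get("n_perm", 199))
    state["models"] = results
    report["stages"]["train"] = stage_report


def _evaluate(config: RunConfig, state: dict, report: dict) -> None:
    matrix = state["matrix"]
    validation = matrix.subset(state["validation_ids"])
    manifest = state["manifest"].set_index("sample_id")
    y_val = binary_labels(validation.groups)
    stage_report = {}
    for alg, res in state["models"].items():
        scores, roc = classify.evaluate(res, validation)
        op = classify.youden_point(roc)
        entry = {
            "validation_auc": roc.auc,
            "validation_ci95": list(roc.ci95),
            "youden_sensitivity_pct": op.sensitivity,
            "youden_specificity_pct": op.specificity,
        }
        cutoff = classify.sens_spec_at_cutoff(scores, y_val,
                                              res.config.probability_cutoff)
        entry["cutoff_sensitivity_pct"] = cutoff.sensitivity
        entry["cutoff_specificity_pct"] = cutoff.specificity
        if "ca125" in manifest.columns:
            ca125 = manifest.loc[validation.sample_ids, "ca125"].to_numpy(float)
            ca_roc = classify.roc_auc(ca125, y_val)
            entry["ca125_auc"] = ca_roc.auc
            entry["delong_p_vs_ca125"] = classify.delong_test(scores, ca125, y_val)
        stage_report[alg] = entry
        state.setdefault("validation_scores", {})[alg] = scores
    report["stages"]["evaluate"] = stage_report


def _panel(config: RunConfig, state: dict, report: dict) -> None:
    matrix = state["matrix"]
    truth = state.get("truth")
    opts = dict(config.panel)
    model = state["models"].get("lasso") or next(iter(state["models"].values()))
    discovery_raw = matrix.subset(state["discovery_ids"])
    candidates = panel_mod.screen_candidates(
        discovery_raw, model,
        i_min=opts.get("i_min", 100.0),
        auc_min=opts.get("auc_min", 0.70),
        score_min=opts.get("score_min", 0.01),
    )
    # emulate the high-resolution accurate-mass measurement: the generator's
    # exact peak position stands in for the FT-ICR read-back
    if truth is not None:
        for cand in candidates:
            j = int(np.argmin(np.abs(truth.true_feature_mzs - cand.feature_mz)))
            cand.accurate_mz = float(truth.true_feature_mzs[j])
    else:
        for cand in candidates:
            cand.accurate_mz = cand.feature_mz
    ppm_window = opts.get("ppm_window", 3.0)
    for cand in candidates:
        panel_mod.annotate_by_mass(cand, ppm_window=ppm_window)

    members: dict[str, list[float]] = {}
    formulas: dict[str, str] = {}
    for cand in candidates:
        for ann in cand.annotations[:1]:  # best annotation per feature
            members.setdefault(ann.name, []).append(cand.feature_mz)
            formulas[ann.name] = ann.formula
    metabolites = [(name, formulas[name], mzs) for name, mzs in members.items()]

    stage_report = {
        "n_candidates": len(candidates),
        "candidate_mzs": [round(c.feature_mz, 4) for c in candidates],
        "identified_metabolites": sorted(members),
    }

    if metabolites:
        intensities = np.column_stack(
            [panel_mod.sum_adducts(matrix, mzs) for _, _, mzs in metabolites]
        )
        y = binary_labels(matrix.groups)
        disc_idx = matrix.row_index(state["discovery_ids"])
        val_idx = matrix.row_index(state["validation_ids"])
        scorer = panel_mod.fit_met_score(intensities, y,
                                         train_ids=state["discovery_ids"],
                                         sample_ids=matrix.sample_ids)
        scores = panel_mod.met_score(scorer, intensities)
        met_auc_val = classify.roc_auc(scores[val_idx], y[val_idx]).auc
        manifest = state["manifest"].set_index("sample_id")
        ca125 = manifest.loc[matrix.sample_ids, "ca125"].to_numpy(float)
        combined = panel_mod.fit_combined(scores, ca125, y,
                                          train_ids=state["discovery_ids"],
                                          sample_ids=matrix.sample_ids)
        combined_scores = combined.predict(np.column_stack([scores, ca125]))
        combined_auc_val = classify.roc_auc(combined_scores[val_idx],
                                            y[val_idx]).auc
        accuracy = panel_mod.clustering_accuracy(intensities, y)
        covars = manifest.loc[matrix.sample_ids,
                              ["age", "bmi", "diabetes", "menopause"]]
        screen = panel_mod.covariate_screen(scores, covars, y)
        screen.to_csv(os.path.join(config.outdir, "covariate_screen.csv"),
                      index=False)
        stage_report.update(
            met_score_validation_auc=met_auc_val,
            combined_validation_auc=combined_auc_val,
            clustering_accuracy_pct=100.0 * accuracy,
            covariate_odds_ratios={
                row.term: {"odds_ratio": row.odds_ratio, "p": row.p_value}
                for row in screen.itertuples()
            },
        )
        state["panel"] = panel_mod.Panel(
            metabolites=metabolites, combined_intensity=intensities,
            met_score_model=scorer, combined_model=combined)
        state["met_scores"] = scores
    report["stages"]["panel"] = stage_report


def _power(config: RunConfig, state: dict, report: dict) -> None:
    matrix = state["matrix"]
    opts = dict(config.power)
    pilot_n = opts.get("pilot_n_per_group", 6)
    rng = np.random.default_rng(_stage_seed(config, "power"))
    pilot_ids = []
    for group in (EC, NON_EC):
        ids = [s for s, g in zip(matrix.sample_ids, matrix.groups) if g == group]
        pilot_ids.extend(rng.choice(ids, size=min(pilot_n, len(ids)),
                                    replace=False))
    pilot = matrix.subset(sorted(pilot_ids))
    summary = power_mod.estimate_effects(pilot)
    curve = power_mod.predicted_power(
        summary,
        n_grid=opts.get("n_grid", (25, 50, 100, 200)),
        fdr=opts.get("fdr", 0.1),
        n_sim=opts.get("n_sim", 100),
        seed=_stage_seed(config, "power-sim"),
    )
    pd.DataFrame(
        {"n_per_group": curve.n_grid, "predicted_power": curve.predicted_power,
         "mc_se": curve.mc_se}
    ).to_csv(os.path.join(config.outdir, "power_curve.csv"), index=False)
    report["stages"]["power"] = {
        "pilot_n_per_group": pilot_n,
        "pi0": summary.pi0,
        "n_grid": curve.n_grid.tolist(),
        "predicted_power": curve.predicted_power.tolist(),
    }


_STAGE_FUNCS = {
    "simulate": _simulate,
    "preprocess": _preprocess,
    "qc": _qc,
    "train": _train,
    "evaluate": _evaluate,
    "panel": _panel,
    "power": _power,
}
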