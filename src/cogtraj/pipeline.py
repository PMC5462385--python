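"""End-to-end orchestration of the trajectory analysis.

One config drives all stages — simulate (or load) the raw tables, build the
analysis cohort, fit/sweep the latent class growth models, characterise the
classes, and evaluate baseline prediction — writing machine-readable
artifacts plus a manifest (config, seeds, row counts, stage timings) under
a run directory. A single global seed is expanded into independent
per-stage streams, so changing one stage's settings never perturbs the
draws of another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import characterize as ch
from . import lcga, predict, preprocess
from . import synthetic as syn

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run", "STAGES"]

STAGES = ("simulate", "preprocess", "fit", "sweep", "characterize", "predict", "all")

#: adjusters always kept in the multinomial model
FORCED_VARIABLES = ["age_at_baseline", "education_band", "gender", "ethnicity",
                    "baseline_mmse"]


@dataclass
class PipelineConfig:
    """Settings for every stage; defaults reproduce the study conditions."""

    # input tables (ignored when simulate=True)
    scores_path: str | None = None
    prescriptions_path: str | None = None
    honos_path: str | None = None
    demographics_path: str | None = None
    diagnoses_path: str | None = None
    simulate: bool = True
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    # lcga
    k: int = 6
    k_max: int = 10
    restarts: int = 20
    tol: float = 1e-8
    max_iter: int = 1000
    blrt_reps: int = 99

    # characterization
    alpha: float = 0.05
    reference_class: int = 4

    # prediction
    class_pair: tuple = (3, 4)
    positive_class: int = 4
    split_ratio: float = 0.8
    cv_folds: int = 10
    cv_repeats: int = 5

    seed: int = 0
    out_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.class_pair, list):
            cfg.class_pair = tuple(cfg.class_pair)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["class_pair"] = list(self.class_pair)
        return d

    def validate(self) -> None:
        if not self.simulate:
            for name in ("scores_path",):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} is required when simulate is false")
                if not Path(p).exists():
                    raise ValueError(f"{name}: no such file {p!r}")

    def stage_seeds(self) -> dict:
        """Independent per-stage integer seeds derived from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(5)
        names = ["simulate", "fit", "blrt", "characterize", "predict"]
        return {
            n: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31)
            for n, c in zip(names, children)
        }


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=str))


def _fit_to_dict(fit: lcga.FitResult) -> dict:
    return {
        "k_effective": fit.k_effective,
        "loglik": fit.loglik,
        "n_obs": fit.n_obs,
        "n_subjects": fit.n_subjects,
        "n_params": fit.n_params,
        "aic": fit.aic,
        "bic": fit.bic,
        "eic": fit.eic,
        "iterations": fit.iterations,
        "converged": fit.converged,
        "time_center": fit.model.time_center,
        "beta": fit.model.beta.tolist(),
        "sigma": fit.model.sigma.tolist(),
        "pi": fit.model.pi.tolist(),
        "coefficient_se": fit.coefficient_se.tolist(),
    }


def run(command: str, config: PipelineConfig, run_dir: str | Path | None = None) -> Path:
    """Execute one stage (or ``all``) and return the run directory.

    Artifacts are deterministic for a fixed config; the manifest records the
    config hash, per-stage seeds, row counts and timings.
    """
    if command not in STAGES:
        raise ValueError(f"unknown command {command!r}; expected one of {STAGES}")
    config.validate()
    seeds = config.stage_seeds()
    out_root = Path(config.out_dir)
    if run_dir is None:
        stamp = time.strftime("%Y%m%d-%H%M%S")
        run_dir = out_root / f"run-{stamp}"
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    cfg_text = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "command": command,
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "stage_seeds": seeds,
        "stages": {},
    }
    stages = (
        ["simulate", "preprocess", "sweep", "characterize", "predict"]
        if command == "all"
        else [command]
    )

    state: dict = {}
    try:
        for stage in stages:
            t0 = time.perf_counter()
            _run_stage(stage, config, seeds, run_dir, state)
            manifest["stages"][stage] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **state.get(f"{stage}_info", {}),
            }
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(run_dir / "manifest.json", manifest)
        raise
    _write_json(run_dir / "manifest.json", manifest)
    return run_dir


def _load_tables(config: PipelineConfig, run_dir: Path):
    base = run_dir / "raw"
    if config.simulate and (base / "scores.csv").exists():
        read = lambda n: pd.read_csv(base / f"{n}.csv")
        return read("scores"), read("prescriptions"), read("honos"), read("demographics")
    paths = {
        "scores": config.scores_path,
        "prescriptions": config.prescriptions_path,
        "honos": config.honos_path,
        "demographics": config.demographics_path,
    }
    out = []
    for name, p in paths.items():
        out.append(pd.read_csv(p) if p else pd.DataFrame())
    return tuple(out)


def _run_stage(stage, config, seeds, run_dir, state):
    if stage == "simulate":
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", seeds["simulate"])
        sim = syn.SimulationConfig(**sim_kwargs)
        cohort = syn.generate_cohort(sim)
        syn.write_cohort(cohort, run_dir / "raw")
        diag = syn.generate_diagnoses(cohort.true_labels, rng=seeds["simulate"] + 1)
        diag.to_csv(run_dir / "raw" / "diagnoses.csv", index=False)
        state["cohort"] = cohort
        state["simulate_info"] = {
            "n_subjects": int(sim.n_subjects),
            "n_score_records": len(cohort.scores),
            "truncation_rate": cohort.truncation_rate,
        }
        return

    if stage == "preprocess":
        scores, rx, honos, demo = _load_tables(config, run_dir)
        clean, profiles, report = preprocess.make_analysis_cohort(
            scores, demographics=demo, prescriptions=rx, honos=honos
        )
        clean.to_csv(run_dir / "clean_scores.csv", index=False)
        profiles.to_csv(run_dir / "baseline_profiles.csv")
        (run_dir / "preprocess_report.json").write_text(report.to_json())
        state["clean"] = clean
        state["profiles"] = profiles
        state["preprocess_info"] = {
            "n_subjects": report.n_subjects_retained,
            "n_records": report.n_records_retained,
        }
        return

    clean = state.get("clean")
    if clean is None:
        clean = pd.read_csv(run_dir / "clean_scores.csv")
        state["clean"] = clean

    if stage == "fit":
        fit = lcga.fit_lcga(
            clean, config.k, restarts=config.restarts, tol=config.tol,
            max_iter=config.max_iter, seed=seeds["fit"],
        )
        state["fit"] = fit
        _write_json(run_dir / f"fit_k{config.k}.json", _fit_to_dict(fit))
        lcga.assign_classes(fit).to_csv(run_dir / "assignments.csv")
        state["fit_info"] = {"loglik": fit.loglik, "bic": fit.bic}
        return

    if stage == "sweep":
        rows, selected, fits = lcga.model_selection_sweep(
            clean, config.k_max, B=config.blrt_reps, seed=seeds["blrt"],
            restarts=config.restarts, tol=config.tol, max_iter=config.max_iter,
        )
        lcga.sweep_to_frame(rows).to_csv(run_dir / "model_selection.csv", index=False)
        fit = fits[selected]
        state["fit"] = fit
        _write_json(run_dir / f"fit_k{selected}.json", _fit_to_dict(fit))
        lcga.assign_classes(fit).to_csv(run_dir / "assignments.csv")
        state["sweep_info"] = {"selected_k": selected}
        return

    # downstream stages need assignments + profiles
    if "fit" in state:
        assignments_df = lcga.assign_classes(state["fit"])
    else:
        assignments_df = pd.read_csv(run_dir / "assignments.csv", index_col=0)
    assignments = assignments_df["assigned_class"]
    profiles = state.get("profiles")
    if profiles is None:
        profiles = pd.read_csv(
            run_dir / "baseline_profiles.csv", index_col=0,
            parse_dates=["baseline_date"],
        )
        med_cols = [c for c in profiles.columns if c.startswith("med_")]
        profiles[med_cols] = profiles[med_cols].isin([True, "True", 1, "1"])
        state["profiles"] = profiles

    if stage == "characterize":
        tests = ch.global_association_tests(
            assignments, profiles, seed=seeds["characterize"]
        )
        ch.association_frame(tests).to_csv(run_dir / "global_tests.csv", index=False)
        significant = [
            t.variable for t in tests
            if t.p_value is not None and t.p_value < config.alpha
        ]
        candidates = [v for v in significant if v not in FORCED_VARIABLES]
        variables = [v for v in FORCED_VARIABLES if v in profiles.columns] + candidates
        X, blocks = ch.build_design(profiles, variables)
        forced = [v for v in FORCED_VARIABLES if v in blocks]
        model, ledger = ch.stepwise_aic(
            assignments, X, blocks, candidates, forced,
            config.reference_class, alpha=config.alpha,
        )
        ledger.to_csv(run_dir / "stepwise_aic.csv", index=False)
        _write_multinomial(model, run_dir / "multinomial_rrr.csv")
        # posterior-weighted sensitivity fit on the same design
        post_cols = [c for c in assignments_df.columns if c != "assigned_class"]
        posteriors = assignments_df[post_cols]
        posteriors.columns = [int(c) for c in posteriors.columns]
        sel_cols = [c for b in getattr(model, "selected_blocks") for c in blocks[b]]
        wmodel = ch.weighted_multinomial(
            posteriors, X[sel_cols], config.reference_class, alpha=config.alpha
        )
        _write_multinomial(wmodel, run_dir / "multinomial_rrr_weighted.csv")
        diag_path = (
            Path(config.diagnoses_path)
            if config.diagnoses_path
            else run_dir / "raw" / "diagnoses.csv"
        )
        if diag_path.exists():
            diagnoses = pd.read_csv(diag_path)
            ch.compare_proportions(
                assignments, diagnoses, focus_pair=config.class_pair,
                seed=seeds["characterize"],
            ).to_csv(run_dir / "diagnosis_tests.csv", index=False)
        state["characterize_info"] = {
            "n_comparisons": model.n_comparisons,
            "n_selected": model.n_selected,
        }
        return

    if stage == "predict":
        result = predict.run_prediction(
            profiles, assignments, class_pair=config.class_pair,
            positive_class=config.positive_class, ratio=config.split_ratio,
            folds=config.cv_folds, repeats=config.cv_repeats,
            seed=seeds["predict"],
        )
        m = result["metrics"]
        m.counts.to_csv(run_dir / "confusion_matrix.csv")
        _write_json(
            run_dir / "prediction_metrics.json",
            {
                "accuracy": m.accuracy,
                "accuracy_ci": list(m.accuracy_ci),
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "auc": m.auc,
                "positive_class": m.positive_class,
                "selected_features": result["rfe"].selected,
                "score_type": "svm_decision_value",
            },
        )
        result["predictions"].to_frame().join(result["decision_scores"]).to_csv(
            run_dir / "predictions.csv"
        )
        state["predict_info"] = {"accuracy": m.accuracy, "auc": m.auc}
        return

    raise AssertionError(f"unhandled stage {stage}")


def _write_multinomial(model, path: Path) -> None:
    """Long-format RRR table: one row per class-contrast x covariate."""
    rows = []
    for cls in model.coef.index:
        for cov in model.coef.columns:
            rows.append(
                {
                    "class_vs_ref": cls,
                    "covariate": cov,
                    "coef": model.coef.loc[cls, cov],
                    "se": model.se.loc[cls, cov],
                    "rrr": model.rrr.loc[cls, cov],
                    "p_raw": model.p_raw.loc[cls, cov],
                    "p_fdr": model.p_fdr.loc[cls, cov] if model.p_fdr is not None else None,
                    "ci_low": model.ci_low.loc[cls, cov] if model.ci_low is not None else None,
                    "ci_high": model.ci_high.loc[cls, cov] if model.ci_high is not None else None,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
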