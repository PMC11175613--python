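"""End-to-end orchestration: simulate -> predict -> indices ->
commonality -> report, with every stage's output written as CSV/JSON
under one run directory. Re-running the same config reproduces all
numeric outputs bit-wise.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    FeatureSetCollection,
    demo_spec,
    generate_cohort,
    load_cohort,
    study_spec,
    write_cohort,
)
from .commonality import analysis_suite
from .config import RunConfig
from .engine import (
    HyperGrid,
    assemble_out_of_fold,
    default_stack_specs,
    importance_stability,
    refit_importance,
    run_level1,
    run_stacking,
)
from .folds import make_fold_scheme
from .indices import build_index_table
from .prep import vectorize_offdiagonal  # noqa: F401  (re-export for adapters)

logger = logging.getLogger(__name__)

__all__ = ["run_all", "report", "simulate_stage", "predict_stage",
            "indices_stage", "commonality_stage"]

_PRESETS = {"demo": demo_spec, "study": study_spec}


def _grid(config: RunConfig) -> HyperGrid:
    return HyperGrid() if config.grid == "full" else HyperGrid.reduced()


def simulate_stage(config: RunConfig, out: Path):
    """Generate (or load) the cohort and write it under ``out/data``."""
    if "manifest" in config.cohort:
        cohort, features = load_cohort(config.cohort["manifest"])
        return cohort, features, None
    params = {k: v for k, v in config.cohort.items() if k != "preset"}
    spec = _PRESETS[config.cohort["preset"]](**params)
    cohort, features, truth = generate_cohort(spec, seed=config.seed)
    write_cohort(out / "data", cohort, features, truth)
    return cohort, features, truth


def predict_stage(config: RunConfig, out: Path, cohort, features: FeatureSetCollection):
    """Nested-CV prediction for both targets; returns results and models."""
    grid = _grid(config)
    scheme = make_fold_scheme(
        cohort.index.to_numpy(), seed=config.seed + 1000
    )
    fold_df = pd.DataFrame(
        {"participant_id": scheme.ids, "outer_fold": scheme.outer}
    )
    fold_df.to_csv(out / "fold_scheme.csv", index=False)

    specs = default_stack_specs(features.categories)
    results = {}
    models = {}
    pred_rows, metric_rows, stability_rows = [], [], []
    for target in ("age", "cognition"):
        level1 = run_level1(
            features, cohort, target, scheme, grid,
            n_components=config.n_components,
            sex_before_pca=config.has("sex_before_pca"),
            oos_train_predictions=config.has("oos_stacking"),
        )
        stacked = run_stacking(
            level1, cohort, target, scheme, grid, specs,
            use_oos_features=config.has("oos_stacking"),
        )
        all_models = {**level1, **stacked}
        res = assemble_out_of_fold(all_models, cohort, target, scheme)
        results[target] = res
        models[target] = all_models
        for name, r in res.items():
            for pid, v in r.out_of_fold.items():
                pred_rows.append(
                    {"participant_id": pid, "model": name, "target": target,
                     "prediction": v,
                     "outer_fold": int(scheme.outer[scheme.ids == pid][0])}
                )
            for _, row in r.per_fold_metrics.iterrows():
                metric_rows.append({"model": name, "target": target, **row.to_dict()})
            vecs = [all_models[name][f].tuned.coefficients
                    for f in sorted(all_models[name])]
            rhos = importance_stability(vecs)
            for k, rho in enumerate(rhos):
                stability_rows.append(
                    {"model": name, "target": target, "pair": k, "spearman_rho": rho}
                )
    pd.DataFrame(pred_rows).to_csv(out / "predictions.csv", index=False)
    pd.DataFrame(metric_rows).to_csv(out / "metrics.csv", index=False)
    pd.DataFrame(stability_rows).to_csv(out / "importance_stability.csv", index=False)

    if config.importance:
        imp_rows = []
        for target in ("age", "cognition"):
            for name in features.names:
                it = refit_importance(
                    features[name], cohort, target, features.kinds[name],
                    _grid(config), seed=config.seed + 2000,
                    n_components=config.n_components, model_name=name,
                )
                for feat, v in it.importance.items():
                    imp_rows.append({"model": name, "target": target,
                                     "feature": feat, "importance": v})
        pd.DataFrame(imp_rows).to_csv(out / "importance.csv", index=False)

    return results, models, scheme


def indices_stage(out: Path, cohort, results, models, scheme) -> dict[str, pd.DataFrame]:
    """Per-model Brain Age index tables (one row per participant)."""
    tables = {}
    rows = []
    for name in results["age"]:
        table = build_index_table(
            results["age"][name], results["cognition"][name],
            cohort, scheme, models["age"][name],
        )
        tables[name] = table
        t = table.copy()
        t.insert(0, "model", name)
        rows.append(t)
    pd.concat(rows, ignore_index=True).to_csv(out / "indices.csv", index=False)
    return tables


def commonality_stage(config: RunConfig, out: Path, index_tables) -> dict[str, pd.DataFrame]:
    """Simple-regression and commonality tables across all models."""
    collected: dict[str, list] = {"simple": [], "commonality2": [], "commonality3": []}
    for name, table in index_tables.items():
        suite = analysis_suite(
            table, model_name=name,
            quadratic_age=config.has("quadratic"),
            ridge=config.has("ridge"),
        )
        for key, df in suite.items():
            collected[key].append(df)
    outputs = {}
    fnames = {"simple": "simple_regression.csv", "commonality2": "commonality2.csv",
              "commonality3": "commonality3.csv"}
    for key, dfs in collected.items():
        df = pd.concat(dfs, ignore_index=True)
        df.to_csv(out / fnames[key], index=False)
        outputs[key] = df
    return outputs


def run_all(config: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write(out / "config.yaml")
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path)
    logging.getLogger().addHandler(handler)
    timings = {}
    try:
        stages = []
        t0 = time.perf_counter()
        cohort, features, _ = simulate_stage(config, out)
        timings["simulate"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        results, models, scheme = predict_stage(config, out, cohort, features)
        timings["predict"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        index_tables = indices_stage(out, cohort, results, models, scheme)
        timings["indices"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        commonality_stage(config, out, index_tables)
        timings["commonality"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        report(out)
        timings["report"] = time.perf_counter() - t0
    except Exception as exc:  # annotate which stage failed
        done = set(timings)
        order = ["simulate", "predict", "indices", "commonality", "report"]
        stage = next((s for s in order if s not in done), "unknown")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        logging.getLogger().removeHandler(handler)
        handler.close()

    manifest = {
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "wall_clock_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def report(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Summaries over a completed run's stored artifacts.

    Produces the model-performance ranking per target (mean per-fold
    metrics), and per-index variance-explained summaries, recomputed
    from the stored CSVs. Conservation of every commonality row is
    checked at report time.
    """
    run_dir = Path(run_dir)
    needed = ["metrics.csv", "predictions.csv", "commonality2.csv", "commonality3.csv",
              "simple_regression.csv", "indices.csv"]
    missing = [f for f in needed if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"incomplete run; missing artifacts: {missing}")

    metrics_df = pd.read_csv(run_dir / "metrics.csv")
    perf = (
        metrics_df.groupby(["target", "model"])[["pearson_r", "r2", "mae"]]
        .mean()
        .reset_index()
        .sort_values(["target", "r2"], ascending=[True, False])
        .reset_index(drop=True)
    )
    perf.to_csv(run_dir / "performance_summary.csv", index=False)

    c2 = pd.read_csv(run_dir / "commonality2.csv")
    resid2 = c2["unique_age"] + c2["unique_index"] + c2["common"] - c2["full_r2"]
    c3 = pd.read_csv(run_dir / "commonality3.csv")
    comp_cols = ["unique_age", "unique_index", "unique_brain_cognition",
                 "common_age_index", "common_age_brain_cognition",
                 "common_index_brain_cognition", "common_all"]
    resid3 = c3[comp_cols].sum(axis=1) - c3["full_r2"]
    if not (np.abs(resid2) < 1e-8).all() or not (np.abs(resid3) < 1e-8).all():
        raise ValueError("commonality components do not sum to the full-model R2")

    index_summary = (
        c2.groupby("index")[["unique_index", "unique_age", "common", "full_r2"]]
        .agg(["mean", "max"])
    )
    index_summary.columns = ["_".join(c) for c in index_summary.columns]
    index_summary = index_summary.reset_index()
    index_summary.to_csv(run_dir / "index_summary.csv", index=False)
    return {"performance": perf, "index_summary": index_summary}
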