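"""Nested-CV prediction engine for Brain Age and Brain Cognition.

Three steps per outer fold, none of which touches the outer-fold test
set until the final application:

1. for each feature set, tune an Elastic Net by grid search over the
   inner folds of the outer-training set (preprocessing re-fitted
   inside every inner fold), then refit the winning configuration on
   the whole outer-training set;
2. treat the refit models' predictions on the outer-training rows as
   features for second-level "stacked" Elastic Nets, tuned on a fresh
   set of inner folds;
3. apply all tuned models to the outer-fold test rows.

Pooling the outer-test predictions over folds yields one out-of-fold
prediction per participant per model: Brain Age when the target is
chronological age, Brain Cognition when it is fluid cognition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import FeatureSetCollection
from .enet import HyperGrid, enet_coef_grid, enet_fit
from .folds import FoldScheme
from .prep import PreprocParams, apply_preproc, fit_preproc

__all__ = [
    "StackSpec",
    "TunedModel",
    "FoldModel",
    "PredictionResult",
    "ImportanceTable",
    "metrics",
    "grid_search",
    "run_level1",
    "run_stacking",
    "assemble_out_of_fold",
    "default_stack_specs",
    "refit_importance",
    "importance_stability",
    "N_COMPONENTS_DEFAULT",
]

#: PCA dimensionality for connectivity-style feature sets
N_COMPONENTS_DEFAULT = 75

TARGET_COLUMNS = {"age": "age_years", "cognition": "fluid_cognition"}


@dataclass
class TunedModel:
    """One tuned-and-refit Elastic Net with its frozen preprocessing."""

    alpha: float
    l1_ratio: float
    coefficients: np.ndarray
    intercept: float
    preproc: PreprocParams
    validation_score: float  # mean inner-fold validation R2

    def predict(self, features, sex) -> np.ndarray:
        x = apply_preproc(features, sex, self.preproc)
        return x @ self.coefficients + self.intercept


@dataclass
class FoldModel:
    """A tuned model for one outer fold plus its train/test predictions."""

    tuned: TunedModel
    train_pred: pd.Series  # in-sample predictions on outer-training rows
    test_pred: pd.Series   # out-of-fold predictions on outer-test rows
    train_pred_oos: pd.Series | None = None  # cross-validated alternative


@dataclass
class PredictionResult:
    """Pooled out-of-fold predictions and per-fold metrics for one model."""

    model_name: str
    target: str
    out_of_fold: pd.Series               # participant -> prediction
    per_fold_metrics: pd.DataFrame       # fold, pearson_r, r2, mae, alpha, l1_ratio
    observed: pd.Series

    def pooled_metrics(self) -> dict:
        return metrics(self.observed.to_numpy(), self.out_of_fold.to_numpy())


@dataclass
class ImportanceTable:
    """Full-data refit coefficients (back-projected for connectivity sets)."""

    model_name: str
    importance: pd.Series     # feature (or region pair) -> importance
    stability_rhos: np.ndarray  # 10 Spearman rhos across outer-fold pairs


@dataclass(frozen=True)
class StackSpec:
    name: str
    member_sets: tuple[str, ...]


def metrics(observed, predicted) -> dict:
    """Pearson r, sum-of-squares R2, and MAE in the target's units.

    R2 = 1 - SS_res/SS_tot and may be negative on held-out data. With a
    constant predicted vector, r is undefined and reported as NaN.
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed/predicted must be equal-length, n >= 2")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    mae = float(np.mean(np.abs(obs - pred)))
    if np.std(pred) == 0.0 or np.std(obs) == 0.0:
        r = float("nan")
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
    return {"pearson_r": r, "r2": r2, "mae": mae}


def _r2(obs: np.ndarray, pred: np.ndarray) -> float:
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    return 1.0 - np.sum((obs - pred) ** 2) / ss_tot


def grid_search(
    features,
    sex,
    y,
    inner_labels: np.ndarray,
    grid: HyperGrid,
    kind: str = "direct",
    n_components: int = N_COMPONENTS_DEFAULT,
    sex_before_pca: bool = False,
    fit_fold_id: str = "full",
) -> TunedModel:
    """Inner-CV grid search followed by a refit on all provided rows.

    Every inner fold re-fits preprocessing on its inner-training rows
    (strict against leakage), scores every grid point on the
    inner-validation rows by sum-of-squares R2, and the grid point with
    the highest mean validation R2 wins. Ties break to the first point
    in ascending (alpha, l1_ratio) order.
    """
    sex = np.asarray(sex, dtype=float)
    y = np.asarray(y, dtype=float)
    inner_labels = np.asarray(inner_labels)
    n_l, n_a = len(grid.l1_ratios), len(grid.alphas)
    scores = np.zeros((n_l, n_a))
    folds = np.unique(inner_labels)
    for f in folds:
        val = inner_labels == f
        tr = ~val
        pp = fit_preproc(
            _rows(features, tr), sex[tr], kind=kind, n_components=n_components,
            fit_fold_id=f"{fit_fold_id}/inner{f}", sex_before_pca=sex_before_pca,
        )
        x_tr = apply_preproc(_rows(features, tr), sex[tr], pp)
        x_val = apply_preproc(_rows(features, val), sex[val], pp)
        coefs, intercepts = enet_coef_grid(x_tr, y[tr], grid)
        preds = np.einsum("vp,lap->lav", x_val, coefs) + intercepts[..., None]
        obs = y[val]
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        ss_res = np.sum((preds - obs[None, None, :]) ** 2, axis=-1)
        scores += 1.0 - ss_res / ss_tot
    scores /= len(folds)

    best, best_score = None, -np.inf
    for ai, alpha in enumerate(grid.alphas):
        for li, l1 in enumerate(grid.l1_ratios):
            if scores[li, ai] > best_score:
                best_score = scores[li, ai]
                best = (alpha, l1)
    alpha, l1 = best

    pp = fit_preproc(
        features, sex, kind=kind, n_components=n_components,
        fit_fold_id=fit_fold_id, sex_before_pca=sex_before_pca,
    )
    x = apply_preproc(features, sex, pp)
    coef, intercept = enet_fit(x, y, alpha, l1)
    return TunedModel(alpha, l1, coef, intercept, pp, float(best_score))


def _rows(features, mask):
    if hasattr(features, "iloc"):
        return features.iloc[mask] if mask.dtype != bool else features.loc[mask]
    return features[mask]


def run_level1(
    features: FeatureSetCollection,
    cohort: pd.DataFrame,
    target: str,
    scheme: FoldScheme,
    grid: HyperGrid,
    n_components: int = N_COMPONENTS_DEFAULT,
    sex_before_pca: bool = False,
    oos_train_predictions: bool = False,
) -> dict[str, dict[int, FoldModel]]:
    """Tune/refit one model per feature set per outer fold.

    Returns ``result[set_name][outer_fold]`` with the tuned model, its
    in-sample predictions on the outer-training rows (the stacking
    features) and its predictions on the outer-test rows. With
    ``oos_train_predictions`` the tuned configuration is additionally
    cross-validated over the inner folds to give out-of-sample
    training-row predictions (the optional alternative stacking input).
    """
    ycol = TARGET_COLUMNS[target]
    out: dict[str, dict[int, FoldModel]] = {}
    for name in features.names:
        table = features[name]
        missing = cohort.index.difference(table.index)
        if len(missing):
            raise ValueError(f"set {name!r} missing participants: {list(missing[:3])}")
        out[name] = {}
        for f in range(scheme.k_outer):
            tr_ids = scheme.outer_train_ids(f)
            te_ids = scheme.outer_test_ids(f)
            tuned = grid_search(
                table.loc[tr_ids],
                cohort.loc[tr_ids, "sex"].to_numpy(),
                cohort.loc[tr_ids, ycol].to_numpy(),
                scheme.inner_labels("level1", f),
                grid,
                kind=features.kinds[name],
                n_components=n_components,
                sex_before_pca=sex_before_pca,
                fit_fold_id=f"outer{f}",
            )
            train_pred = pd.Series(
                tuned.predict(table.loc[tr_ids], cohort.loc[tr_ids, "sex"].to_numpy()),
                index=pd.Index(tr_ids, name="participant_id"),
            )
            test_pred = pd.Series(
                tuned.predict(table.loc[te_ids], cohort.loc[te_ids, "sex"].to_numpy()),
                index=pd.Index(te_ids, name="participant_id"),
            )
            oos = None
            if oos_train_predictions:
                oos = _cv_train_predictions(
                    table.loc[tr_ids],
                    cohort.loc[tr_ids, "sex"].to_numpy(),
                    cohort.loc[tr_ids, ycol].to_numpy(),
                    scheme.inner_labels("level1", f),
                    tuned,
                    kind=features.kinds[name],
                    n_components=n_components,
                    sex_before_pca=sex_before_pca,
                )
            out[name][f] = FoldModel(tuned, train_pred, test_pred, oos)
    return out


def _cv_train_predictions(
    table, sex, y, inner_labels, tuned: TunedModel, kind, n_components, sex_before_pca
) -> pd.Series:
    """Out-of-sample predictions on training rows: refit the tuned
    (alpha, l1_ratio) within each inner fold and predict its held-out rows."""
    pred = pd.Series(np.nan, index=table.index)
    for f in np.unique(inner_labels):
        val = inner_labels == f
        tr = ~val
        pp = fit_preproc(table.loc[tr], sex[tr], kind=kind,
                         n_components=n_components, sex_before_pca=sex_before_pca)
        x_tr = apply_preproc(table.loc[tr], sex[tr], pp)
        coef, intercept = enet_fit(x_tr, y[tr], tuned.alpha, tuned.l1_ratio)
        x_val = apply_preproc(table.loc[val], sex[val], pp)
        pred.loc[val] = x_val @ coef + intercept
    return pred


def default_stack_specs(categories: dict[str, str]) -> list[StackSpec]:
    """The eight standard stacked-model configurations, resolved from
    each feature set's category tag. Configurations with no member sets
    in the manifest are dropped."""
    names = list(categories)

    def pick(*cats):
        return tuple(n for n in names if categories[n] in cats)

    raw = [
        StackSpec("stacked_all", tuple(names)),
        StackSpec("stacked_all_excl_task_fc", pick("task_contrast", "rest_fc", "smri")),
        StackSpec("stacked_all_excl_task_contrast", pick("task_fc", "rest_fc", "smri")),
        StackSpec("stacked_non_task", pick("rest_fc", "smri")),
        StackSpec("stacked_rest_and_task_fc", pick("rest_fc", "task_fc")),
        StackSpec("stacked_task_contrast_and_fc", pick("task_contrast", "task_fc")),
        StackSpec("stacked_task_contrast", pick("task_contrast")),
        StackSpec("stacked_task_fc", pick("task_fc")),
    ]
    return [s for s in raw if s.member_sets]


def run_stacking(
    level1: dict[str, dict[int, FoldModel]],
    cohort: pd.DataFrame,
    target: str,
    scheme: FoldScheme,
    grid: HyperGrid,
    specs: list[StackSpec],
    use_oos_features: bool = False,
) -> dict[str, dict[int, FoldModel]]:
    """Tune/refit the stacked models on the level-1 predictions.

    The stacking design matrix holds one column per member set: the
    refit level-1 model's predictions on the outer-training rows
    (training) and on the outer-test rows (application). Second-level
    preprocessing is plain standardisation; inner folds are the
    stacking-stage folds, drawn independently of the level-1 folds.
    """
    ycol = TARGET_COLUMNS[target]
    known = set(level1)
    out: dict[str, dict[int, FoldModel]] = {}
    for spec in specs:
        unknown = [m for m in spec.member_sets if m not in known]
        if unknown:
            raise ValueError(f"stack {spec.name!r} references unknown sets {unknown}")
        out[spec.name] = {}
        for f in range(scheme.k_outer):
            tr_ids = scheme.outer_train_ids(f)
            te_ids = scheme.outer_test_ids(f)
            def _train_feature(m):
                fm = level1[m][f]
                if use_oos_features:
                    if fm.train_pred_oos is None:
                        raise ValueError(
                            f"set {m!r} has no out-of-sample training predictions"
                        )
                    return fm.train_pred_oos.loc[tr_ids]
                return fm.train_pred.loc[tr_ids]

            x_tr = pd.DataFrame({m: _train_feature(m) for m in spec.member_sets})
            x_te = pd.DataFrame(
                {m: level1[m][f].test_pred.loc[te_ids] for m in spec.member_sets}
            )
            zeros_tr = np.zeros(len(tr_ids))
            tuned = grid_search(
                x_tr,
                zeros_tr,
                cohort.loc[tr_ids, ycol].to_numpy(),
                scheme.inner_labels("stacking", f),
                grid,
                kind="direct",
                fit_fold_id=f"outer{f}/stack",
            )
            train_pred = pd.Series(
                tuned.predict(x_tr, zeros_tr), index=x_tr.index
            )
            test_pred = pd.Series(
                tuned.predict(x_te, np.zeros(len(te_ids))), index=x_te.index
            )
            out[spec.name][f] = FoldModel(tuned, train_pred, test_pred)
    return out


def assemble_out_of_fold(
    models: dict[str, dict[int, FoldModel]],
    cohort: pd.DataFrame,
    target: str,
    scheme: FoldScheme,
) -> dict[str, PredictionResult]:
    """Pool outer-test predictions into one table per model.

    Every participant receives exactly one out-of-fold prediction per
    model, produced by the model trained without that participant's
    outer fold.
    """
    ycol = TARGET_COLUMNS[target]
    results: dict[str, PredictionResult] = {}
    for name, per_fold in models.items():
        preds = pd.concat([fm.test_pred for fm in per_fold.values()])
        if preds.index.duplicated().any():
            raise ValueError(f"duplicate out-of-fold predictions in {name!r}")
        missing = cohort.index.difference(preds.index)
        if len(missing):
            raise ValueError(f"model {name!r} lacks predictions for {list(missing[:3])}")
        preds = preds.loc[cohort.index]
        rows = []
        for f, fm in sorted(per_fold.items()):
            obs = cohort.loc[fm.test_pred.index, ycol].to_numpy()
            m = metrics(obs, fm.test_pred.to_numpy())
            rows.append(
                {"fold": f, **m, "alpha": fm.tuned.alpha, "l1_ratio": fm.tuned.l1_ratio}
            )
        results[name] = PredictionResult(
            model_name=name,
            target=target,
            out_of_fold=preds,
            per_fold_metrics=pd.DataFrame(rows),
            observed=cohort[ycol].copy(),
        )
    return results


def refit_importance(
    table: pd.DataFrame,
    cohort: pd.DataFrame,
    target: str,
    kind: str,
    grid: HyperGrid,
    seed: int = 0,
    n_components: int = N_COMPONENTS_DEFAULT,
    model_name: str | None = None,
    per_fold_models: dict[int, FoldModel] | None = None,
) -> ImportanceTable:
    """Feature importance from an Elastic Net refit on the full data.

    The configuration is tuned by an inner-CV-style grid search over
    the full dataset (no outer split), then refit. Direct sets report
    the coefficients; connectivity sets back-project through the PCA:
    per original pair feature, sum over components of
    |loading| * coefficient.

    If per-fold models are supplied, rank stability of their
    coefficients across the C(5,2)=10 outer-fold pairs is attached.
    """
    from .folds import _partition  # reuse the seeded partitioner

    ycol = TARGET_COLUMNS[target]
    rng = np.random.default_rng(seed)
    labels = _partition(len(table), 5, rng)
    tuned = grid_search(
        table,
        cohort.loc[table.index, "sex"].to_numpy(),
        cohort.loc[table.index, ycol].to_numpy(),
        labels,
        grid,
        kind=kind,
        n_components=n_components,
        fit_fold_id="full",
    )
    if kind == "connectivity":
        imp = np.abs(tuned.preproc.pca_components).T @ tuned.coefficients
        index = pd.Index(tuned.preproc.columns, name="feature")
    else:
        imp = tuned.coefficients
        index = pd.Index(tuned.preproc.columns, name="feature")
    rhos = np.array([])
    if per_fold_models is not None:
        vecs = [per_fold_models[f].tuned.coefficients for f in sorted(per_fold_models)]
        rhos = importance_stability(vecs)
    return ImportanceTable(
        model_name=model_name or "model",
        importance=pd.Series(imp, index=index),
        stability_rhos=rhos,
    )


def importance_stability(coefficient_vectors) -> np.ndarray:
    """Spearman rho between every unordered pair of per-fold coefficient
    vectors; five folds give C(5,2) = 10 values. A constant vector makes
    its pairs undefined (NaN)."""
    vecs = [np.asarray(v, dtype=float) for v in coefficient_vectors]
    if len({v.shape for v in vecs}) != 1:
        raise ValueError("coefficient vectors must have equal length")
    rhos = []
    for i in range(len(vecs)):
        for j in range(i + 1, len(vecs)):
            if np.std(vecs[i]) == 0.0 or np.std(vecs[j]) == 0.0:
                rhos.append(float("nan"))
            else:
                rhos.append(float(stats.spearmanr(vecs[i], vecs[j]).statistic))
    return np.array(rhos)
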