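"""Brain Age indices: Brain Age, Brain Age Gap, Corrected Brain Age,
Corrected Brain Age Gap.

Brain Age is the out-of-fold predicted age. Because penalised models
shrink predictions toward the training mean, Brain Age overestimates
young and underestimates old participants, so the raw gap
(Brain Age - age) correlates negatively with age. The correction fits
an OLS line Brain Age = b0 + b1 * age on each outer-fold *training*
set and applies (Brain Age - b0) / b1 to the corresponding test fold,
removing that regression-to-the-mean dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import FoldModel, PredictionResult
from .folds import FoldScheme

__all__ = [
    "BiasModel",
    "brain_age_gap",
    "fit_bias",
    "corrected_brain_age",
    "build_index_table",
    "INDEX_COLUMNS",
]

INDEX_COLUMNS = (
    "brain_age",
    "brain_age_gap",
    "corrected_brain_age",
    "corrected_brain_age_gap",
)


@dataclass(frozen=True)
class BiasModel:
    """OLS of Brain Age on chronological age in one training fold."""

    beta0: float
    beta1: float
    fit_fold_id: str = "full"


def brain_age_gap(brain_age, age):
    """Brain Age minus chronological age (years)."""
    return np.asarray(brain_age, dtype=float) - np.asarray(age, dtype=float)


def fit_bias(
    train_brain_age, train_age, fit_fold_id: str = "full", tol: float = 1e-6
) -> BiasModel:
    """Fit the age-bias line on training-fold predictions.

    Raises if the fitted slope is smaller than ``tol`` in magnitude
    (a constant predictor makes the correction undefined).
    """
    ba = np.asarray(train_brain_age, dtype=float)
    age = np.asarray(train_age, dtype=float)
    if ba.size < 3:
        raise ValueError("need at least 3 rows to fit the bias line")
    if np.std(age) == 0.0:
        raise ValueError("chronological age is constant; bias line undefined")
    beta1 = float(np.cov(ba, age, ddof=0)[0, 1] / np.var(age))
    beta0 = float(ba.mean() - beta1 * age.mean())
    if abs(beta1) < tol:
        raise ValueError(
            "constant-prediction degenerate: correction undefined "
            f"(|slope|={abs(beta1):.2e} < {tol})"
        )
    return BiasModel(beta0, beta1, str(fit_fold_id))


def corrected_brain_age(brain_age, bias: BiasModel):
    """De-biased predicted age: (Brain Age - beta0) / beta1."""
    return (np.asarray(brain_age, dtype=float) - bias.beta0) / bias.beta1


def build_index_table(
    age_result: PredictionResult,
    cognition_result: PredictionResult,
    cohort: pd.DataFrame,
    scheme: FoldScheme,
    age_fold_models: dict[int, FoldModel],
) -> pd.DataFrame:
    """One row per participant with all four Brain Age indices plus
    Brain Cognition, chronological age and observed fluid cognition.

    The bias line is fitted per outer fold on that fold's training-row
    predictions (the refit model's in-sample predictions) and applied
    to the fold's out-of-fold test predictions.
    """
    if age_result.target != "age" or cognition_result.target != "cognition":
        raise ValueError("expected an age result and a cognition result")
    ids = cohort.index
    table = pd.DataFrame(
        {
            "participant_id": ids,
            "age": cohort["age_years"].to_numpy(),
            "fluid_cognition": cohort["fluid_cognition"].to_numpy(),
            "brain_age": age_result.out_of_fold.loc[ids].to_numpy(),
            "brain_cognition": cognition_result.out_of_fold.loc[ids].to_numpy(),
        },
        index=ids,
    )
    table["brain_age_gap"] = brain_age_gap(table["brain_age"], table["age"])
    corrected = pd.Series(np.nan, index=ids)
    for f in range(scheme.k_outer):
        fm = age_fold_models.get(f)
        if fm is None:
            raise ValueError(f"no age fold model for outer fold {f}")
        tr_ids = scheme.outer_train_ids(f)
        te_ids = scheme.outer_test_ids(f)
        if not np.array_equal(np.sort(fm.test_pred.index), np.sort(te_ids)):
            raise ValueError(f"fold {f}: test predictions do not match the scheme")
        bias = fit_bias(
            fm.train_pred.loc[tr_ids].to_numpy(),
            cohort.loc[tr_ids, "age_years"].to_numpy(),
            fit_fold_id=f"outer{f}",
        )
        corrected.loc[te_ids] = corrected_brain_age(
            fm.test_pred.loc[te_ids].to_numpy(), bias
        )
    table["corrected_brain_age"] = corrected
    table["corrected_brain_age_gap"] = table["corrected_brain_age"] - table["age"]
    return table
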