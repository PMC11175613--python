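"""Commonality analysis: partitioning explained variance in fluid
cognition into unique and common effects of regressor blocks.

For blocks V = {1..k}, the R-squared of every non-empty subset model is
combined into one component per non-empty subset S of V:

    C(S) = sum_{T subseteq S} (-1)^(|S|-|T|+1) R2(V \\ T)

with R2 of the empty model taken as 0. Singleton components are the
unique effects (the Delta-R2 of adding that block last) and larger
subsets are common effects; the components always sum to the full
model's R2. Common effects can be negative under suppression; the
conventional remedy zeroes them and rescales the rest to preserve the
full-model R2.

Significance of a unique effect Delta-R2 uses the hierarchical
F-change statistic

    F = (N - k2 - 1) * Delta-R2 / (k_change * (1 - R2_full))

on (k_change, N - k2 - 1) degrees of freedom, where k2 counts the
regressors of the larger model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Ridge, RidgeCV

__all__ = [
    "RegressorBlock",
    "CommonalityResult",
    "ols_r2",
    "commonality",
    "f_change",
    "zero_and_rescale",
    "ridge_commonality",
    "analysis_suite",
]


@dataclass(frozen=True)
class RegressorBlock:
    """One or more predictor columns treated as a unit (e.g. {age} or
    {age, age^2})."""

    name: str
    columns: tuple = ()

    @classmethod
    def from_array(cls, name: str, values) -> "RegressorBlock":
        arr = np.atleast_2d(np.asarray(values, dtype=float))
        if arr.shape[0] == 1:
            arr = arr.T
        if not np.isfinite(arr).all():
            raise ValueError(f"block {name!r} has non-finite values")
        return cls(name, tuple(map(tuple, arr.T)))

    @property
    def matrix(self) -> np.ndarray:
        return np.asarray(self.columns, dtype=float).T

    @property
    def n_columns(self) -> int:
        return len(self.columns)


@dataclass
class CommonalityResult:
    """Unique/common variance components of one decomposition.

    ``components`` maps a frozenset of block names (singletons = unique
    effects, larger sets = common effects) to its variance share.
    ``f_change`` maps each block name to (F, p) for its unique effect.
    """

    full_r2: float
    components: dict[frozenset, float]
    f_change: dict[str, tuple[float, float]]
    n: int
    rescaled: bool = False

    def component(self, *names: str) -> float:
        return self.components[frozenset(names)]


def _design(blocks) -> np.ndarray:
    return np.hstack([b.matrix for b in blocks])


def ols_r2(outcome, blocks) -> float:
    """In-sample R2 of an OLS fit with intercept on the given blocks."""
    y = np.asarray(outcome, dtype=float)
    x = _design(blocks)
    n, p = x.shape
    if n <= p + 1:
        raise ValueError(f"need n > {p + 1} observations, got {n}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    rank = np.linalg.matrix_rank(xc)
    if rank < p:
        for b in blocks:
            if np.linalg.matrix_rank(b.matrix - b.matrix.mean(axis=0)) < b.n_columns:
                raise ValueError(f"rank-deficient design: block {b.name!r} is collinear")
        raise ValueError(
            "rank-deficient design: blocks "
            f"{[b.name for b in blocks]} are mutually collinear"
        )
    beta, *_ = np.linalg.lstsq(xc, yc, rcond=None)
    ss_res = float(np.sum((yc - xc @ beta) ** 2))
    ss_tot = float(np.sum(yc**2))
    if ss_tot == 0.0:
        raise ValueError("outcome is constant")
    return 1.0 - ss_res / ss_tot


def f_change(
    r2_full: float, delta_r2: float, n: int, k2: int, k_change: int
) -> tuple[float, float]:
    """Hierarchical-regression F test of a Delta-R2 between nested models.

    ``k2`` is the regressor count of the larger model, ``k_change`` the
    number of regressors added. Returns (F, p).
    """
    if r2_full >= 1.0:
        raise ValueError("r2_full must be < 1")
    if not 0.0 <= delta_r2 <= r2_full + 1e-12:
        raise ValueError("delta_r2 must lie in [0, r2_full]")
    df2 = n - k2 - 1
    if df2 <= 0:
        raise ValueError("non-positive denominator degrees of freedom")
    f = (df2 * delta_r2) / (k_change * (1.0 - r2_full))
    p = float(stats.f.sf(f, k_change, df2))
    return float(f), p


def _subset_r2s(outcome, blocks, r2_fn) -> dict[frozenset, float]:
    names = [b.name for b in blocks]
    if len(set(names)) != len(names):
        raise ValueError("block names must be unique")
    by_name = {b.name: b for b in blocks}
    r2s: dict[frozenset, float] = {frozenset(): 0.0}
    for k in range(1, len(blocks) + 1):
        for combo in combinations(names, k):
            r2s[frozenset(combo)] = r2_fn(outcome, [by_name[c] for c in combo])
    return r2s


def _decompose(r2s: dict[frozenset, float], names: list[str]) -> dict[frozenset, float]:
    """Möbius-inversion commonality components from subset R2s."""
    v = frozenset(names)
    comps: dict[frozenset, float] = {}
    for k in range(1, len(names) + 1):
        for combo in combinations(names, k):
            s = frozenset(combo)
            total = 0.0
            for j in range(len(combo) + 1):
                for sub in combinations(combo, j):
                    t = frozenset(sub)
                    total += (-1) ** (len(s) - len(t) + 1) * r2s[v - t]
            comps[s] = total
    return comps


def commonality(outcome, blocks, compute_f: bool = True) -> CommonalityResult:
    """Full commonality decomposition over 2 or more regressor blocks.

    Computes the OLS R2 of every non-empty subset of blocks and returns
    one component per subset; singletons are unique effects with an
    F-change significance test against the model lacking that block.
    """
    blocks = list(blocks)
    if len(blocks) < 2:
        raise ValueError("need at least two regressor blocks")
    y = np.asarray(outcome, dtype=float)
    names = [b.name for b in blocks]
    r2s = _subset_r2s(y, blocks, ols_r2)
    comps = _decompose(r2s, names)
    full = r2s[frozenset(names)]
    k2 = sum(b.n_columns for b in blocks)
    fstats: dict[str, tuple[float, float]] = {}
    if compute_f:
        for b in blocks:
            delta = max(comps[frozenset([b.name])], 0.0)
            fstats[b.name] = f_change(full, min(delta, full), len(y), k2, b.n_columns)
    return CommonalityResult(full, comps, fstats, n=len(y))


def zero_and_rescale(result: CommonalityResult) -> CommonalityResult:
    """Zero negative common effects and rescale the rest to the full R2.

    Negative common effects (suppression) are set to 0 and the
    remaining components are multiplied by full_r2 / (their sum) so the
    decomposition again sums to the full-model R2.
    """
    comps = dict(result.components)
    kept = {s: max(v, 0.0) if len(s) > 1 else v for s, v in comps.items()}
    pos_sum = sum(v for v in kept.values() if v > 0.0)
    if result.full_r2 > 0.0 and pos_sum <= 0.0:
        raise ValueError("all components non-positive with positive full R2")
    if pos_sum > 0.0:
        scale = result.full_r2 / pos_sum
        kept = {s: (v * scale if v > 0.0 else max(v, 0.0)) for s, v in kept.items()}
    return CommonalityResult(
        result.full_r2, kept, dict(result.f_change), n=result.n, rescaled=True
    )


def _ridge_r2_factory(penalty: float):
    def r2_fn(outcome, blocks) -> float:
        y = np.asarray(outcome, dtype=float)
        x = _design(blocks)
        model = Ridge(alpha=penalty, fit_intercept=True)
        model.fit(x, y)
        pred = model.predict(x)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot

    return r2_fn


def ridge_commonality(
    outcome, blocks, penalty_grid=None, seed: int = 0
) -> CommonalityResult:
    """Commonality decomposition with ridge-regression subset R2s.

    The penalty is selected once, by cross-validation on the full
    model, and reused for every subset so the components remain
    comparable. The same inclusion-exclusion arithmetic applies; the
    F-change tests are carried over from the OLS forms.
    """
    blocks = list(blocks)
    if len(blocks) < 2:
        raise ValueError("need at least two regressor blocks")
    y = np.asarray(outcome, dtype=float)
    if penalty_grid is None:
        penalty_grid = np.logspace(-4, 2, 30)
    cv = RidgeCV(alphas=np.asarray(penalty_grid, dtype=float))
    cv.fit(_design(blocks), y)
    penalty = float(cv.alpha_)
    names = [b.name for b in blocks]
    r2s = _subset_r2s(y, blocks, _ridge_r2_factory(penalty))
    comps = _decompose(r2s, names)
    full = r2s[frozenset(names)]
    k2 = sum(b.n_columns for b in blocks)
    fstats = {}
    for b in blocks:
        delta = min(max(comps[frozenset([b.name])], 0.0), max(full, 0.0))
        if full < 1.0 and full >= 0.0:
            fstats[b.name] = f_change(full, delta, len(y), k2, b.n_columns)
    return CommonalityResult(full, comps, fstats, n=len(y))


# ---------------------------------------------------------------------------
# analysis suite over an index table

def _age_block(table: pd.DataFrame, quadratic: bool) -> RegressorBlock:
    age = table["age"].to_numpy()
    if quadratic:
        # centered quadratic term, one block so "age" stays interpretable
        a_c = age - age.mean()
        return RegressorBlock.from_array("age", np.column_stack([age, a_c**2]))
    return RegressorBlock.from_array("age", age)


def analysis_suite(
    index_table: pd.DataFrame,
    model_name: str = "model",
    quadratic_age: bool = False,
    ridge: bool = False,
    alpha_level: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """The three regression analyses for one age-model's index table.

    Returns three tables:

    - ``simple``: R2 of each Brain Age index, and of Brain Cognition,
      as the sole regressor of fluid cognition;
    - ``commonality2``: {age, index} decomposition per index with the
      F-change test of each unique effect;
    - ``commonality3``: {age, index, brain cognition} decomposition
      per index.

    Components are reported before rescaling (so they sum to the full
    R2, possibly with negative commons); zeroed-and-rescaled common
    effects are appended as ``*_rescaled`` columns.
    """
    from .indices import INDEX_COLUMNS

    required = set(INDEX_COLUMNS) | {"age", "fluid_cognition", "brain_cognition"}
    missing = required - set(index_table.columns)
    if missing:
        raise ValueError(f"index table missing columns: {sorted(missing)}")
    y = index_table["fluid_cognition"].to_numpy()
    decomposer = ridge_commonality if ridge else commonality

    simple_rows = []
    for col in (*INDEX_COLUMNS, "brain_cognition"):
        block = RegressorBlock.from_array(col, index_table[col].to_numpy())
        simple_rows.append({"model": model_name, "regressor": col,
                            "r2": ols_r2(y, [block])})
    simple = pd.DataFrame(simple_rows)

    rows2, rows3 = [], []
    for col in INDEX_COLUMNS:
        idx_block = RegressorBlock.from_array("index", index_table[col].to_numpy())
        age_block = _age_block(index_table, quadratic_age)
        res = decomposer(y, [age_block, idx_block])
        scaled = zero_and_rescale(res)
        f_idx, p_idx = res.f_change["index"]
        f_age, p_age = res.f_change["age"]
        rows2.append(
            {
                "model": model_name,
                "index": col,
                "unique_age": res.component("age"),
                "unique_index": res.component("index"),
                "common": res.component("age", "index"),
                "full_r2": res.full_r2,
                "F_index": f_idx,
                "p_index": p_idx,
                "significant_index": p_idx < alpha_level,
                "F_age": f_age,
                "p_age": p_age,
                "common_rescaled": scaled.component("age", "index"),
            }
        )
        cog_block = RegressorBlock.from_array(
            "brain_cognition", index_table["brain_cognition"].to_numpy()
        )
        res3 = decomposer(y, [age_block, idx_block, cog_block])
        f_cog, p_cog = res3.f_change["brain_cognition"]
        rows3.append(
            {
                "model": model_name,
                "index": col,
                "unique_age": res3.component("age"),
                "unique_index": res3.component("index"),
                "unique_brain_cognition": res3.component("brain_cognition"),
                "common_age_index": res3.component("age", "index"),
                "common_age_brain_cognition": res3.component("age", "brain_cognition"),
                "common_index_brain_cognition": res3.component("index", "brain_cognition"),
                "common_all": res3.component("age", "index", "brain_cognition"),
                "full_r2": res3.full_r2,
                "F_brain_cognition": f_cog,
                "p_brain_cognition": p_cog,
                "significant_brain_cognition": p_cog < alpha_level,
            }
        )
    return {
        "simple": simple,
        "commonality2": pd.DataFrame(rows2),
        "commonality3": pd.DataFrame(rows3),
    }
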