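"""Deterministic nested cross-validation fold assignment.

Five outer folds partition the cohort; within each outer-training set,
five inner folds drive hyperparameter tuning. The stacking stage draws
its own, independent inner folds over the same outer-training set, as
the second-level models are tuned after the first-level models are
fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FoldScheme", "make_fold_scheme"]

STAGES = ("level1", "stacking")


@dataclass
class FoldScheme:
    """Outer and per-stage inner fold assignments over participant ids."""

    ids: np.ndarray            # participant ids, fixed order
    outer: np.ndarray          # outer fold label per id, 0..k_outer-1
    inner: dict                # inner[stage][outer_fold] -> labels aligned
                               # to outer_train_ids(outer_fold)
    seed: int
    k_outer: int = 5
    k_inner: int = 5

    def outer_test_ids(self, fold: int) -> np.ndarray:
        return self.ids[self.outer == fold]

    def outer_train_ids(self, fold: int) -> np.ndarray:
        return self.ids[self.outer != fold]

    def inner_labels(self, stage: str, fold: int) -> np.ndarray:
        """Inner-fold label per outer-training participant (aligned to
        ``outer_train_ids(fold)``)."""
        return self.inner[stage][fold]


def _partition(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition of n items into k folds with sizes differing <= 1."""
    labels = np.empty(n, dtype=int)
    perm = rng.permutation(n)
    for f, chunk in enumerate(np.array_split(perm, k)):
        labels[chunk] = f
    return labels


def make_fold_scheme(ids, k_outer: int = 5, k_inner: int = 5, seed: int = 0) -> FoldScheme:
    """Draw a nested fold scheme; deterministic given (ids, seed).

    ``ids`` may be an integer n (ids become 0..n-1) or a sequence of
    participant identifiers.
    """
    if np.isscalar(ids):
        ids = np.arange(int(ids))
    ids = np.asarray(ids)
    n = len(ids)
    if n < k_outer * k_inner:
        raise ValueError(
            f"need at least {k_outer * k_inner} participants, got {n}"
        )
    rng = np.random.default_rng(seed)
    outer = _partition(n, k_outer, rng)
    inner: dict[str, dict[int, np.ndarray]] = {}
    for stage in STAGES:
        inner[stage] = {}
        for f in range(k_outer):
            n_train = int((outer != f).sum())
            inner[stage][f] = _partition(n_train, k_inner, rng)
    return FoldScheme(ids=ids, outer=outer, inner=inner, seed=seed,
                      k_outer=k_outer, k_inner=k_inner)
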