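"""Elastic Net fitting against the standard penalised least-squares
objective

    argmin_b  ||y - X b||^2 / (2 n) + alpha * l1_ratio * ||b||_1
              + 0.5 * alpha * (1 - l1_ratio) * ||b||_2^2

with an unpenalised intercept fitted on centered data. The l1_ratio > 0
cases go through scikit-learn's coordinate descent; pure-ridge mixing
(l1_ratio = 0) is solved exactly from the normal equations of the same
objective, where coordinate descent is unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, enet_path

__all__ = ["HyperGrid", "enet_fit", "enet_coef_grid"]


@dataclass(frozen=True)
class HyperGrid:
    """Hyperparameter grid: alphas log-spaced, l1_ratios linearly spaced.

    Defaults are 70 alphas in log10 space over [0.1, 100] and 25
    l1_ratios over [0, 1], endpoints inclusive.
    """

    alphas: tuple = tuple(np.logspace(-1, 2, 70))
    l1_ratios: tuple = tuple(np.linspace(0, 1, 25))

    def __post_init__(self) -> None:
        if len(self.alphas) == 0 or len(self.l1_ratios) == 0:
            raise ValueError("empty hyperparameter grid")
        if np.any(np.diff(self.alphas) <= 0) or (
            len(self.l1_ratios) > 1 and np.any(np.diff(self.l1_ratios) <= 0)
        ):
            raise ValueError("grid values must be strictly increasing")
        if min(self.alphas) < 0 or min(self.l1_ratios) < 0 or max(self.l1_ratios) > 1:
            raise ValueError("alpha must be >= 0 and l1_ratio in [0, 1]")

    @classmethod
    def reduced(cls) -> "HyperGrid":
        """A 7 x 5 grid over the same ranges, for quick runs."""
        return cls(tuple(np.logspace(-1, 2, 7)), tuple(np.linspace(0, 1, 5)))

    @classmethod
    def single(cls, alpha: float, l1_ratio: float) -> "HyperGrid":
        return cls((alpha,), (l1_ratio,))


def _ridge_exact(xc: np.ndarray, yc: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Exact minimisers of the objective at l1_ratio=0 for many alphas.

    Returns coefficients of shape (n_alphas, p). Solved via the
    eigendecomposition of X'X/n, so the whole alpha path costs one
    decomposition.
    """
    n = xc.shape[0]
    gram = xc.T @ xc / n
    xty = xc.T @ yc / n
    evals, evecs = np.linalg.eigh(gram)
    proj = evecs.T @ xty
    coefs = np.empty((len(alphas), xc.shape[1]))
    for i, a in enumerate(alphas):
        if a == 0.0:
            inv = np.where(evals > 1e-12, 1.0 / np.where(evals > 0, evals, 1.0), 0.0)
        else:
            inv = 1.0 / (evals + a)
        coefs[i] = evecs @ (inv * proj)
    return coefs


def enet_fit(
    X, y, alpha: float, l1_ratio: float, tol: float = 1e-8, max_iter: int = 100_000
) -> tuple[np.ndarray, float]:
    """Fit one Elastic Net; returns (coefficients, intercept)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite inputs")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    xm, ym = X.mean(axis=0), y.mean()
    if alpha == 0.0 or l1_ratio == 0.0:
        coef = _ridge_exact(X - xm, y - ym, np.array([alpha * (1 - l1_ratio)]))[0]
        return coef, float(ym - xm @ coef)
    model = ElasticNet(
        alpha=alpha, l1_ratio=l1_ratio, fit_intercept=True, tol=tol, max_iter=max_iter
    )
    model.fit(X, y)
    return model.coef_.copy(), float(model.intercept_)


def enet_coef_grid(
    X, y, grid: HyperGrid, tol: float = 1e-7, max_iter: int = 10_000
) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients for every grid point, computed efficiently.

    For each l1_ratio > 0 the whole alpha path is fitted with warm
    starts (scikit-learn's ``enet_path``); l1_ratio = 0 uses the exact
    ridge solution.

    Returns
    -------
    coefs : ndarray (n_l1_ratios, n_alphas, p)
    intercepts : ndarray (n_l1_ratios, n_alphas)
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    xm, ym = X.mean(axis=0), y.mean()
    xc, yc = X - xm, y - ym
    alphas = np.asarray(grid.alphas, dtype=float)
    n_a, n_l, p = len(alphas), len(grid.l1_ratios), X.shape[1]
    coefs = np.empty((n_l, n_a, p))
    for i, l1 in enumerate(grid.l1_ratios):
        if l1 == 0.0:
            coefs[i] = _ridge_exact(xc, yc, alphas)
        else:
            # enet_path expects alphas in descending order
            order = np.argsort(alphas)[::-1]
            _, path_coefs, _ = enet_path(
                xc, yc, l1_ratio=l1, alphas=alphas[order], tol=tol, max_iter=max_iter
            )
            coefs[i][order] = path_coefs.T
    intercepts = ym - coefs @ xm
    return coefs, intercepts
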