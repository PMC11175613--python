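"""Training-fold-anchored feature preprocessing.

Every statistic used to transform features (PCA loadings, sex-
residualisation coefficients, means, standard deviations) is estimated
on a training partition only and *transferred* to the corresponding
test partition, so no information can leak from held-out rows.

Connectivity-style sets (wide vectorised correlation matrices) are
PCA-reduced first, then the component scores are sex-residualised and
standardised. Direct sets skip PCA. A switch allows residualising sex
from the raw columns before PCA instead, since either order is
defensible for correlational features.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

__all__ = [
    "fisher_z",
    "vectorize_offdiagonal",
    "PreprocParams",
    "fit_preproc",
    "apply_preproc",
]


def fisher_z(r):
    """Fisher r-to-z transform, arctanh(r). Requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def vectorize_offdiagonal(corr: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Unique off-diagonal entries of a symmetric correlation matrix.

    Returns the p(p-1)/2 upper-triangle entries in row-major order:
    (0,1), (0,2), ..., (0,p-1), (1,2), ... This fixed ordering is the
    documented feature order for connectivity sets.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(corr, corr.T, atol=atol):
        raise ValueError("matrix is not symmetric")
    iu = np.triu_indices(corr.shape[0], k=1)
    return corr[iu]


@dataclass
class PreprocParams:
    """Frozen transformation parameters estimated on one training fold.

    Attributes mirror the transformation order: optional PCA
    (``pca_mean``, ``pca_components``), then per-column sex
    residualisation (``sex_intercept + sex_slope * sex`` is subtracted),
    then centering/scaling by ``feature_means`` / ``feature_sds``.
    ``columns`` records the retained input columns (zero-variance input
    columns are dropped at fit time).
    """

    kind: str
    fit_fold_id: str
    columns: list[str]
    sex_intercept: np.ndarray
    sex_slope: np.ndarray
    feature_means: np.ndarray
    feature_sds: np.ndarray
    pca_mean: np.ndarray | None = None
    pca_components: np.ndarray | None = None  # (n_components, n_columns)
    sex_before_pca: bool = False
    raw_sex_intercept: np.ndarray | None = None
    raw_sex_slope: np.ndarray | None = None

    @property
    def n_components(self) -> int | None:
        return None if self.pca_components is None else self.pca_components.shape[0]

    def to_json(self) -> str:
        def enc(v):
            return v.tolist() if isinstance(v, np.ndarray) else v

        return json.dumps({k: enc(v) for k, v in self.__dict__.items()})

    @classmethod
    def from_json(cls, text: str) -> "PreprocParams":
        raw = json.loads(text)
        for key in ("sex_intercept", "sex_slope", "feature_means", "feature_sds",
                    "pca_mean", "pca_components", "raw_sex_intercept", "raw_sex_slope"):
            if raw.get(key) is not None:
                raw[key] = np.asarray(raw[key], dtype=float)
        return cls(**raw)


def _sex_fit(x: np.ndarray, sex: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column OLS of features on [1, sex]; slope 0 if sex is constant."""
    sex = np.asarray(sex, dtype=float)
    var = sex.var()
    if var == 0.0:
        slope = np.zeros(x.shape[1])
    else:
        slope = (x * (sex - sex.mean())[:, None]).mean(axis=0) / var
    intercept = x.mean(axis=0) - slope * sex.mean()
    return intercept, slope


def _fit_pca(x: np.ndarray, n_components: int) -> tuple[np.ndarray, np.ndarray]:
    """Training-fold PCA with a deterministic sign convention."""
    rank = min(x.shape[0] - 1, x.shape[1])
    if n_components > rank:
        warnings.warn(
            f"n_components={n_components} exceeds training rank {rank}; reduced",
            stacklevel=3,
        )
        n_components = rank
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(x)
    comps = pca.components_.copy()
    # sign fixed so each loading vector's largest-magnitude entry is positive
    idx = np.argmax(np.abs(comps), axis=1)
    signs = np.sign(comps[np.arange(comps.shape[0]), idx])
    signs[signs == 0] = 1.0
    comps *= signs[:, None]
    return pca.mean_, comps


def fit_preproc(
    train_features,
    train_sex,
    kind: str = "direct",
    n_components: int = 75,
    fit_fold_id: str = "full",
    sex_before_pca: bool = False,
) -> PreprocParams:
    """Estimate all preprocessing parameters from the training rows only.

    Parameters
    ----------
    train_features : DataFrame or ndarray (n_train, p)
    train_sex : array of 0/1
    kind : {"direct", "connectivity"}
        Connectivity sets get a PCA reduction to ``n_components``
        scores before residualisation/standardisation.
    sex_before_pca : bool
        If True, residualise sex from the raw columns before PCA
        (alternative ordering; default is PCA first).
    """
    cols = (
        list(train_features.columns)
        if hasattr(train_features, "columns")
        else [f"f{j}" for j in range(np.asarray(train_features).shape[1])]
    )
    x = np.asarray(train_features, dtype=float)
    sex = np.asarray(train_sex, dtype=float)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training rows")
    if not np.isfinite(x).all():
        raise ValueError("non-finite training features")

    # tolerance absorbs rounding in exactly-constant columns
    keep = x.std(axis=0) > 1e-12 * np.maximum(1.0, np.abs(x.mean(axis=0)))
    if not keep.all():
        dropped = [c for c, k in zip(cols, keep) if not k]
        logger.warning("dropping %d zero-variance feature(s): %s ...",
                       len(dropped), dropped[:5])
        x = x[:, keep]
        cols = [c for c, k in zip(cols, keep) if k]

    raw_int = raw_slope = None
    pca_mean = pca_comps = None
    if kind == "connectivity":
        if sex_before_pca:
            raw_int, raw_slope = _sex_fit(x, sex)
            x = x - (raw_int[None, :] + np.outer(sex, raw_slope))
        pca_mean, pca_comps = _fit_pca(x, n_components)
        x = (x - pca_mean) @ pca_comps.T
    elif kind != "direct":
        raise ValueError(f"unknown kind {kind!r}")

    sex_int, sex_slope = _sex_fit(x, sex)
    resid = x - (sex_int[None, :] + np.outer(sex, sex_slope))
    means = resid.mean(axis=0)
    sds = resid.std(axis=0, ddof=1)  # sample-sd convention
    if np.any(sds == 0.0):
        # residualised scores with no variance: neutralise scaling
        logger.warning("zero-variance residualised column(s); scale set to 1")
        sds = np.where(sds == 0.0, 1.0, sds)

    return PreprocParams(
        kind=kind,
        fit_fold_id=str(fit_fold_id),
        columns=cols,
        sex_intercept=sex_int,
        sex_slope=sex_slope,
        feature_means=means,
        feature_sds=sds,
        pca_mean=pca_mean,
        pca_components=pca_comps,
        sex_before_pca=sex_before_pca,
        raw_sex_intercept=raw_int,
        raw_sex_slope=raw_slope,
    )


def apply_preproc(features, sex, params: PreprocParams) -> np.ndarray:
    """Transform rows using stored parameters only (train -> test transfer)."""
    if hasattr(features, "columns"):
        have = list(features.columns)
        missing = [c for c in params.columns if c not in set(have)]
        if missing:
            raise ValueError(f"feature columns missing: {missing[:5]} ...")
        x = np.asarray(features[params.columns], dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        if x.shape[1] != len(params.columns):
            raise ValueError(
                f"expected {len(params.columns)} columns, got {x.shape[1]}"
            )
    sex = np.asarray(sex, dtype=float)
    if params.kind == "connectivity":
        if params.sex_before_pca:
            x = x - (params.raw_sex_intercept[None, :]
                     + np.outer(sex, params.raw_sex_slope))
        x = (x - params.pca_mean) @ params.pca_components.T
    x = x - (params.sex_intercept[None, :] + np.outer(sex, params.sex_slope))
    return (x - params.feature_means) / params.feature_sds
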