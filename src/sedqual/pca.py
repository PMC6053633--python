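"""Correlation-matrix PCA, varimax rotation, and the ECI weight B_n.

The factor machinery operates on an observations x metals matrix (for the
per-site use case: periods as observations). Data are z-scored column-wise
(sample s.d., ddof=1) so the decomposition is of the correlation matrix; a
p-variable model therefore has eigenvalues summing to p, and the variability
explained by component k is eigenvalue_k / p * 100.

Loadings follow the factor-analysis convention loading = eigenvector *
sqrt(eigenvalue), so the loading matrix reproduces the correlation matrix
(L L^T = R when no components are discarded). Column signs are normalised so
each component's largest-magnitude loading is positive — printed loading
signs are otherwise convention-dependent.

B_n, the ECI weight, is the reciprocal of a chosen (by default the first,
anthropogenic-source) eigenvalue.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA as _SkPCA

from .core import ValidationError


@dataclass(frozen=True)
class FactorModel:
    """Eigenstructure of a correlation PCA over a set of metals."""

    metals: tuple[str, ...]
    eigenvalues: np.ndarray          # descending
    loadings: np.ndarray             # metals x retained components
    variability_pct: np.ndarray      # eigenvalue / p * 100 per component
    cumulative_pct: np.ndarray       # running sum of variability
    rotation: str = "none"           # "none" | "varimax"
    #: number of variables p in the fitted correlation matrix (eigenvalue sum)
    n_variables: int = 0

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def to_frame(self) -> pd.DataFrame:
        """Table-2-style layout: one column per component."""
        cols = [f"PC{k + 1}" for k in range(self.n_components)]
        body = pd.DataFrame(self.loadings, index=[f"Load of {m}" for m in self.metals], columns=cols)
        tail = pd.DataFrame(
            [self.eigenvalues, self.variability_pct, self.cumulative_pct],
            index=["Eigenvalue", "Variability (%)", "Cumulative %"],
            columns=cols,
        )
        return pd.concat([body, tail])


def _fix_signs(loadings: np.ndarray) -> np.ndarray:
    """Flip column signs so the largest-|loading| entry of each is positive."""
    loadings = loadings.copy()
    for k in range(loadings.shape[1]):
        col = loadings[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, k] = -col
    return loadings


def standardize(matrix, metals: Sequence[str] | None = None) -> np.ndarray:
    """Z-score each column to mean 0 and sample s.d. 1 (ddof=1).

    Raises on zero-variance columns, naming the offending metal when labels
    are available.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("standardization needs a 2-D matrix with >= 2 observations")
    sd = X.std(axis=0, ddof=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [metals[j] for j in zero] if metals is not None else list(zero)
        raise ValidationError(f"zero-variance column(s): {names}")
    return (X - X.mean(axis=0)) / sd


def fit_pca(matrix, metals: Sequence[str] | None = None) -> FactorModel:
    """Correlation-matrix PCA of an observations x metals matrix.

    Accepts a DataFrame (column names become metal labels) or an array plus
    explicit ``metals``. When there are fewer than p+1 observations the
    correlation matrix is rank-deficient and trailing eigenvalues are
    reported as zero.
    """
    if isinstance(matrix, pd.DataFrame):
        if metals is None:
            metals = [str(c) for c in matrix.columns]
        matrix = matrix.to_numpy(dtype=float)
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValidationError("PCA needs at least two metals")
    if metals is None:
        metals = [f"V{j + 1}" for j in range(p)]
    Z = standardize(X, metals)
    # SVD-based PCA on z-scores: explained_variance_ (ddof=1) equals the
    # eigenvalues of the correlation matrix.
    fitted = _SkPCA(n_components=min(n, p)).fit(Z)
    eig = np.zeros(p)
    eig[: fitted.n_components_] = fitted.explained_variance_
    eig[eig < 0] = 0.0
    vectors = np.zeros((p, p))
    vectors[:, : fitted.n_components_] = fitted.components_.T
    loadings = _fix_signs(vectors * np.sqrt(eig))
    variability = eig / p * 100.0
    return FactorModel(
        metals=tuple(metals),
        eigenvalues=eig,
        loadings=loadings,
        variability_pct=variability,
        cumulative_pct=np.cumsum(variability),
        rotation="none",
        n_variables=p,
    )


def retain_components(model: FactorModel, rule: str = "kaiser", k: int | None = None) -> FactorModel:
    """Truncate a model to the retained components.

    ``rule="kaiser"`` keeps components with eigenvalue > 1 (at least one is
    always kept); ``rule="fixed"`` keeps the first ``k``.
    """
    if rule == "kaiser":
        keep = max(1, int(np.sum(model.eigenvalues > 1.0)))
    elif rule == "fixed":
        if k is None:
            raise ValidationError("fixed retention requires k")
        if not 1 <= k <= model.n_components:
            raise ValidationError(f"k={k} outside [1, {model.n_components}]")
        keep = k
    else:
        raise ValidationError(f"unknown retention rule {rule!r}")
    return replace(
        model,
        eigenvalues=model.eigenvalues[:keep],
        loadings=model.loadings[:, :keep],
        variability_pct=model.variability_pct[:keep],
        cumulative_pct=model.cumulative_pct[:keep],
    )


def varimax_criterion(loadings: np.ndarray) -> float:
    """The quantity varimax maximises: summed column variance of squared loadings."""
    L2 = np.asarray(loadings, float) ** 2
    return float(np.sum(L2.var(axis=0)))


def varimax_rotate(
    loadings: np.ndarray,
    normalize: bool = True,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> np.ndarray:
    """Orthogonal varimax rotation of a metals x k loading matrix.

    Uses the standard SVD fixed-point iteration, with Kaiser row
    normalization by default (rows scaled to unit communality during the
    rotation, restored afterwards). Communalities are invariant under the
    rotation. A single-column input is returned unchanged with a warning.
    """
    L = np.asarray(loadings, dtype=float).copy()
    if L.ndim != 2:
        raise ValidationError("loadings must be a 2-D matrix")
    p, k = L.shape
    if k < 2:
        warnings.warn("varimax undefined for a single component; returning input")
        return _fix_signs(L)
    h = None
    if normalize:
        h = np.sqrt((L**2).sum(axis=1))
        if (h == 0).any():
            raise ValidationError("zero-communality row; cannot Kaiser-normalize")
        L = L / h[:, None]
    R = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        d_old = d
        B = L @ R
        U, S, Vt = np.linalg.svd(L.T @ (B**3 - B @ np.diag((B**2).sum(axis=0)) / p))
        R = U @ Vt
        d = S.sum()
        if d_old != 0 and d / d_old < 1 + tol:
            break
    rotated = L @ R
    if normalize:
        rotated = rotated * h[:, None]
    return _fix_signs(rotated)


def rotate_model(model: FactorModel, normalize: bool = True) -> FactorModel:
    """Varimax-rotate a (retained) model.

    Eigenvalues and variability are re-derived as the rotated components'
    sums of squared loadings, the usual post-rotation convention.
    """
    rotated = varimax_rotate(model.loadings, normalize=normalize)
    ssl = (rotated**2).sum(axis=0)
    order = np.argsort(-ssl)
    rotated, ssl = rotated[:, order], ssl[order]
    p = model.n_variables or model.loadings.shape[0]
    variability = ssl / p * 100.0
    return replace(
        model,
        eigenvalues=ssl,
        loadings=rotated,
        variability_pct=variability,
        cumulative_pct=np.cumsum(variability),
        rotation="varimax",
    )


def bn_weight(model_or_eigenvalue, component: int = 1) -> float:
    """B_n = 1 / eigenvalue of the chosen component (1-based; default PC1)."""
    if isinstance(model_or_eigenvalue, FactorModel):
        if not 1 <= component <= model_or_eigenvalue.n_components:
            raise ValidationError(
                f"component {component} outside [1, {model_or_eigenvalue.n_components}]"
            )
        eig = float(model_or_eigenvalue.eigenvalues[component - 1])
    else:
        eig = float(model_or_eigenvalue)
    if not (math.isfinite(eig) and eig > 0):
        raise ValidationError(f"B_n requires a positive eigenvalue, got {eig!r}")
    return 1.0 / eig
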