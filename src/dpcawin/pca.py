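"""PCA on a training window matrix and projection of windows onto its basis.

The model is fitted by eigendecomposition of the ``l × l`` sample covariance
of the mean-centred training rows (each length-``l`` window is one
observation of ``l`` lagged variables).  The training column mean is stored
and subtracted from every window that is later projected; no per-window
centring is applied.  Eigenvectors are returned unit-norm, ordered by
decreasing eigenvalue, with a deterministic sign convention: each column is
flipped so that its largest-magnitude entry (earliest index on ties) is
positive.  Individual eigenvectors are unstable when eigenvalues nearly
coincide, but the spanned subspace — and hence every norm and energy computed
from the scores — remains well defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import WindowMatrix

__all__ = [
    "PCAModel",
    "ProjectedWindow",
    "fit_pca",
    "project_window",
    "project_rows",
    "explained_variance_ratio",
]


@dataclass
class PCAModel:
    """Fitted PCA basis for length-``l`` windows.

    Attributes
    ----------
    mean_vector : (l,) ndarray
        Per-column mean of the training matrix.
    loadings : (l, l) ndarray
        Orthonormal eigenvector matrix; column ``v`` is the ``v``-th
        principal direction (decreasing eigenvalue order, sign-fixed).
    eigenvalues : (l,) ndarray
        Non-negative, non-increasing variances along each direction.
    """

    mean_vector: np.ndarray
    loadings: np.ndarray
    eigenvalues: np.ndarray
    window_length: int
    n_train_rows: int


@dataclass
class ProjectedWindow:
    """Full score vector of one window in the fitted PC basis."""

    scores: np.ndarray
    window_index: int = 0
    source_id: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float).ravel()


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| (earliest on ties) is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(col)))  # argmax returns the earliest maximum
        if col[i] < 0:
            out[:, j] = -col
    return out


def fit_pca(training: WindowMatrix) -> PCAModel:
    """Fit a PCA model to the rows of a training window matrix.

    Raises if fewer than two rows are available or any entry is non-finite.
    """
    X = training.rows
    if X.shape[0] < 2:
        raise ValueError(
            f"PCA needs at least 2 training rows, got {X.shape[0]}"
        )
    bad = ~np.isfinite(X)
    if bad.any():
        r = int(np.argwhere(bad.any(axis=1))[0, 0])
        raise ValueError(
            f"non-finite entries in training row {r} "
            f"(origin {training.row_origins[r]!r})"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    cov = (Xc.T @ Xc) / (X.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _fix_signs(evecs[:, order])
    return PCAModel(
        mean_vector=mean,
        loadings=evecs,
        eigenvalues=evals,
        window_length=training.window_length,
        n_train_rows=int(X.shape[0]),
    )


def project_window(model: PCAModel, window: np.ndarray,
                   window_index: int = 0, source_id: str = "") -> ProjectedWindow:
    """Project one window onto the model's eigenvector basis.

    ``scores_v = <window - mean, V_v>`` for ``v = 1..l``.
    """
    w = np.asarray(window, dtype=float).ravel()
    if w.size != model.window_length:
        raise ValueError(
            f"window has length {w.size} but model expects "
            f"{model.window_length}"
        )
    scores = (w - model.mean_vector) @ model.loadings
    return ProjectedWindow(scores=scores, window_index=window_index,
                           source_id=source_id)


def project_rows(model: PCAModel, rows: np.ndarray) -> np.ndarray:
    """Vectorised projection: score matrix for an ``(n, l)`` stack of windows."""
    rows = np.asarray(rows, dtype=float)
    if rows.ndim != 2 or rows.shape[1] != model.window_length:
        raise ValueError(
            f"rows must be (n, {model.window_length}), got {rows.shape}"
        )
    return (rows - model.mean_vector) @ model.loadings


def explained_variance_ratio(model: PCAModel, n_components: int) -> float:
    """Fraction of total training variance carried by the first ``n`` PCs.

    Returns 1.0 for a degenerate model with zero total variance.
    """
    l = model.window_length
    if not 1 <= n_components <= l:
        raise ValueError(f"n_components must be in [1, {l}], got {n_components}")
    total = float(model.eigenvalues.sum())
    if total == 0.0:
        return 1.0
    return float(model.eigenvalues[:n_components].sum()) / total
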