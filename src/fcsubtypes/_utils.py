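"""Shared numerical helpers: row-wise Pearson correlation with missing-value support."""

from __future__ import annotations

import numpy as np

__all__ = ["as_matrix", "pearson_rows", "pearson_pairwise", "row_standardize"]


def as_matrix(x) -> np.ndarray:
    """Return a 2-D float array from an array, DataFrame, or SeedFCMatrix-like object."""
    if hasattr(x, "values") and not isinstance(x, np.ndarray):
        x = x.values
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D matrix, got shape {arr.shape}")
    return arr


def row_standardize(X: np.ndarray) -> np.ndarray:
    """Center and unit-normalize each row (for spatial correlation via dot products).

    Rows with zero variance raise, naming the offending row.
    """
    X = as_matrix(X)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        raise ValueError(f"zero-variance map(s) at row index {bad.tolist()}")
    return Xc / norms[:, None]


def _pearson_rows_masked(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pairwise-complete Pearson correlation between rows of X and rows of Y."""
    n, m = X.shape[0], Y.shape[0]
    out = np.empty((n, m))
    for i in range(n):
        xi = X[i]
        for j in range(m):
            yj = Y[j]
            ok = np.isfinite(xi) & np.isfinite(yj)
            if ok.sum() < 3:
                raise ValueError(
                    f"fewer than 3 mutually non-missing features between rows {i} and {j}"
                )
            a = xi[ok] - xi[ok].mean()
            b = yj[ok] - yj[ok].mean()
            na, nb = np.linalg.norm(a), np.linalg.norm(b)
            if na == 0 or nb == 0:
                raise ValueError(f"zero-variance map over shared features (rows {i}, {j})")
            out[i, j] = float(a @ b / (na * nb))
    return out


def pearson_rows(X, Y) -> np.ndarray:
    """Spatial Pearson correlation between every row of ``X`` and every row of ``Y``.

    Returns an (n_X, n_Y) matrix in [-1, 1]. Missing values (NaN) are handled
    pairwise-complete; the fast path requires fully observed rows.
    """
    X, Y = as_matrix(X), as_matrix(Y)
    if X.shape[1] != Y.shape[1]:
        raise ValueError(f"feature mismatch: {X.shape[1]} vs {Y.shape[1]}")
    if np.isnan(X).any() or np.isnan(Y).any():
        return np.clip(_pearson_rows_masked(X, Y), -1.0, 1.0)
    R = row_standardize(X) @ row_standardize(Y).T
    return np.clip(R, -1.0, 1.0)


def pearson_pairwise(X) -> np.ndarray:
    """Symmetric correlation matrix between rows of X (unit diagonal enforced)."""
    R = pearson_rows(X, X)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R
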