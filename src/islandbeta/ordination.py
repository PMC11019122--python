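"""Principal-coordinate and redundancy-analysis primitives.

Shared by the spatial-eigenvector selection and the variation
partitioning: principal coordinates of a dissimilarity matrix (with the
square-root transform that makes Jaccard-family dissimilarities
Euclidean-embeddable), least-squares explained variance of the
coordinate cloud on a predictor matrix, and the classical adjusted R².
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import DomainError

EIG_TOL = 1e-9


def pcoa_axes(D: np.ndarray, sqrt_transform: bool = True) -> np.ndarray:
    """Principal coordinates of a symmetric dissimilarity matrix.

    With ``sqrt_transform`` the matrix of squared distances is D itself
    (the square root of each dissimilarity is taken before Gower double
    centering), which keeps Jaccard-family input free of negative
    eigenvalues.  Axes with eigenvalue <= 1e-9 are discarded.
    """
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DomainError("dissimilarity matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise DomainError("dissimilarity matrix must be symmetric")
    sq = D if sqrt_transform else D**2
    n = D.shape[0]
    H = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * H @ sq @ H
    G = (G + G.T) / 2.0
    lam, V = np.linalg.eigh(G)
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    keep = lam > EIG_TOL
    return V[:, keep] * np.sqrt(lam[keep])


def center_predictors(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if np.isnan(X).any():
        raise DomainError("predictor matrix contains missing values")
    return X - X.mean(axis=0)


def drop_constant_columns(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove predictors with zero variance (e.g. a strait indicator that
    is constant after scale filtering); returns the kept frame and the
    dropped column names."""
    dropped = [c for c in X.columns if float(np.ptp(X[c].to_numpy(dtype=float))) == 0.0]
    return X.drop(columns=dropped), dropped


def predictor_q(X: pd.DataFrame | np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Orthonormal basis of the centered predictor space; errors on collinearity."""
    Xc = center_predictors(X)
    if names is None:
        names = (
            list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(Xc.shape[1])]
        )
    Q, R = np.linalg.qr(Xc)
    small = np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(np.diag(R)).max())
    if small.any():
        bad = [names[i] for i in np.where(small)[0]]
        raise DomainError(f"collinear or constant predictor columns: {bad}")
    return Q


def r_squared(Y: np.ndarray, Q: np.ndarray) -> float:
    """Fraction of the total sum of squares of Y captured by projection on Q."""
    total = float(np.sum(Y * Y))
    if total == 0:
        raise DomainError("response has no variance")
    proj = Q.T @ Y
    return float(np.sum(proj * proj) / total)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Classical Ezard / Peres-Neto correction 1 - (1-R^2)(n-1)/(n-p-1)."""
    if n <= p + 1:
        raise DomainError(f"n = {n} too small for p = {p} predictors")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
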