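"""Comparator models: PLSR on full spectra and global OLS on selected wavelets.

PLSR extracts latent components by the iterative (NIPALS) recursion on the
X'y cross-covariance, with the component count chosen by seeded ten-fold
cross-validation; WLR is ordinary least squares with intercept on the
wavelet features chosen by the selection stage, scored with the
small-sample-corrected AIC so it is directly comparable with the GWR AICc.
"""

from __future__ import annotations

import numpy as np
from dataclasses import dataclass, field

from sklearn.model_selection import KFold

__all__ = ["PLSRModel", "WLRModel", "fit_plsr", "predict_plsr", "fit_wlr", "linear_aicc"]


@dataclass
class PLSRModel:
    n_components: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # p x A
    loadings: np.ndarray      # p x A
    scores: np.ndarray        # n x A (training scores)
    y_loadings: np.ndarray    # A
    coef: np.ndarray          # regression vector on centered X at chosen A
    cv_rmse: np.ndarray | None = None  # mean CV RMSE per candidate A

    def regression_vector(self):
        """(intercept, slopes) on the original X scale."""
        return float(self.y_mean - self.x_mean @ self.coef), self.coef


def _nipals_pls1(Xc, yc, A):
    """NIPALS PLS1 on centered data; returns (W, P, T, q) for A components."""
    n, p = Xc.shape
    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    q = np.empty(A)
    X = Xc.copy()
    y = yc.copy()
    for a in range(A):
        w = X.T @ y
        nrm = np.linalg.norm(w)
        if nrm == 0:
            raise np.linalg.LinAlgError("degenerate cross-covariance; reduce components")
        w /= nrm
        t = X @ w
        tt = t @ t
        if tt == 0:
            raise np.linalg.LinAlgError("zero score vector; reduce components")
        pvec = X.T @ t / tt
        qa = y @ t / tt
        X = X - np.outer(t, pvec)
        y = y - qa * t
        W[:, a], P[:, a], T[:, a], q[a] = w, pvec, t, qa
    return W, P, T, q


def _pls_coef(W, P, q, A):
    """Regression vector b with ŷ = Xc b for the first A components."""
    Wa, Pa, qa = W[:, :A], P[:, :A], q[:A]
    return Wa @ np.linalg.solve(Pa.T @ Wa, qa)


def fit_plsr(X, y, max_components: int = 20, folds: int = 10, seed: int = 0) -> PLSRModel:
    """PLS1 regression with the component count minimising mean CV RMSE.

    Centering is done inside each cross-validation fold (no leakage); the
    fold partition is seeded and shared across candidate component counts.
    Ties in CV RMSE go to the smaller component count.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if np.ptp(y) == 0:
        raise ValueError("response has zero variance")
    A_max = min(max_components, n - 1, p)
    if A_max < 1:
        raise ValueError("max_components must allow at least one component")

    folds = min(folds, n)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sse = np.zeros(A_max)
    count = 0
    for tr, te in kf.split(X):
        A_fold = min(A_max, tr.size - 1)
        xm = X[tr].mean(axis=0)
        ym = y[tr].mean()
        W, P, T, q = _nipals_pls1(X[tr] - xm, y[tr] - ym, A_fold)
        Xe = X[te] - xm
        for A in range(1, A_max + 1):
            b = _pls_coef(W, P, q, min(A, A_fold))
            pred = ym + Xe @ b
            sse[A - 1] += np.sum((y[te] - pred) ** 2)
        count += te.size
    cv_rmse = np.sqrt(sse / count)
    A_opt = int(np.flatnonzero(cv_rmse <= cv_rmse.min() + 1e-12)[0]) + 1

    xm = X.mean(axis=0)
    ym = float(y.mean())
    W, P, T, q = _nipals_pls1(X - xm, y - ym, A_opt)
    return PLSRModel(
        n_components=A_opt, x_mean=xm, y_mean=ym,
        weights=W, loadings=P, scores=T, y_loadings=q,
        coef=_pls_coef(W, P, q, A_opt), cv_rmse=cv_rmse,
    )


def predict_plsr(model: PLSRModel, X_new) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError("column count does not match the training design")
    return model.y_mean + (X_new - model.x_mean) @ model.coef


def linear_aicc(n: int, rss: float, n_features: int) -> float:
    """Small-sample AICc of a Gaussian linear model.

    k counts intercept + slopes + residual variance. The constant
    convention matches the GWR hat-trace AICc exactly in the OLS limit
    (tr S = n_features + 1), so relative likelihoods across model families
    are meaningful.
    """
    k = n_features + 2
    if n - k - 1 <= 0 or rss <= 0:
        return float("inf")
    return float(n * np.log(rss / n) + n * np.log(2 * np.pi) + n
                 + 2 * k + 2 * k * (k + 1) / (n - k - 1))


@dataclass
class WLRModel:
    """Global OLS on intercept + selected wavelet features."""

    coefficients: np.ndarray
    fitted: np.ndarray
    rss: float
    aicc: float
    n: int = 0
    columns: list = field(default_factory=list)

    def predict(self, X_new) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        return self.coefficients[0] + X_new @ self.coefficients[1:]


def fit_wlr(X, y, columns=None) -> WLRModel:
    """OLS with intercept on the selected features; AICc per linear_aicc."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta, _, rank, _ = np.linalg.lstsq(Z, y, rcond=None)
    if rank < m + 1:
        raise np.linalg.LinAlgError("rank-deficient design in WLR")
    fitted = Z @ beta
    rss = float(np.sum((y - fitted) ** 2))
    return WLRModel(coefficients=beta, fitted=fitted, rss=rss,
                    aicc=linear_aicc(n, rss, m), n=n,
                    columns=list(columns) if columns is not None else [])
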