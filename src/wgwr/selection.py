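"""Three-stage optimal wavelet-coefficient selection.

Stage 1 ranks every (scale, wavelength) column by the absolute Pearson
correlation |R| with the response. Stage 2 walks the ranked list greedily,
keeping a candidate only if the variance inflation factors of the tentative
accepted set all stay below a threshold (default 10), so the surviving
features are mutually near-orthogonal. Stage 3 adds the survivors one at a
time, in rank order, to a ten-fold cross-validated OLS and picks the subset
size with the largest mean held-out R^2.

All three stages are meant to run on training rows only, so the held-out
test split never leaks into feature choice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "RankedFeature",
    "SelectionResult",
    "rank_features",
    "vif",
    "sequential_vif_filter",
    "cv_select_k",
    "select_features",
]


@dataclass(frozen=True)
class RankedFeature:
    """One wavelet feature with its rank by |Pearson R| against the response."""

    column: int
    scale: str
    wavelength: float
    abs_corr: float
    rank: int


@dataclass
class SelectionResult:
    ranked: list
    vif_filtered: list
    vif_trace: list  # (feature, max_vif_if_added, accepted)
    cv_mean_train_r2: np.ndarray
    cv_mean_test_r2: np.ndarray
    k_opt: int
    selected: list = field(default_factory=list)

    def selected_columns(self) -> list:
        return [f.column for f in self.selected]

    def to_dict(self) -> dict:
        return {
            "k_opt": self.k_opt,
            "selected": [
                {"scale": f.scale, "wavelength": f.wavelength,
                 "abs_corr": f.abs_corr, "rank": f.rank}
                for f in self.selected
            ],
            "n_ranked": len(self.ranked),
            "n_vif_filtered": len(self.vif_filtered),
            "cv_mean_train_r2": [float(v) for v in self.cv_mean_train_r2],
            "cv_mean_test_r2": [float(v) for v in self.cv_mean_test_r2],
            "vif_trace": [
                {"scale": f.scale, "wavelength": f.wavelength,
                 "max_vif": (None if not np.isfinite(v) else float(v)),
                 "accepted": bool(a)}
                for f, v, a in self.vif_trace
            ],
        }


def _columns_of(features):
    """Accept a WaveletFeatureMatrix or a plain 2-D array."""
    if hasattr(features, "values") and hasattr(features, "scale_of"):
        return features.values, features.scale_of
    X = np.asarray(features, dtype=float)
    return X, lambda j: (f"col{j}", float(j))


def rank_features(features, y) -> list:
    """Rank columns by absolute Pearson correlation with ``y`` (descending).

    Zero-variance columns get |R| = 0. Ties are broken by column order
    (scale-major, then wavelength), so the ranking is deterministic.
    """
    X, scale_of = _columns_of(features)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.size:
        raise ValueError("feature rows and response length differ")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples to correlate")
    if np.ptp(y) == 0:
        raise ValueError("response is constant")

    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / (sx * sy)
    absr = np.abs(np.where(sx > 0, r, 0.0))
    absr = np.clip(absr, 0.0, 1.0)

    order = np.lexsort((np.arange(absr.size), -absr))
    return [
        RankedFeature(column=int(j), scale=scale_of(int(j))[0],
                      wavelength=scale_of(int(j))[1],
                      abs_corr=float(absr[j]), rank=rk + 1)
        for rk, j in enumerate(order)
    ]


def vif(X) -> np.ndarray:
    """Variance inflation factors of the columns of ``X``.

    VIF_j = 1 / (1 - R^2_j), with R^2_j from regressing column j on the
    remaining columns plus an intercept. Exact collinearity yields +inf
    rather than an exception. A single column has VIF 1 by convention.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if p == 1:
        return np.array([1.0])
    if n <= p:
        raise ValueError(f"need n > p for VIF (n={n}, p={p})")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant column in VIF computation")
    out = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        yj = X[:, j]
        Zj = np.concatenate([ones, np.delete(X, j, axis=1)], axis=1)
        beta, *_ = np.linalg.lstsq(Zj, yj, rcond=None)
        resid = yj - Zj @ beta
        sst = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - resid @ resid / sst
        out[j] = np.inf if 1.0 - r2 < 1e-12 else 1.0 / (1.0 - r2)
    return out


def sequential_vif_filter(ranked, features, threshold: float = 10.0,
                          max_features: int | None = None):
    """Greedy multicollinearity filter over the ranked feature list.

    The top-ranked feature is accepted unconditionally. Each subsequent
    candidate is tentatively added to the accepted set; it is kept iff the
    maximum VIF of the tentative set stays below ``threshold``. VIFs are
    computed from the inverse correlation matrix of the standardized
    accepted set, updated by the bordered-inverse identity, which is
    algebraically the regression definition.

    ``max_features`` optionally bounds the accepted-set size (the greedy
    rule itself is unchanged; the pass just stops once the bound is hit),
    keeping the later cross-validation stage well-posed when thousands of
    candidates are offered.

    Returns ``(accepted, trace)`` where trace rows are
    ``(feature, max_vif_if_added, accepted_flag)``.
    """
    if not ranked:
        raise ValueError("ranked feature list is empty")
    X, _ = _columns_of(features)
    n = X.shape[0]

    def standardized(col):
        v = X[:, col].astype(float)
        sd = v.std(ddof=1)
        if sd == 0:
            return None
        return (v - v.mean()) / sd

    accepted = []
    trace = []
    Z_acc = None        # n x k standardized accepted columns
    C_inv = None        # inverse correlation matrix of accepted set
    for feat in ranked:
        z = standardized(feat.column)
        if z is None:
            trace.append((feat, np.inf, False))
            continue
        if not accepted:
            accepted.append(feat)
            Z_acc = z[:, None]
            C_inv = np.array([[1.0]])
            trace.append((feat, 1.0, True))
            continue
        k = len(accepted)
        if k + 1 >= n - 1:
            break  # VIF no longer well defined; accepted set is as large as n allows
        r = Z_acc.T @ z / (n - 1)
        u = C_inv @ r
        s = 1.0 - r @ u  # Schur complement = 1 - R^2 of candidate on accepted
        if s <= 1e-12:
            max_vif = np.inf
        else:
            vifs_old = np.diag(C_inv) + u ** 2 / s
            max_vif = max(1.0 / s, float(vifs_old.max()))
        ok = max_vif < threshold
        trace.append((feat, max_vif, ok))
        if ok:
            # bordered inverse update
            top = C_inv + np.outer(u, u) / s
            C_inv = np.block([[top, -u[:, None] / s],
                              [-u[None, :] / s, np.array([[1.0 / s]])]])
            Z_acc = np.concatenate([Z_acc, z[:, None]], axis=1)
            accepted.append(feat)
            if max_features is not None and len(accepted) >= max_features:
                break
    return accepted, trace


def cv_select_k(filtered, features, y, folds: int = 10, seed: int = 0):
    """Choose the subset size by ten-fold cross-validated OLS.

    For k = 1..len(filtered), an OLS with intercept on the first k filtered
    features is fit inside each CV training fold and scored by R^2 on the
    held-out fold; the fold partition is seeded and shared across k.
    Returns ``(k_opt, mean_train_r2, mean_test_r2)``; ties in mean test R^2
    go to the smallest k.
    """
    if not filtered:
        raise ValueError("no filtered features to cross-validate")
    X, _ = _columns_of(features)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < folds:
        raise ValueError(f"n={n} smaller than folds={folds}")
    p = len(filtered)
    min_train = n - int(np.ceil(n / folds))
    if min_train < p + 2:
        new_folds = max(2, int(np.ceil(n / (n - p - 2)))) if n > p + 2 else 2
        warnings.warn(f"reducing folds from {folds} to {new_folds} so each "
                      f"training fold holds at least k+2 samples")
        folds = new_folds

    cols = [f.column for f in filtered]
    Xf = X[:, cols]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    train_r2 = np.zeros((folds, p))
    test_r2 = np.zeros((folds, p))
    for fi, (tr, te) in enumerate(kf.split(Xf)):
        for k in range(1, p + 1):
            Zt = np.column_stack([np.ones(tr.size), Xf[tr, :k]])
            beta, *_ = np.linalg.lstsq(Zt, y[tr], rcond=None)
            fit = Zt @ beta
            sst = np.sum((y[tr] - y[tr].mean()) ** 2)
            train_r2[fi, k - 1] = 1.0 - np.sum((y[tr] - fit) ** 2) / sst
            Ze = np.column_stack([np.ones(te.size), Xf[te, :k]])
            pred = Ze @ beta
            sst_e = np.sum((y[te] - y[te].mean()) ** 2)
            if sst_e == 0:  # degenerate fold: constant held-out response
                test_r2[fi, k - 1] = np.nan
            else:
                test_r2[fi, k - 1] = 1.0 - np.sum((y[te] - pred) ** 2) / sst_e
    mean_train = train_r2.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_test = np.nanmean(test_r2, axis=0)
    best = float(mean_test.max())
    k_opt = int(np.flatnonzero(mean_test >= best - 1e-12)[0]) + 1
    if best <= 0:
        warnings.warn("no cross-validated skill: mean held-out R^2 <= 0 for every k")
    return k_opt, mean_train, mean_test


def select_features(features, y, threshold: float = 10.0, folds: int = 10,
                    seed: int = 0, max_features: int | None = None) -> SelectionResult:
    """Run the full three-stage procedure and bundle the outcome."""
    ranked = rank_features(features, y)
    filtered, trace = sequential_vif_filter(ranked, features, threshold=threshold,
                                            max_features=max_features)
    k_opt, mean_train, mean_test = cv_select_k(filtered, features, y,
                                               folds=folds, seed=seed)
    return SelectionResult(
        ranked=ranked,
        vif_filtered=filtered,
        vif_trace=trace,
        cv_mean_train_r2=mean_train,
        cv_mean_test_r2=mean_test,
        k_opt=k_opt,
        selected=filtered[:k_opt],
    )
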