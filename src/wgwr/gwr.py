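"""Geographically weighted regression with an adaptive Gaussian kernel.

The model is s = beta_0(u) + sum_i beta_i(u) w_i + eps: at every location a
weighted least-squares fit is computed with weights that decay with distance
as exp(-0.5 (d/b)^2), where the bandwidth b is the distance to the q-th
nearest training location (adaptive: the kernel widens where sampling is
sparse). The neighbour count q is chosen by minimising the corrected Akaike
criterion computed from the trace of the hat matrix, and spatial
non-stationarity of the coefficients is assessed with a Monte-Carlo
randomisation test that reassigns locations to observations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "GWRModel",
    "NonstationarityTest",
    "adaptive_gaussian_weights",
    "fit_local",
    "fit_gwr",
    "gwr_aicc",
    "optimize_bandwidth",
    "predict",
    "montecarlo_nonstationarity_test",
    "lonlat_to_planar",
    "jitter_locations",
]

_EARTH_RADIUS_KM = 6371.0


def lonlat_to_planar(lon, lat, lat0=None):
    """Equirectangular projection of lon/lat degrees to planar km.

    A rough convenience for exercising the model with geographic inputs;
    real analyses should supply properly projected coordinates.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lat0 = float(np.mean(lat)) if lat0 is None else lat0
    x = np.radians(lon) * _EARTH_RADIUS_KM * np.cos(np.radians(lat0))
    y = np.radians(lat) * _EARTH_RADIUS_KM
    return np.column_stack([x, y])


def jitter_locations(locations, scale=1e-6, seed=0):
    """Break exact coordinate ties with tiny uniform noise (seeded).

    Useful when duplicated sampling locations make the adaptive bandwidth
    collapse to zero.
    """
    locs = np.asarray(locations, dtype=float)
    rng = np.random.default_rng(seed)
    return locs + rng.uniform(-scale, scale, size=locs.shape)


def _kernel(d, b, kind):
    z = d / b
    if kind == "gaussian":
        return np.exp(-0.5 * z ** 2)
    if kind == "bisquare":
        w = (1.0 - z ** 2) ** 2
        return np.where(z < 1.0, w, 0.0)
    raise ValueError(f"unknown kernel {kind!r}")


def adaptive_gaussian_weights(u0, train_locations, q, *, exclude_self=False,
                              kernel="gaussian"):
    """Kernel weights of the training points as seen from location ``u0``.

    The bandwidth is the distance from ``u0`` to its q-th nearest training
    location. When ``u0`` is itself a training point (``exclude_self``),
    one zero distance is ignored for the bandwidth rank, but the point
    still receives weight 1 in the fit.
    """
    u0 = np.asarray(u0, dtype=float).reshape(1, 2)
    locs = np.asarray(train_locations, dtype=float)
    d = cdist(u0, locs)[0]
    n = d.size
    if not 1 <= q <= n:
        raise ValueError(f"q={q} outside [1, {n}]")
    ds = np.sort(d)
    if exclude_self:
        zero = np.flatnonzero(ds == 0.0)
        if zero.size:
            ds = np.delete(ds, zero[0])
    b = ds[min(q, ds.size) - 1]
    if b == 0.0:
        raise ValueError(
            "adaptive bandwidth is zero (q-th neighbour coincident); "
            "jitter coincident locations or increase q"
        )
    return _kernel(d, b, kernel)


def fit_local(X, y, weights):
    """Weighted least squares beta = (X'WX)^-1 X'Wy via a stable lstsq solve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    sw = np.sqrt(w)
    beta, _, rank, _ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError("weighted design is rank deficient")
    return beta


def _weight_matrix(locations, q, kernel, flat):
    """n x n matrix whose row i holds the weights for fitting at location i."""
    locs = np.asarray(locations, dtype=float)
    n = locs.shape[0]
    if flat:
        return np.ones((n, n))
    D = cdist(locs, locs)
    # per-row adaptive bandwidth: q-th nearest other point (self excluded once)
    Ds = np.sort(D, axis=1)
    has_self = Ds[:, 0] == 0.0
    idx = np.minimum(q - 1 + has_self, n - 1)
    b = Ds[np.arange(n), idx]
    if np.any(b == 0.0):
        i = int(np.flatnonzero(b == 0.0)[0])
        raise ValueError(
            f"zero adaptive bandwidth at training location index {i} "
            "(q-th neighbour coincident); jitter locations or increase q"
        )
    return _kernel(D, b[:, None], kernel)


@dataclass
class GWRModel:
    """Fitted GWR: local coefficient surfaces plus goodness-of-fit summary."""

    X: np.ndarray
    y: np.ndarray
    locations: np.ndarray
    q: int
    kernel: str
    flat: bool
    local_coefficients: np.ndarray  # n x (m+1)
    fitted: np.ndarray
    trace_S: float
    sigma2: float
    aicc: float

    @property
    def n(self) -> int:
        return self.y.size

    def hat_row(self, i: int) -> np.ndarray:
        """Row i of the hat matrix S: fitted_i = S[i] @ y."""
        W = _weight_matrix(self.locations, self.q, self.kernel, self.flat)
        w = W[i]
        A = self.X.T @ (self.X * w[:, None])
        z = np.linalg.solve(A, self.X[i])
        return (self.X @ z) * w

    def summary(self) -> dict:
        return {
            "q": int(self.q),
            "kernel": self.kernel,
            "n": int(self.n),
            "trace_S": float(self.trace_S),
            "sigma2": float(self.sigma2),
            "aicc": float(self.aicc),
        }


def gwr_aicc(n: int, sigma2: float, trace_S: float) -> float:
    """Corrected AIC of a linear smoother with tr(S) effective parameters.

    AICc = 2n ln(sigma_hat) + n ln(2 pi) + n (n + tr S) / (n - 2 - tr S);
    returns +inf when the effective parameter count exhausts the sample.
    """
    denom = n - 2.0 - trace_S
    if denom <= 0 or sigma2 <= 0:
        return float("inf")
    return float(n * np.log(sigma2) + n * np.log(2 * np.pi)
                 + n * (n + trace_S) / denom)


def fit_gwr(X, y, locations, q, *, kernel="gaussian", flat=False) -> GWRModel:
    """Fit local coefficients at every training location.

    ``flat=True`` replaces the kernel by uniform weights (the infinite
    bandwidth limit), under which every local fit equals the global OLS.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    locs = np.asarray(locations, dtype=float)
    n, p = X.shape
    if n != y.size or locs.shape != (n, 2):
        raise ValueError("X, y and locations must agree in length")
    if n <= p + 2:
        raise ValueError(f"need n > m + 2 (n={n}, m+1={p})")
    if not flat and not p + 2 <= q <= n:
        raise ValueError(f"q={q} outside [m+2, n] = [{p + 2}, {n}]")

    W = _weight_matrix(locs, q, kernel, flat)
    # batched weighted normal equations: A_i = X' diag(W_i) X, c_i = X' W_i y
    A = np.einsum("nt,tj,tk->njk", W, X, X, optimize=True)
    c = W @ (X * y[:, None])
    try:
        beta = np.linalg.solve(A, c[:, :, None])[..., 0]
        z = np.linalg.solve(A, X[:, :, None])[..., 0]  # A_i^{-1} x_i
    except np.linalg.LinAlgError:
        for i in range(n):
            try:
                np.linalg.cholesky(A[i] + A[i].T)
            except np.linalg.LinAlgError:
                raise np.linalg.LinAlgError(
                    f"rank-deficient weighted design at location index {i}"
                ) from None
        raise
    fitted = np.einsum("ij,ij->i", X, beta)
    hat_diag = W[np.arange(n), np.arange(n)] * np.einsum("ij,ij->i", X, z)
    trace_S = float(hat_diag.sum())
    rss = float(np.sum((y - fitted) ** 2))
    sigma2 = rss / n
    return GWRModel(
        X=X, y=y, locations=locs, q=int(q) if not flat else n, kernel=kernel,
        flat=flat, local_coefficients=beta, fitted=fitted,
        trace_S=trace_S, sigma2=sigma2,
        aicc=gwr_aicc(n, sigma2, trace_S),
    )


def optimize_bandwidth(X, y, locations, q_range=None, *, kernel="gaussian"):
    """Adaptive neighbour count minimising the AICc.

    Golden-section search on the integer grid, followed by an exhaustive
    sweep of the final bracket, which guards against mild non-unimodality.
    Returns ``(q_opt, {q: aicc})``.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if q_range is None:
        q_range = (p + 3, n)
    lo, hi = int(q_range[0]), int(q_range[1])
    if not p + 2 <= lo <= hi <= n:
        raise ValueError(f"q_range {q_range} outside [{p + 2}, {n}]")

    cache: dict = {}

    def f(q):
        if q not in cache:
            cache[q] = fit_gwr(X, y, locations, q, kernel=kernel).aicc
        return cache[q]

    phi = (np.sqrt(5) - 1) / 2
    a, b = lo, hi
    while b - a > 4:
        c1 = int(round(b - phi * (b - a)))
        c2 = int(round(a + phi * (b - a)))
        if c1 >= c2:
            break
        if f(c1) <= f(c2):
            b = c2
        else:
            a = c1
    for q in range(a, b + 1):
        f(q)
    finite = {q: v for q, v in cache.items() if np.isfinite(v)}
    if not finite:
        raise ValueError("AICc not finite for any bandwidth; model too flexible for n")
    q_opt = min(finite, key=lambda q: (finite[q], q))
    return q_opt, cache


def predict(model: GWRModel, X_new, new_locations) -> np.ndarray:
    """Local prediction at unseen locations.

    For each new location, adaptive weights against the training locations
    are recomputed with the fitted q, a local fit is solved on the training
    data, and the new design row is evaluated at those coefficients.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    locs_new = np.atleast_2d(np.asarray(new_locations, dtype=float))
    if X_new.shape[1] != model.X.shape[1]:
        raise ValueError("X_new column count does not match the training design")
    if locs_new.shape != (X_new.shape[0], 2):
        raise ValueError("new_locations must be (n_new, 2)")
    out = np.empty(X_new.shape[0])
    for i in range(X_new.shape[0]):
        if model.flat:
            w = np.ones(model.n)
        else:
            w = adaptive_gaussian_weights(locs_new[i], model.locations, model.q,
                                          kernel=model.kernel, exclude_self=True)
        beta = fit_local(model.X, model.y, w)
        out[i] = X_new[i] @ beta
    return out


@dataclass
class NonstationarityTest:
    """Randomisation test of spatial variability in the local coefficients."""

    variance: np.ndarray        # observed variance of each coefficient surface
    cv: np.ndarray              # observed |coefficient of variation|
    p_variance: np.ndarray      # permutation p-value per coefficient (variance stat)
    p_cv: np.ndarray            # permutation p-value per coefficient (CV stat)
    n_perm: int


def _coef_stats(beta):
    var = beta.var(axis=0, ddof=1)
    mean = beta.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.abs(np.sqrt(var) / mean)
    return var, cv


def montecarlo_nonstationarity_test(X, y, locations, q, n_perm: int = 99,
                                    seed: int = 0, *, kernel="gaussian") -> NonstationarityTest:
    """Monte-Carlo randomisation test of coefficient non-stationarity.

    Locations are randomly reassigned to observations; the GWR is refit at
    the same q and the variability of each local coefficient surface is
    recomputed. p = (1 + #{perm stat >= observed}) / (n_perm + 1).
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    locs = np.asarray(locations, dtype=float)
    rng = np.random.default_rng(seed)
    model = fit_gwr(X, y, locs, q, kernel=kernel)
    var_obs, cv_obs = _coef_stats(model.local_coefficients)

    ge_var = np.zeros_like(var_obs)
    ge_cv = np.zeros_like(cv_obs)
    for _ in range(n_perm):
        for attempt in range(4):
            perm = rng.permutation(locs.shape[0])
            try:
                m = fit_gwr(X, y, locs[perm], q, kernel=kernel)
                break
            except (np.linalg.LinAlgError, ValueError):
                if attempt == 3:
                    raise
        var_p, cv_p = _coef_stats(m.local_coefficients)
        ge_var += var_p >= var_obs
        ge_cv += cv_p >= cv_obs
    return NonstationarityTest(
        variance=var_obs,
        cv=cv_obs,
        p_variance=(1.0 + ge_var) / (n_perm + 1.0),
        p_cv=(1.0 + ge_cv) / (n_perm + 1.0),
        n_perm=n_perm,
    )
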