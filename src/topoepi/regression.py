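"""Mortality–topography association: Pearson correlation and
geographically weighted regression (GWR).

GWR replaces the single global slope of an ordinary regression with a
slope surface: at each village location a weighted least-squares fit is
computed with kernel weights that decay over geographic distance, so
the coefficient of (say) VDC can strengthen inside a basin and fade on
the ridges. The default kernel is adaptive bisquare — the bandwidth is
the distance to the k-th nearest village, so dense areas get tight
kernels and sparse areas wide ones:

    w_ij = (1 - (d_ij / b_i)^2)^2   for d_ij < b_i, else 0.

A fixed Gaussian kernel (w = exp(-d²/2b²)) is also available. The
bandwidth (k for adaptive, a distance for fixed) is chosen by
golden-section search on the corrected Akaike criterion

    AICc = 2n ln σ̂ + n ln 2π + n (n + tr(S)) / (n - 2 - tr(S)),

where S is the hat matrix mapping y to fitted values and tr(S) the
effective number of parameters. Covariates are z-standardised before
fitting to stabilise the search; reported coefficients are
back-transformed to the raw scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from topoepi.errors import ConfigError, DataError, NumericalError

KERNELS = ("adaptive_bisquare", "fixed_gaussian")


@dataclass
class CorrelationResult:
    """Pearson correlation with its two-sided t-test p-value."""

    r: float
    p_value: float
    n: int
    label: str = ""


def pearson_correlation(a, b, label: str = "") -> CorrelationResult:
    """Sample Pearson correlation between two paired vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DataError("inputs must be 1-D and paired")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if len(a) < 3:
        raise DataError("correlation needs at least 3 finite pairs")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise NumericalError("correlation undefined for a constant input")
    res = stats.pearsonr(a, b)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(a), label)


@dataclass
class GWRResult:
    """Local coefficient surfaces plus global fit diagnostics.

    ``local`` is a DataFrame (one row per observation) with raw-scale
    ``intercept`` and one column per covariate, plus ``fitted``,
    ``residual``, ``std_residual``, ``leverage`` and ``local_r2``.
    """

    local: pd.DataFrame
    r2: float
    adj_r2: float
    aicc: float
    bandwidth: float
    kernel: str
    enp: float
    sigma2: float
    n: int
    covariates: list[str] = field(default_factory=list)


def _distance_matrix(coords: np.ndarray) -> np.ndarray:
    d = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((d**2).sum(axis=2))


def _kernel_weights(dist: np.ndarray, kernel: str, bandwidth: float) -> np.ndarray:
    """(n_loc, n_obs) weight matrix; bandwidth=inf means uniform weights."""
    if kernel == "adaptive_bisquare":
        if not math.isfinite(bandwidth):
            return np.ones_like(dist)
        k = int(round(bandwidth))
        n = dist.shape[1]
        if k < 2:
            raise ConfigError("adaptive bandwidth must be at least 2 neighbours")
        k = min(k, n)
        # distance to the k-th nearest observation (self included at d=0)
        b = np.sort(dist, axis=1)[:, k - 1]
        b = np.maximum(b, 1e-12)
        u = dist / b[:, None]
        w = np.where(u < 1.0, (1.0 - u**2) ** 2, 0.0)
        return w
    if kernel == "fixed_gaussian":
        if not math.isfinite(bandwidth):
            return np.ones_like(dist)
        if bandwidth <= 0:
            raise ConfigError("fixed bandwidth must be positive")
        return np.exp(-0.5 * (dist / bandwidth) ** 2)
    raise ConfigError(f"unknown kernel {kernel!r}; use one of {KERNELS}")


def _prepare(y, X, coords):
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    coords = np.asarray(coords, dtype=float)
    n = len(y)
    if X.shape[0] != n or coords.shape != (n, 2):
        raise DataError("y, X and coords must have matching lengths")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(X)) and np.all(np.isfinite(coords))):
        raise DataError("GWR inputs must be finite")
    return y, X, coords


def fit_gwr(
    y,
    X,
    coords,
    kernel: str = "adaptive_bisquare",
    bandwidth: float | None = None,
    covariate_names: list[str] | None = None,
    standardize: bool = True,
) -> GWRResult:
    """Fit a GWR model at every observation location.

    Parameters
    ----------
    y : (n,) response (e.g. smoothed mortality rate per 100 000).
    X : (n, p) covariates WITHOUT an intercept column (added here).
        p = 0 (an empty array) fits the intercept-only model.
    coords : (n, 2) projected coordinates in meters.
    kernel : "adaptive_bisquare" (bandwidth = neighbour count) or
        "fixed_gaussian" (bandwidth = distance in meters).
    bandwidth : kernel bandwidth; ``np.inf`` gives uniform weights and
        reproduces the global least-squares fit.
    """
    y, X, coords = _prepare(y, X, coords)
    n, p = X.shape
    if bandwidth is None:
        raise ConfigError("bandwidth is required; use select_bandwidth()")
    if covariate_names is None:
        covariate_names = [f"x{j + 1}" for j in range(p)]
    if len(covariate_names) != p:
        raise ConfigError("covariate_names length must match X columns")

    if standardize and p > 0:
        mu, sd = X.mean(axis=0), X.std(axis=0, ddof=0)
        if np.any(sd == 0):
            bad = [covariate_names[j] for j in np.flatnonzero(sd == 0)]
            raise DataError(f"constant covariate(s): {bad}")
        Xs = (X - mu) / sd
    else:
        mu, sd = np.zeros(p), np.ones(p)
        Xs = X

    Xd = np.column_stack([np.ones(n), Xs])
    dist = _distance_matrix(coords)
    W = _kernel_weights(dist, kernel, bandwidth)

    # batched weighted least squares: A_m = X' diag(W_m) X, b_m = X' W_m y
    A = np.einsum("nj,mn,nk->mjk", Xd, W, Xd)
    rhs = np.einsum("nj,mn,n->mj", Xd, W, y)
    try:
        beta = np.linalg.solve(A, rhs[:, :, None])[:, :, 0]
    except np.linalg.LinAlgError:
        sing = [m for m in range(n) if np.linalg.matrix_rank(A[m]) < p + 1]
        raise NumericalError(
            f"singular local design at location(s) {sing[:5]} — "
            "bandwidth too small for the local sample"
        ) from None
    fitted = np.einsum("mj,mj->m", Xd, beta)
    resid = y - fitted
    # hat-matrix diagonal: S_mm = W_mm * x_m' A_m^{-1} x_m
    Ainv_x = np.linalg.solve(A, Xd[:, :, None])[:, :, 0]
    leverage = np.einsum("mj,mj->m", Xd, Ainv_x) * np.diag(W)
    tr_s = float(leverage.sum())

    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - tr_s) if n > tr_s else float("nan")
    sigma2_ml = rss / n
    if n - 2 - tr_s <= 0:
        raise NumericalError("effective parameters too large for AICc (n - 2 - tr(S) <= 0)")
    aicc = (
        n * math.log(max(sigma2_ml, 1e-300))
        + n * math.log(2 * math.pi)
        + n * (n + tr_s) / (n - 2 - tr_s)
    )
    dof = max(n - tr_s, 1e-12)
    sigma2 = rss / dof
    scale = max(float(np.abs(y).max()), 1.0)
    if sigma2 <= (1e-10 * scale) ** 2:  # numerically exact fit
        std_resid = np.zeros(n)
    else:
        denom = np.sqrt(np.clip(1.0 - leverage, 1e-12, None)) * math.sqrt(sigma2)
        std_resid = resid / denom

    # local weighted R² around each regression point
    wsum = W.sum(axis=1)
    ybar_local = (W @ y) / wsum
    ss_res_local = W @ (resid**2)
    ss_tot_local = np.einsum("mn,mn->m", W, (y[None, :] - ybar_local[:, None]) ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        local_r2 = np.where(ss_tot_local > 0, 1.0 - ss_res_local / ss_tot_local, np.nan)

    # back-transform standardised coefficients to raw scale
    slopes_raw = beta[:, 1:] / sd[None, :] if p > 0 else beta[:, 1:]
    intercept_raw = beta[:, 0] - (slopes_raw * mu[None, :]).sum(axis=1)
    local = pd.DataFrame({"intercept": intercept_raw})
    for j, name in enumerate(covariate_names):
        local[name] = slopes_raw[:, j]
    local["fitted"] = fitted
    local["residual"] = resid
    local["std_residual"] = std_resid
    local["leverage"] = leverage
    local["local_r2"] = local_r2

    return GWRResult(
        local=local,
        r2=r2,
        adj_r2=adj_r2,
        aicc=aicc,
        bandwidth=float(bandwidth),
        kernel=kernel,
        enp=tr_s,
        sigma2=sigma2,
        n=n,
        covariates=list(covariate_names),
    )


_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


def select_bandwidth(
    y,
    X,
    coords,
    kernel: str = "adaptive_bisquare",
    bounds: tuple[float, float] | None = None,
    tol: float = 1.0,
    standardize: bool = True,
) -> float:
    """Choose the bandwidth minimising AICc by golden-section search.

    For the adaptive kernel the search runs over the neighbour count
    (rounded to integers, default bounds [2(p+1)+2, n]); for the fixed
    kernel over distance (default bounds from the 5th percentile of
    pairwise distances to the domain diameter). Deterministic.
    """
    y, X, coords = _prepare(y, X, coords)
    n, p = X.shape
    if n < 20:
        raise DataError("bandwidth selection needs at least 20 observations")
    if bounds is None:
        if kernel == "adaptive_bisquare":
            bounds = (float(min(2 * (p + 1) + 2, n)), float(n))
        else:
            dist = _distance_matrix(coords)
            pos = dist[dist > 0]
            if pos.size == 0:
                raise DataError("coordinates are not distinct")
            bounds = (float(np.percentile(pos, 5)), float(pos.max()))
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ConfigError(f"invalid bandwidth bounds {bounds}")

    cache: dict[float, float] = {}

    def score(b: float) -> float:
        b_eval = float(round(b)) if kernel == "adaptive_bisquare" else float(b)
        if b_eval in cache:
            return cache[b_eval]
        try:
            aicc = fit_gwr(
                y, X, coords, kernel=kernel, bandwidth=b_eval,
                standardize=standardize,
            ).aicc
        except NumericalError:
            aicc = float("inf")
        cache[b_eval] = aicc
        return aicc

    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)
    if kernel == "adaptive_bisquare":
        tol = max(tol, 0.9)
    while b - a > tol:
        if score(c) <= score(d):
            b = d
        else:
            a = c
        c = b - _GOLDEN * (b - a)
        d = a + _GOLDEN * (b - a)
    candidates = [a, b, c, d, lo, hi]
    if kernel == "adaptive_bisquare":
        candidates = [float(round(v)) for v in candidates]
    best = min(candidates, key=score)
    if not math.isfinite(score(best)):
        raise NumericalError(
            "AICc was non-finite across the whole bandwidth search range; "
            "try wider bounds"
        )
    return best


def stdresid_coverage(gwr: GWRResult, bounds: tuple[float, float] = (-2.0, 2.0)) -> float:
    """Fraction of observations with standardised residual inside the
    closed interval ``bounds``."""
    lo, hi = bounds
    sr = gwr.local["std_residual"].to_numpy()
    return float(np.mean((sr >= lo) & (sr <= hi)))


def compare_models(
    y,
    covariates: pd.DataFrame,
    coords,
    variants: list[list[str]] | None = None,
    kernel: str = "adaptive_bisquare",
    bounds: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Fit GWR variants on identical observations and rank them by AICc.

    ``variants`` defaults to the three terrain models: RDLS only,
    VDC only, and both. Returns one row per variant with AICc, R²,
    adjusted R² and the selected bandwidth, sorted by AICc ascending.
    """
    if variants is None:
        variants = [["RDLS"], ["VDC"], ["RDLS", "VDC"]]
    rows = []
    results = {}
    for cols in variants:
        missing = [c for c in cols if c not in covariates.columns]
        if missing:
            raise ConfigError(f"variant {cols} references missing covariates {missing}")
        X = covariates[cols].to_numpy(dtype=float)
        bw = select_bandwidth(y, X, coords, kernel=kernel, bounds=bounds)
        fit = fit_gwr(y, X, coords, kernel=kernel, bandwidth=bw, covariate_names=cols)
        name = "+".join(cols)
        results[name] = fit
        rows.append(
            {
                "model": name,
                "aicc": fit.aicc,
                "r2": fit.r2,
                "adj_r2": fit.adj_r2,
                "bandwidth": fit.bandwidth,
                "enp": fit.enp,
            }
        )
    table = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    table.attrs["fits"] = results
    return table
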