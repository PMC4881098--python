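"""Spatial weights, global Moran's I, and local Getis-Ord Gi* hotspots.

Contiguity weights are binary (1 when two village polygons are
adjacent, 0 otherwise) and deliberately *not* row-standardised: the
statistics below are evaluated exactly as defined on the raw 0/1
matrix.

Global Moran's I over attributes x with weights ω:

    I = N · Σ_i Σ_j ω_ij (x_i − x̄)(x_j − x̄)
        ───────────────────────────────────────
        (Σ_i Σ_j ω_ij) · Σ_i (x_i − x̄)²

Inference is by random permutation of the attribute over the villages
(default, 999 draws) or by the analytic randomisation-moments normal
approximation.

Local Getis-Ord Gi* per village i (weights include the village itself):

    Gi* = [Σ_j ω_ij x_j − X̄ Σ_j ω_ij] /
          (S · sqrt([n Σ_j ω_ij² − (Σ_j ω_ij)²] / (n − 1)))

with X̄ = Σ x_j / n and S = sqrt(Σ x_j²/n − X̄²). Gi* is already a
z-score; villages are classed hot/cold at the 95% (|z| ≥ 1.960) and
99% (|z| ≥ 2.576) two-sided normal thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from shapely import STRtree

from topoepi.errors import ConfigError, DataError, NumericalError
from topoepi.villages import VillageSet

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054
Z99 = 2.5758293035489004

HOT99, HOT95, NS, COLD95, COLD99 = "hot99", "hot95", "ns", "cold95", "cold99"


@dataclass
class SpatialWeights:
    """Binary contiguity matrix over an ordered village list."""

    ids: list[str]
    matrix: np.ndarray
    rule: str = "queen"
    include_self: bool = False

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise DataError("weights matrix shape does not match ids")
        if len(set(self.ids)) != n:
            raise DataError("duplicate ids in spatial weights")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise DataError("weights matrix must be symmetric")
        if not np.isin(self.matrix, (0.0, 1.0)).all():
            raise DataError("weights must be binary")
        diag = np.diag(self.matrix)
        if self.include_self and not np.all(diag == 1):
            raise DataError("include_self weights must have unit diagonal")
        if not self.include_self and np.any(diag != 0):
            raise DataError("diagonal must be zero unless include_self")

    def __len__(self) -> int:
        return len(self.ids)

    def with_self(self) -> "SpatialWeights":
        """Copy with ones on the diagonal (the Gi* convention)."""
        if self.include_self:
            return self
        m = self.matrix.copy()
        np.fill_diagonal(m, 1.0)
        return SpatialWeights(list(self.ids), m, rule=self.rule, include_self=True)

    def subset(self, keep_ids) -> "SpatialWeights":
        pos = {vid: k for k, vid in enumerate(self.ids)}
        missing = [v for v in keep_ids for _ in (1,) if v not in pos]
        if missing:
            raise DataError(f"ids not in weights: {sorted(set(missing))}")
        idx = np.array([pos[v] for v in keep_ids])
        return SpatialWeights(
            list(keep_ids),
            self.matrix[np.ix_(idx, idx)],
            rule=self.rule,
            include_self=self.include_self,
        )

    @property
    def n_neighbors(self) -> np.ndarray:
        off = self.matrix.copy()
        np.fill_diagonal(off, 0.0)
        return off.sum(axis=1).astype(int)


def build_contiguity_weights(
    villages: VillageSet, rule: str = "queen", include_self: bool = False
) -> SpatialWeights:
    """Polygon-contiguity weights: queen (any shared boundary point) or
    rook (shared boundary segment of positive length).

    Islands (villages touching nothing) are allowed and logged.
    """
    if rule not in ("queen", "rook"):
        raise ConfigError(f"rule must be 'queen' or 'rook', got {rule!r}")
    n = len(villages)
    geoms = villages.geometries
    matrix = np.zeros((n, n))
    tree = STRtree(geoms)
    for i in range(n):
        for j in tree.query(geoms[i], predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            inter = geoms[i].intersection(geoms[j])
            if inter.is_empty:
                continue
            touch = inter.length > 0 if rule == "rook" else True
            if touch:
                matrix[i, j] = matrix[j, i] = 1.0
    if include_self:
        np.fill_diagonal(matrix, 1.0)
    w = SpatialWeights(list(villages.ids), matrix, rule=rule, include_self=include_self)
    islands = [vid for vid, k in zip(w.ids, w.n_neighbors) if k == 0]
    if islands:
        logger.warning("island villages with no neighbours: %s", ", ".join(islands))
    return w


def _check_attribute(x: np.ndarray, weights: SpatialWeights) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) != len(weights):
        raise DataError("attribute length does not match weights")
    if not np.all(np.isfinite(x)):
        raise DataError("attribute contains non-finite values")
    return x


def morans_i(x, weights: SpatialWeights) -> float:
    """Global Moran's I of x under binary weights (exact evaluation)."""
    x = _check_attribute(x, weights)
    n = len(x)
    if n < 3:
        raise DataError("Moran's I needs at least 3 villages")
    w = weights.matrix
    s0 = w.sum()
    if s0 <= 0:
        raise DataError("weights matrix has no links")
    z = x - x.mean()
    denom = np.sum(z**2)
    if denom == 0:
        raise NumericalError("Moran's I undefined for a constant attribute")
    return float(n * z @ w @ z / (s0 * denom))


def _moran_randomization_moments(x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Mean and variance of I under the randomisation null."""
    n = len(x)
    s0 = w.sum()
    s1 = 0.5 * np.sum((w + w.T) ** 2)
    s2 = np.sum((w.sum(axis=1) + w.sum(axis=0)) ** 2)
    z = x - x.mean()
    m2 = np.mean(z**2)
    m4 = np.mean(z**4)
    b2 = m4 / m2**2
    e_i = -1.0 / (n - 1)
    num = n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2) - b2 * (
        (n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2
    )
    var = num / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
    return e_i, var


@dataclass
class MoranResult:
    """Moran's I with permutation or analytic inference."""

    I: float
    z_score: float
    p_value: float
    method: str
    n_perm: int = 0
    seed: int | None = None
    alternative: str = "two-sided"
    perm_mean: float = float("nan")
    perm_sd: float = float("nan")


def morans_i_inference(
    x,
    weights: SpatialWeights,
    method: str = "permutation",
    n_perm: int = 999,
    seed: int | None = None,
    alternative: str = "two-sided",
) -> MoranResult:
    """Moran's I with a permutation test (default) or the analytic
    randomisation-moments normal approximation.

    Permutation p-values carry the +1 correction (they are never 0):
    the tail count in the direction of the observed deviation is
    (1 + #{I_perm at least as extreme}) / (n_perm + 1), doubled and
    capped at 1 for the default two-sided alternative.
    """
    x = _check_attribute(x, weights)
    obs = morans_i(x, weights)
    w = weights.matrix
    if method == "analytic":
        e_i, var = _moran_randomization_moments(x, w)
        z = (obs - e_i) / np.sqrt(var)
        if alternative == "two-sided":
            p = 2 * stats.norm.sf(abs(z))
        elif alternative == "greater":
            p = stats.norm.sf(z)
        else:
            p = stats.norm.cdf(z)
        return MoranResult(obs, float(z), float(min(p, 1.0)), "analytic",
                           alternative=alternative)
    if method != "permutation":
        raise ConfigError(f"unknown inference method {method!r}")
    if n_perm < 99:
        logger.warning("n_perm=%d is very small; p-values will be coarse", n_perm)
    rng = np.random.default_rng(seed)
    n = len(x)
    s0 = w.sum()
    # vectorised: permute centred values, evaluate I over the edge list
    ii, jj = np.nonzero(w)
    perms = rng.permuted(np.broadcast_to(x, (n_perm, n)), axis=1)
    zc = perms - x.mean()
    denom = np.sum(zc**2, axis=1)
    i_perm = n * np.sum(zc[:, ii] * zc[:, jj], axis=1) / (s0 * denom)
    mean, sd = float(i_perm.mean()), float(i_perm.std(ddof=0))
    z = (obs - mean) / sd if sd > 0 else np.inf * np.sign(obs - mean)
    if obs >= mean:
        tail = (1 + np.sum(i_perm >= obs)) / (n_perm + 1)
    else:
        tail = (1 + np.sum(i_perm <= obs)) / (n_perm + 1)
    if alternative == "two-sided":
        p = min(1.0, 2 * tail)
    elif alternative == "greater":
        p = (1 + np.sum(i_perm >= obs)) / (n_perm + 1)
    elif alternative == "less":
        p = (1 + np.sum(i_perm <= obs)) / (n_perm + 1)
    else:
        raise ConfigError(f"unknown alternative {alternative!r}")
    return MoranResult(
        obs, float(z), float(p), "permutation", n_perm=n_perm, seed=seed,
        alternative=alternative, perm_mean=mean, perm_sd=sd,
    )


def gi_star(x, weights: SpatialWeights) -> pd.DataFrame:
    """Local Getis-Ord Gi* per village (a z-score) with two-sided
    normal p-values.

    Weights are forced to include the focal village itself — the
    defining feature of the starred statistic.
    """
    weights = weights.with_self()
    x = _check_attribute(x, weights)
    n = len(x)
    if n < 3:
        raise DataError("Gi* needs at least 3 villages")
    xbar = x.mean()
    s = np.sqrt(np.mean(x**2) - xbar**2)
    if s == 0:
        raise NumericalError("Gi* undefined for a constant attribute")
    w = weights.matrix
    wsum = w.sum(axis=1)
    wsq = (w**2).sum(axis=1)
    num = w @ x - xbar * wsum
    den = s * np.sqrt((n * wsq - wsum**2) / (n - 1))
    if np.any(den == 0):
        raise NumericalError("Gi* denominator is zero (village connected to all)")
    z = num / den
    p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"z": z, "p_value": p}, index=pd.Index(weights.ids, name="village_id"))


# GiStarTable is a per-village DataFrame with columns z, p_value (and,
# after classify_hotspots, hotspot).
GiStarTable = pd.DataFrame


def classify_hotspots(gi: pd.DataFrame, z95: float = Z95, z99: float = Z99) -> pd.DataFrame:
    """Add the five-way hotspot class from the Gi* z-scores."""
    out = gi.copy()
    z = out["z"].to_numpy()
    cls = np.full(len(z), NS, dtype=object)
    cls[z >= z95] = HOT95
    cls[z >= z99] = HOT99
    cls[z <= -z95] = COLD95
    cls[z <= -z99] = COLD99
    out["hotspot"] = cls
    return out


def persistent_hotspots(tables: list[pd.DataFrame]) -> list[str]:
    """Villages classified hot (95% or 99%) in *every* period.

    All tables must cover the same village set.
    """
    if len(tables) < 2:
        raise DataError("persistent hotspots need at least 2 periods")
    base = set(tables[0].index)
    for k, t in enumerate(tables[1:], start=2):
        if set(t.index) != base:
            diff = sorted(base.symmetric_difference(set(t.index)))
            raise DataError(f"period {k} village set differs from period 1: {diff}")
    hot_sets = []
    for t in tables:
        if "hotspot" not in t.columns:
            t = classify_hotspots(t)
        hot_sets.append({vid for vid, c in t["hotspot"].items() if c in (HOT95, HOT99)})
    persistent = set.intersection(*hot_sets)
    return sorted(persistent, key=lambda v: list(tables[0].index).index(v))
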