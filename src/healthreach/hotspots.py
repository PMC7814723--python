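"""Getis-Ord Gi* hotspot detection with higher-order queen contiguity.

Zonal (parish-level) mean travel times are screened for statistically
significant clusters of high values (low access, "hot") and low values (fast
access, "cold") with the Gi* local statistic, which includes the focal zone's
own value (w_ii = 1). Contiguity is queen's case; order-k weights are
cumulative — every zone within k adjacency steps. A zone counts as a cluster
at order k only if its pseudo p-value clears alpha at that order AND its
|z| exceeds its |z| at every lower order, so cluster scale must grow with
order (the monotone multi-order rule). Significance uses conditional
permutation: the focal value is held fixed while the remaining values are
reassigned among the other zones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpatialWeights",
    "GiStarResult",
    "queen_weights",
    "queen_weights_from_labels",
    "queen_weights_from_polygons",
    "gi_star",
    "permutation_p",
    "multi_order_clusters",
    "zonal_mean",
]


@dataclass
class SpatialWeights:
    """Binary symmetric contiguity at cumulative orders 1..max_order.

    ``adjacency[k]`` is an (n, n) boolean matrix of order-k neighbors
    (self excluded); order-k sets contain order-(k−1) sets. ``active`` marks
    zones usable for inference (zones isolated at order 1 are excluded).
    """

    ids: np.ndarray
    adjacency: dict[int, np.ndarray]
    active: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def neighbors(self, order: int):
        """Per-zone neighbor index lists at cumulative ``order``."""
        A = self.adjacency[order]
        return [np.nonzero(A[i])[0] for i in range(self.n)]


def _cumulative_orders(A1: np.ndarray, max_order: int) -> dict[int, np.ndarray]:
    orders = {1: A1.copy()}
    reach = A1.copy()
    for k in range(2, max_order + 1):
        reach = reach | (reach @ A1)
        Ak = reach.copy()
        np.fill_diagonal(Ak, False)
        orders[k] = Ak
    return orders


def _finish(ids, A1, max_order):
    np.fill_diagonal(A1, False)
    A1 |= A1.T  # enforce symmetry
    active = A1.any(axis=1)
    if not active.all():
        warnings.warn(
            f"{int((~active).sum())} zone(s) have no order-1 neighbor; excluded from inference",
            stacklevel=3,
        )
    return SpatialWeights(ids=np.asarray(ids), adjacency=_cumulative_orders(A1, max_order), active=active)


def queen_weights_from_labels(labels: np.ndarray, max_order: int = 3) -> SpatialWeights:
    """Queen contiguity from a zone-label raster.

    Two zones are order-1 neighbors when any two of their cells touch at an
    edge or a corner (8-neighborhood), i.e. the zones share at least a
    boundary point.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels[labels >= 0])
    index = {int(v): i for i, v in enumerate(ids)}
    n = len(ids)
    A1 = np.zeros((n, n), dtype=bool)
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        if dc >= 0:
            a = labels[: labels.shape[0] - dr, : labels.shape[1] - dc]
            b = labels[dr:, dc:]
        else:
            a = labels[: labels.shape[0] - dr, -dc:]
            b = labels[dr:, : labels.shape[1] + dc]
        ok = (a >= 0) & (b >= 0) & (a != b)
        pairs = np.unique(np.stack([a[ok], b[ok]], axis=1), axis=0) if ok.any() else []
        for u, v in pairs:
            A1[index[int(u)], index[int(v)]] = True
    return _finish(ids, A1, max_order)


def queen_weights_from_polygons(polygons, ids=None, max_order: int = 3) -> SpatialWeights:
    """Queen contiguity from non-overlapping shapely polygons."""
    from shapely.strtree import STRtree

    polys = list(polygons)
    if ids is None:
        ids = np.arange(len(polys))
    n = len(polys)
    A1 = np.zeros((n, n), dtype=bool)
    tree = STRtree(polys)
    for i, g in enumerate(polys):
        for j in tree.query(g, predicate="intersects"):
            if int(j) != i:
                A1[i, int(j)] = True
    return _finish(ids, A1, max_order)


def queen_weights(zones, max_order: int = 3) -> SpatialWeights:
    """Dispatch: a label raster (2-D int array) or a sequence of polygons."""
    if isinstance(zones, np.ndarray) and zones.ndim == 2:
        return queen_weights_from_labels(zones, max_order)
    return queen_weights_from_polygons(zones, max_order=max_order)


def _gi_star_parts(x: np.ndarray, A: np.ndarray, active: np.ndarray):
    """Numerator pieces and denominator of the standardized Gi* statistic."""
    n = int(active.sum())
    if n < 3:
        raise ValueError("need at least 3 active zones")
    xa = x[active]
    xbar = xa.mean()
    s = xa.std()  # population standard deviation, per the Gi* formula
    if s == 0:
        raise ValueError("zero variance: Gi* undefined for constant values")
    Aa = A[np.ix_(active, active)]
    Wi = Aa.sum(axis=1) + 1.0  # +1: the self term, w_ii = 1
    lag = Aa @ xa + xa  # Σ_j w_ij x_j including j = i
    # Wi == n: the neighborhood covers the whole study area and Gi* is
    # undefined (zero denominator); such zones come back NaN
    denom = s * np.sqrt((n * Wi - Wi**2) / (n - 1))
    denom[denom == 0] = np.nan
    return xa, xbar, Wi, lag, denom


def gi_star(values: np.ndarray, weights: SpatialWeights, order: int = 1) -> np.ndarray:
    """Standardized Gi* z-value per zone (NaN for excluded zones)."""
    x = np.asarray(values, dtype=float)
    if x.shape[0] != weights.n:
        raise ValueError("values length does not match number of zones")
    active = weights.active & np.isfinite(x)
    xa, xbar, Wi, lag, denom = _gi_star_parts(x, weights.adjacency[order], active)
    z = np.full(weights.n, np.nan)
    z[active] = (lag - xbar * Wi) / denom
    return z


def _perm_pvalues(x, A, active, n_perm, rng, shared_sorted=None):
    """Conditional-permutation pseudo p-values for one contiguity order.

    For zone i the observed value stays put; the remaining values are
    reassigned at random among the other zones. Because the value multiset is
    unchanged, the global mean/std and the denominator are permutation
    invariant, so only the numerator needs resampling: x_i plus the sum of
    k_i values drawn without replacement from the others.
    """
    xa, xbar, Wi, lag, denom = _gi_star_parts(x, A, active)
    z_obs = (lag - xbar * Wi) / denom
    n = len(xa)
    if shared_sorted is None:
        keys = rng.random((n_perm, n - 1))
        shared_sorted = np.argsort(keys, axis=1)
    p = np.full(len(active), np.nan)
    act_idx = np.nonzero(active)[0]
    for ii, i in enumerate(act_idx):
        k = int(Wi[ii] - 1)  # neighbors excluding self
        if k <= 0:
            continue
        others = np.delete(xa, ii)
        sums = others[shared_sorted[:, :k]].sum(axis=1)
        num_perm = xa[ii] + sums - xbar * Wi[ii]
        num_obs = lag[ii] - xbar * Wi[ii]
        extreme = np.abs(num_perm) >= np.abs(num_obs) - 1e-12 * max(1.0, abs(num_obs))
        p[i] = (1.0 + int(extreme.sum())) / (1.0 + n_perm)
    return z_obs, p, shared_sorted


def permutation_p(
    values: np.ndarray,
    weights: SpatialWeights,
    order: int = 1,
    n_perm: int = 9999,
    seed: int = 0,
) -> np.ndarray:
    """Pseudo p-value per zone: (1 + #{|z*| ≥ |z|}) / (1 + n_perm)."""
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")
    x = np.asarray(values, dtype=float)
    active = weights.active & np.isfinite(x)
    rng = np.random.default_rng(seed)
    _, p, _ = _perm_pvalues(x, weights.adjacency[order], active, n_perm, rng)
    return p


@dataclass
class GiStarResult:
    """Per-zone Gi* z, pseudo p and cluster label for each contiguity order.

    ``z`` and ``p`` are (orders, n); ``label`` entries are "high", "low" or
    "none"; ``order`` is the highest order at which the monotone rule holds
    (0 = never significant). ``cluster`` is the label at that order.
    """

    ids: np.ndarray
    orders: tuple[int, ...]
    z: np.ndarray
    p: np.ndarray
    label: np.ndarray  # (orders, n) str
    order: np.ndarray  # (n,) int
    cluster: np.ndarray  # (n,) str
    alpha: float


def multi_order_clusters(
    values: np.ndarray,
    weights: SpatialWeights,
    alpha: float = 0.001,
    n_perm: int = 9999,
    seed: int = 0,
) -> GiStarResult:
    """Gi* clusters under the monotone multi-order rule.

    A zone is labeled at order k iff p_k ≤ alpha and |z_k| > |z_j| for every
    lower order j; its reported order is the highest k satisfying the rule.
    """
    if n_perm < 999:
        raise ValueError("n_perm must be at least 999")
    x = np.asarray(values, dtype=float)
    active = weights.active & np.isfinite(x)
    orders = tuple(sorted(weights.adjacency))
    rng = np.random.default_rng(seed)
    n = weights.n
    Z = np.full((len(orders), n), np.nan)
    P = np.full((len(orders), n), np.nan)
    shared = None
    for oi, k in enumerate(orders):
        z_a, p, shared = _perm_pvalues(x, weights.adjacency[k], active, n_perm, rng, shared)
        z = np.full(n, np.nan)
        z[active] = z_a
        Z[oi] = z
        P[oi] = p
    label = np.full((len(orders), n), "none", dtype=object)
    best_order = np.zeros(n, dtype=int)
    cluster = np.full(n, "none", dtype=object)
    for oi, k in enumerate(orders):
        sig = (P[oi] <= alpha) & np.isfinite(Z[oi])
        if oi > 0:
            prev = np.abs(Z[:oi])
            prev_max = np.max(np.where(np.isnan(prev), -np.inf, prev), axis=0)
            sig &= np.abs(Z[oi]) > prev_max
        hi = sig & (Z[oi] > 0)
        lo = sig & (Z[oi] < 0)
        label[oi][hi] = "high"
        label[oi][lo] = "low"
        best_order[sig] = k
        cluster[hi] = "high"
        cluster[lo] = "low"
    return GiStarResult(
        ids=weights.ids,
        orders=orders,
        z=Z,
        p=P,
        label=label,
        order=best_order,
        cluster=cluster,
        alpha=alpha,
    )


def zonal_mean(minutes: np.ndarray, labels: np.ndarray, ids=None) -> np.ndarray:
    """Unweighted mean of finite cell minutes per zone (NaN if none)."""
    minutes = np.asarray(minutes, dtype=float)
    labels = np.asarray(labels)
    if minutes.shape != labels.shape:
        raise ValueError("raster and label shapes differ")
    if ids is None:
        ids = np.unique(labels[labels >= 0])
    out = np.full(len(ids), np.nan)
    finite = np.isfinite(minutes)
    for i, zid in enumerate(ids):
        sel = (labels == zid) & finite
        if not sel.any():
            warnings.warn(f"zone {zid} has no finite travel-time cell; zonal mean missing",
                          stacklevel=2)
            continue
        out[i] = minutes[sel].mean()
    return out
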