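"""Travel-time surfaces: minutes to the nearest eligible facility.

The accessibility surface is the exact multi-source shortest path over the
friction surface on the 8-connected grid graph. Moving between adjacent cells
costs the time to cross half of each cell at that cell's own speed:

    t(a, b) = (d/2) / v_a + (d/2) / v_b

with ``d`` the center-to-center distance (cell size, or cell size × √2 on a
diagonal). This half-cell-at-each-speed rule is symmetric and matches the
conventions of raster cost-distance tools.

Facility tiers form a strict hierarchy (HC II < HC III < HC IV < General
Hospital < Regional Referral < National Referral); the analysis for level L
admits every facility of tier ≥ L, because any service offered at level L is
also offered above it.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .friction import FrictionSurface
from .grids import GridSpec

__all__ = [
    "Tier",
    "FacilitySet",
    "TravelTimeSurface",
    "eligible_facilities",
    "snap_to_passable",
    "compute_travel_time",
    "time_saved",
]


class Tier(enum.IntEnum):
    """Facility levels, ordered from lowest to highest service tier."""

    HC2 = 1
    HC3 = 2
    HC4 = 3
    GH = 4
    RRH = 5
    NRH = 6


@dataclass
class FacilitySet:
    """Facility point locations with their service tier."""

    xy: np.ndarray  # (n, 2) planar coordinates, meters
    tier: np.ndarray  # (n,) of Tier / int

    def __post_init__(self):
        self.xy = np.atleast_2d(np.asarray(self.xy, dtype=float))
        self.tier = np.asarray([Tier(int(t)) for t in np.atleast_1d(self.tier)])
        if self.xy.shape[0] != self.tier.shape[0]:
            raise ValueError("xy and tier lengths differ")

    def __len__(self) -> int:
        return self.xy.shape[0]

    def counts_by_tier(self) -> dict[Tier, int]:
        return {t: int(np.sum(self.tier == t)) for t in Tier}


@dataclass
class TravelTimeSurface:
    """Minutes to the nearest eligible facility; unreachable cells are +inf."""

    grid: GridSpec
    minutes: np.ndarray
    level: Tier
    mode: str
    multiplier: float

    def __post_init__(self):
        self.minutes = np.asarray(self.minutes, dtype=float)
        if self.minutes.shape != self.grid.shape:
            raise ValueError("minutes shape does not match grid")

    @property
    def provenance(self) -> tuple:
        return (Tier(self.level), self.mode, self.multiplier)


def eligible_facilities(facilities: FacilitySet, level: Tier) -> FacilitySet:
    """Facilities admissible for a level-``level`` analysis: tier ≥ level."""
    level = Tier(level)
    keep = facilities.tier >= level
    return FacilitySet(xy=facilities.xy[keep], tier=facilities.tier[keep])


def snap_to_passable(friction: FrictionSurface, xy: np.ndarray, radius: int = 3):
    """Snap points to the nearest passable cell within ``radius`` cells.

    Returns flat cell indices of the snapped cells. Points already on a
    passable cell stay put; a point with no passable cell within the square
    search window of half-width ``radius`` raises.
    """
    grid = friction.grid
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    rows, cols = grid.xy_to_rowcol(xy[:, 0], xy[:, 1])
    out = np.empty(len(xy), dtype=np.int64)
    for i, (r, c) in enumerate(zip(np.atleast_1d(rows), np.atleast_1d(cols))):
        if friction.passable[r, c]:
            out[i] = r * grid.ncols + c
            continue
        r0, r1 = max(0, r - radius), min(grid.nrows, r + radius + 1)
        c0, c1 = max(0, c - radius), min(grid.ncols, c + radius + 1)
        window = friction.passable[r0:r1, c0:c1]
        if not window.any():
            raise ValueError(
                f"facility at {tuple(xy[i])} has no passable cell within {radius} cells"
            )
        rr, cc = np.nonzero(window)
        d2 = (rr + r0 - r) ** 2 + (cc + c0 - c) ** 2
        j = int(np.argmin(d2))
        out[i] = (rr[j] + r0) * grid.ncols + (cc[j] + c0)
    return out


def _grid_graph(friction: FrictionSurface):
    """Sparse 8-connected graph with half-cell-at-each-speed minute costs."""
    grid = friction.grid
    speed = friction.speed
    passable = friction.passable
    n = grid.n_cells
    d_km = grid.cell_size / 1000.0
    idx = np.arange(n).reshape(grid.shape)
    rows_l, cols_l, costs = [], [], []
    # four unique forward offsets cover all 8 neighbors in an undirected graph
    for dr, dc, diag in ((0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True)):
        if dc >= 0:
            a = (slice(0, grid.nrows - dr), slice(0, grid.ncols - dc))
            b = (slice(dr, grid.nrows), slice(dc, grid.ncols))
        else:
            a = (slice(0, grid.nrows - dr), slice(-dc, grid.ncols))
            b = (slice(dr, grid.nrows), slice(0, grid.ncols + dc))
        ok = passable[a] & passable[b]
        if not ok.any():
            continue
        dist = d_km * (np.sqrt(2.0) if diag else 1.0)
        va = speed[a][ok]
        vb = speed[b][ok]
        t_min = 60.0 * (dist / 2.0) * (1.0 / va + 1.0 / vb)
        rows_l.append(idx[a][ok])
        cols_l.append(idx[b][ok])
        costs.append(t_min)
    if not rows_l:
        return coo_matrix((n, n)).tocsr()
    r = np.concatenate(rows_l)
    c = np.concatenate(cols_l)
    v = np.concatenate(costs)
    return coo_matrix((v, (r, c)), shape=(n, n)).tocsr()


def compute_travel_time(
    friction: FrictionSurface,
    sources: FacilitySet,
    level: Tier | None = None,
    snap_radius: int = 3,
) -> TravelTimeSurface:
    """Exact multi-source Dijkstra travel time in minutes.

    Every source cell has time 0; cells disconnected from all sources (or
    impassable) are +inf.
    """
    if len(sources) == 0:
        raise ValueError("empty source set")
    src = snap_to_passable(friction, sources.xy, radius=snap_radius)
    graph = _grid_graph(friction)
    minutes = dijkstra(graph, directed=False, indices=np.unique(src), min_only=True)
    minutes = minutes.reshape(friction.grid.shape)
    minutes[~friction.passable] = np.inf
    scenario = friction.scenario
    return TravelTimeSurface(
        grid=friction.grid,
        minutes=minutes,
        level=Tier(level) if level is not None else Tier(int(sources.tier.min())),
        mode=scenario.mode if scenario is not None else "walk",
        multiplier=scenario.multiplier if scenario is not None else 1.0,
    )


def time_saved(walk: TravelTimeSurface, bike: TravelTimeSurface) -> np.ndarray:
    """Cellwise minutes saved by bicycling instead of walking.

    Cells unreachable under both modes are NaN (no data); cells unreachable
    on foot but reachable by bicycle are +inf (a capped, flagged saving).
    """
    if walk.grid != bike.grid:
        raise ValueError("surfaces on different grids")
    if (walk.level, walk.multiplier) != (bike.level, bike.multiplier):
        raise ValueError(
            f"provenance mismatch: {walk.provenance} vs {bike.provenance}"
        )
    w, b = walk.minutes, bike.minutes
    with np.errstate(invalid="ignore"):  # inf - inf where neither mode reaches
        saved = np.where(np.isfinite(w) & np.isfinite(b), w - b, np.nan)
    saved = np.where(np.isinf(w) & np.isfinite(b), np.inf, saved)
    return saved
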