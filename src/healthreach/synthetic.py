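"""Synthetic landscapes with the statistical structure the analysis assumes.

Real inputs for a country-scale accessibility study — landcover, roads,
facility registries, gridded population, a poverty surface, administrative
boundaries — cannot be redistributed, so this module generates scenes that
emulate their joint structure:

* population concentrated in spatial clusters with a heavy-tailed (log-normal
  style) marginal;
* a smooth poverty surface in [0, 1] constructed to be *negatively*
  correlated with log population density (the rural poor);
* facilities placed with probability increasing in population density —
  more strongly for higher tiers — and decreasing in poverty, so access is
  genuinely worse in poor areas even conditional on density;
* roads connecting cluster centers (primary), towns to the primary network
  (secondary), and local fill (tertiary);
* protected-area barrier blobs;
* a parish/sub-region two-level administrative partition (Voronoi).

All randomness flows from one integer seed; no global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from scipy.special import expit, logit
from shapely.geometry import LineString, MultiPoint, Point, box
from shapely.ops import unary_union, voronoi_diagram

from .friction import LANDCOVER_CODES, rasterize_roads
from .grids import GridSpec
from .traveltime import FacilitySet, Tier

__all__ = ["SceneParams", "Zones", "SyntheticScene", "generate_parishes", "generate_scene"]


@dataclass(frozen=True)
class SceneParams:
    """Knobs of the synthetic landscape.

    Defaults are a scaled-down national scene: clustered settlement, a
    six-tier facility hierarchy with counts falling steeply with tier,
    poverty anti-correlated with density at −0.5, and ~5% of the area under
    protected-area barriers.
    """

    n_clusters: int = 12
    facility_counts: tuple[int, ...] = (40, 20, 8, 4, 2, 1)
    total_population: float = 1_000_000.0
    poverty_density_corr: float = -0.5
    mean_poverty: float = 0.35
    facility_poverty_bias: float = 5.0
    tier_density_power: tuple[float, ...] = (1.0, 1.2, 1.5, 1.8, 2.2, 2.5)
    road_density: float = 1.0
    barrier_fraction: float = 0.05
    n_parishes: int = 120
    n_subregions: int = 11

    def __post_init__(self):
        if len(self.facility_counts) != len(Tier):
            raise ValueError(f"facility_counts must have {len(Tier)} entries")
        if any(c <= 0 for c in self.facility_counts):
            raise ValueError("every tier needs at least one facility")
        if any(
            self.facility_counts[i] < self.facility_counts[i + 1]
            for i in range(len(self.facility_counts) - 1)
        ):
            raise ValueError("facility counts must be non-increasing with tier")
        if not 0 <= self.barrier_fraction < 1:
            raise ValueError("barrier_fraction must lie in [0, 1)")
        if not -1 < self.poverty_density_corr < 0:
            raise ValueError("poverty_density_corr must lie in (-1, 0)")
        if self.n_parishes < 4 or self.n_subregions < 2:
            raise ValueError("need at least 4 parishes and 2 subregions")
        if self.n_parishes < self.n_subregions:
            raise ValueError("need at least as many parishes as subregions")


@dataclass
class Zones:
    """A polygonal partition of the study area plus its raster labels."""

    labels: np.ndarray  # (nrows, ncols) int, zone index per cell
    polygons: list  # shapely polygons, index-aligned with ids
    ids: np.ndarray
    seeds: np.ndarray  # (k, 2) generating points


@dataclass
class SyntheticScene:
    """One synthetic study area; every downstream stage runs from this."""

    grid: GridSpec
    landcover: np.ndarray
    roads: list  # [(LineString, class)]
    barriers: list  # shapely polygons
    barrier_mask: np.ndarray
    population: np.ndarray
    poverty: np.ndarray
    facilities: FacilitySet
    parishes: Zones
    subregions: Zones
    subregion_of_parish: np.ndarray
    study_mask: np.ndarray
    params: SceneParams
    seed: int

    @cached_property
    def road_raster(self) -> np.ndarray:
        return rasterize_roads(self.roads, self.grid)

    @property
    def density(self) -> np.ndarray:
        """Population density, persons per km²."""
        return self.population / self.grid.cell_area_km2


def _standardize(a: np.ndarray) -> np.ndarray:
    return (a - a.mean()) / a.std()


def _smooth_field(rng, shape, sigma) -> np.ndarray:
    return _standardize(gaussian_filter(rng.standard_normal(shape), sigma=sigma))


def generate_parishes(seed: int, grid: GridSpec, k: int, rng=None) -> Zones:
    """Voronoi partition of the study rectangle into ``k`` zones.

    The contiguity graph of a Voronoi partition of a convex region is
    connected, and every zone has at least one neighbor for k ≥ 2.
    """
    if k < 4:
        raise ValueError("need at least 4 zones")
    if k > grid.n_cells:
        raise ValueError("more zones than grid cells")
    if rng is None:
        rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.extent
    seeds = np.column_stack(
        [rng.uniform(xmin, xmax, size=k), rng.uniform(ymin, ymax, size=k)]
    )
    # raster labels: nearest seed == Voronoi membership
    X, Y = grid.cell_centers()
    pts = np.column_stack([X.ravel(), Y.ravel()])
    labels = np.argmin(cdist(pts, seeds), axis=1).reshape(grid.shape)
    # polygons via the geometric Voronoi diagram, clipped to the study box
    frame = box(xmin, ymin, xmax, ymax)
    cells = voronoi_diagram(MultiPoint([Point(p) for p in seeds]), envelope=frame)
    polys = [None] * k
    for geom in cells.geoms:
        clipped = geom.intersection(frame)
        if clipped.is_empty:
            continue
        d = cdist(np.asarray([[clipped.representative_point().x,
                               clipped.representative_point().y]]), seeds)
        polys[int(np.argmin(d))] = clipped
    for i in range(k):  # degenerate clip: fall back to the seed's cell bbox
        if polys[i] is None:
            sel = labels == i
            if not sel.any():
                raise ValueError("empty Voronoi zone; use fewer zones or a larger grid")
            rr, cc = np.nonzero(sel)
            x0, y1 = grid.rowcol_to_xy(rr.min(), cc.min())
            x1, y0 = grid.rowcol_to_xy(rr.max(), cc.max())
            h = grid.cell_size / 2
            polys[i] = box(x0 - h, y0 - h, x1 + h, y1 + h)
    return Zones(labels=labels, polygons=polys, ids=np.arange(k), seeds=seeds)


def _population_field(rng, grid: GridSpec, params: SceneParams) -> np.ndarray:
    xmin, ymin, xmax, ymax = grid.extent
    w, h = xmax - xmin, ymax - ymin
    X, Y = grid.cell_centers()
    centers = np.column_stack(
        [
            rng.uniform(xmin + 0.08 * w, xmax - 0.08 * w, params.n_clusters),
            rng.uniform(ymin + 0.08 * h, ymax - 0.08 * h, params.n_clusters),
        ]
    )
    sigmas = rng.uniform(0.03, 0.09, params.n_clusters) * min(w, h)
    weights = rng.lognormal(mean=0.0, sigma=0.8, size=params.n_clusters)
    dens = np.zeros(grid.shape)
    for (cx, cy), s, wgt in zip(centers, sigmas, weights):
        d2 = (X - cx) ** 2 + (Y - cy) ** 2
        dens += wgt * np.exp(-d2 / (2 * s * s))
    dens += 0.015 * dens.max()  # rural background
    # multiplicative log-normal texture for a heavy-tailed marginal
    dens *= np.exp(0.6 * _smooth_field(rng, grid.shape, sigma=2.5))
    pop = dens / dens.sum() * params.total_population
    return pop, centers


def _poverty_field(rng, grid, params, density) -> np.ndarray:
    """Smooth field in [0, 1], anti-correlated with log density.

    poverty = logistic(a + g·(−c·u + e)) with u the standardized log density
    and e smooth noise; c is calibrated by a short deterministic iteration so
    the realized Pearson correlation with log(1+density) hits the target.
    """
    u = _standardize(np.log1p(density))
    e = _smooth_field(rng, grid.shape, sigma=5.0)
    t = params.poverty_density_corr
    a = logit(params.mean_poverty)
    lin = t
    for _ in range(4):
        c = abs(lin) / np.sqrt(1 - lin * lin)
        raw = _standardize(-c * u + e)
        pov = np.clip(expit(a + 1.0 * raw), 0.0, 1.0)
        r = np.corrcoef(pov.ravel(), np.log1p(density).ravel())[0, 1]
        if abs(r - t) < 0.01:
            break
        lin = float(np.clip(lin * t / r, -0.98, -0.02))
    return pov


def _landcover_field(rng, grid, params, density) -> np.ndarray:
    f = _smooth_field(rng, grid.shape, sigma=4.0)
    wfield = _smooth_field(rng, grid.shape, sigma=3.0)
    lc = np.full(grid.shape, LANDCOVER_CODES["grassland"], dtype=np.int16)
    # vegetation mosaic by quantiles of one smooth field
    qs = np.quantile(f, [0.15, 0.30, 0.55, 0.88, 0.93])
    lc[f <= qs[0]] = LANDCOVER_CODES["forest"]
    lc[(f > qs[0]) & (f <= qs[1])] = LANDCOVER_CODES["shrubland"]
    lc[(f > qs[1]) & (f <= qs[2])] = LANDCOVER_CODES["grassland"]
    lc[(f > qs[2]) & (f <= qs[3])] = LANDCOVER_CODES["cropland"]
    lc[(f > qs[3]) & (f <= qs[4])] = LANDCOVER_CODES["sparse_vegetation"]
    lc[f > qs[4]] = LANDCOVER_CODES["bare"]
    # water bodies and flood zones from an independent field
    lc[wfield <= np.quantile(wfield, 0.02)] = LANDCOVER_CODES["water"]
    flooded = (wfield > np.quantile(wfield, 0.02)) & (wfield <= np.quantile(wfield, 0.035))
    lc[flooded] = LANDCOVER_CODES["flooded"]
    # dense settlement reads as built-up
    lc[density > np.quantile(density, 0.98)] = LANDCOVER_CODES["built_up"]
    return lc


def _roads(rng, grid, params, centers, density):
    roads = []
    # primary: minimum spanning tree over cluster centers
    D = cdist(centers, centers)
    mst = minimum_spanning_tree(D).tocoo()
    for i, j in zip(mst.row, mst.col):
        roads.append((LineString([centers[i], centers[j]]), "primary"))
    # secondary: density-weighted towns tied to the nearest cluster center
    n_towns = max(2, int(round(2 * params.n_clusters * params.road_density)))
    flat = density.ravel()
    p = flat / flat.sum()
    town_cells = rng.choice(flat.size, size=n_towns, replace=False, p=p)
    rr, cc = np.unravel_index(town_cells, grid.shape)
    tx, ty = grid.rowcol_to_xy(rr, cc)
    towns = np.column_stack([tx, ty])
    for t in towns:
        k = int(np.argmin(np.sum((centers - t) ** 2, axis=1)))
        roads.append((LineString([t, centers[k]]), "secondary"))
    # tertiary: local fill around towns
    xmin, ymin, xmax, ymax = grid.extent
    reach = 0.08 * (xmax - xmin)
    n_tert = max(2, int(round(4 * params.n_clusters * params.road_density)))
    for _ in range(n_tert):
        t = towns[rng.integers(len(towns))]
        ang = rng.uniform(0, 2 * np.pi)
        L = rng.uniform(0.3, 1.0) * reach
        end = np.clip(t + L * np.array([np.cos(ang), np.sin(ang)]),
                      [xmin, ymin], [xmax, ymax])
        roads.append((LineString([t, end]), "tertiary"))
    return roads


def _barriers(rng, grid, params):
    xmin, ymin, xmax, ymax = grid.extent
    w, h = xmax - xmin, ymax - ymin
    X, Y = grid.cell_centers()
    mask = np.zeros(grid.shape, dtype=bool)
    polys = []
    target = params.barrier_fraction
    guard = 0
    while mask.mean() < target and guard < 100:
        guard += 1
        cx, cy = rng.uniform(xmin, xmax), rng.uniform(ymin, ymax)
        r = rng.uniform(0.04, 0.10) * min(w, h)
        polys.append(Point(cx, cy).buffer(r, quad_segs=16))
        mask |= (X - cx) ** 2 + (Y - cy) ** 2 <= r * r
    return polys, mask


def _place_facilities(rng, grid, params, density, poverty, blocked):
    xs, ys, tiers = [], [], []
    base = density.ravel().astype(float)
    pov = poverty.ravel()
    open_cells = ~blocked.ravel()
    for tier, count, gamma in zip(Tier, params.facility_counts, params.tier_density_power):
        # density attraction (stronger for higher tiers) and an exponential
        # poverty penalty, so access is worse in poor areas given density
        wgt = np.where(open_cells, base**gamma * np.exp(-params.facility_poverty_bias * pov), 0.0)
        if (wgt > 0).sum() < count:
            raise ValueError("not enough eligible cells for facility placement")
        cells = rng.choice(base.size, size=count, replace=False, p=wgt / wgt.sum())
        rr, cc = np.unravel_index(cells, grid.shape)
        cx, cy = grid.rowcol_to_xy(rr, cc)
        jitter = rng.uniform(-0.4, 0.4, size=(count, 2)) * grid.cell_size
        xs.append(cx + jitter[:, 0])  # jitter keeps each point inside its cell
        ys.append(cy + jitter[:, 1])
        tiers.extend([tier] * count)
    xy = np.column_stack([np.concatenate(xs), np.concatenate(ys)])
    return FacilitySet(xy=xy, tier=np.array(tiers))


def generate_scene(seed: int, grid: GridSpec, params: SceneParams | None = None) -> SyntheticScene:
    """Generate one deterministic synthetic scene from an integer seed."""
    if params is None:
        params = SceneParams()
    rng = np.random.default_rng(seed)

    population, centers = _population_field(rng, grid, params)
    poverty = _poverty_field(rng, grid, params, population / grid.cell_area_km2)
    landcover = _landcover_field(rng, grid, params, population)
    roads = _roads(rng, grid, params, centers, population)
    barriers, barrier_mask = _barriers(rng, grid, params)

    impassable_lc = np.isin(
        landcover, [LANDCOVER_CODES["water"], LANDCOVER_CODES["flooded"]]
    )
    facilities = _place_facilities(
        rng, grid, params, population / grid.cell_area_km2, poverty,
        blocked=impassable_lc | barrier_mask,
    )

    parishes = generate_parishes(seed, grid, params.n_parishes, rng=rng)
    sub_seeds = np.column_stack(
        [
            rng.uniform(grid.extent[0], grid.extent[2], params.n_subregions),
            rng.uniform(grid.extent[1], grid.extent[3], params.n_subregions),
        ]
    )
    # each parish nests in the subregion whose seed is nearest its own seed
    sub_of_parish = np.argmin(cdist(parishes.seeds, sub_seeds), axis=1)
    # guarantee every subregion is non-empty
    for s in range(params.n_subregions):
        if not np.any(sub_of_parish == s):
            d = cdist(parishes.seeds, sub_seeds[[s]])
            sub_of_parish[int(np.argmin(d))] = s
    sub_labels = sub_of_parish[parishes.labels]
    sub_ids = np.arange(params.n_subregions)
    sub_polys = [
        unary_union([parishes.polygons[i] for i in np.nonzero(sub_of_parish == s)[0]])
        for s in sub_ids
    ]
    subregions = Zones(labels=sub_labels, polygons=sub_polys, ids=sub_ids, seeds=sub_seeds)

    return SyntheticScene(
        grid=grid,
        landcover=landcover,
        roads=roads,
        barriers=barriers,
        barrier_mask=barrier_mask,
        population=population,
        poverty=poverty,
        facilities=facilities,
        parishes=parishes,
        subregions=subregions,
        subregion_of_parish=sub_of_parish,
        study_mask=np.ones(grid.shape, dtype=bool),
        params=params,
        seed=seed,
    )
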