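"""Per-scenario friction (speed) surfaces.

A friction surface assigns every grid cell the traversal speed (km/h) of one
transport mode: the speed of the road class crossing the cell if any road
does, otherwise the speed of the cell's landcover class, scaled by a
scenario-wide multiplier. Classes with zero speed (open water, regularly
flooded areas) are impassable, as are cells inside protected-area barriers —
except where a major (primary or secondary) road transects the barrier — and
cells outside the study mask.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .grids import GridSpec

__all__ = [
    "LANDCOVER_CODES",
    "ROAD_CODES",
    "ROAD_NONE",
    "ScenarioSpec",
    "FrictionSurface",
    "default_speed_table",
    "rasterize_roads",
    "supercover_cells",
    "build_friction",
]

# integer raster codes for the nine landcover classes
LANDCOVER_CODES: dict[str, int] = {
    "forest": 1,
    "shrubland": 2,
    "grassland": 3,
    "cropland": 4,
    "flooded": 5,
    "sparse_vegetation": 6,
    "bare": 7,
    "built_up": 8,
    "water": 9,
}

ROAD_NONE = 0
# priority order: primary beats secondary beats tertiary within a cell
ROAD_CODES: dict[str, int] = {"primary": 1, "secondary": 2, "tertiary": 3}
_ROAD_CLASS_KEY = {1: "primary_road", 2: "secondary_road", 3: "tertiary_road"}

MODES = ("walk", "bicycle", "drive")


def default_speed_table(mode: str) -> dict[str, float]:
    """Shipped default speed table (km/h) for one mode."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    ref = importlib.resources.files("healthreach") / "data" / "speeds.yaml"
    tables = yaml.safe_load(ref.read_text())
    return {k: float(v) for k, v in tables[mode].items()}


@dataclass(frozen=True)
class ScenarioSpec:
    """One travel scenario: mode, speed table and speed multiplier.

    ``multiplier`` scales every speed in the table; 0.8 and 1.2 bracket the
    central 1.0 run to express travel-time variability. ``barrier_exempt_roads``
    names the road classes allowed to cross protected-area barriers.
    """

    mode: str
    multiplier: float = 1.0
    speed_table: dict[str, float] | None = None
    barrier_exempt_roads: tuple[str, ...] = ("primary", "secondary")

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")
        if self.speed_table is None:
            object.__setattr__(self, "speed_table", default_speed_table(self.mode))
        if any(v < 0 for v in self.speed_table.values()):
            raise ValueError("speeds must be non-negative")
        unknown = set(self.barrier_exempt_roads) - set(ROAD_CODES)
        if unknown:
            raise ValueError(f"unknown road classes in barrier exemption: {sorted(unknown)}")


@dataclass
class FrictionSurface:
    """Per-cell traversal speed for one scenario.

    ``speed`` is km/h; impassable cells have speed 0 and ``passable`` False.
    """

    grid: GridSpec
    speed: np.ndarray
    passable: np.ndarray
    scenario: ScenarioSpec | None = None

    def __post_init__(self):
        self.speed = np.asarray(self.speed, dtype=float)
        self.passable = np.asarray(self.passable, dtype=bool)
        if self.speed.shape != self.grid.shape or self.passable.shape != self.grid.shape:
            raise ValueError("speed/passable shape does not match grid")
        if np.any(self.speed[self.passable] <= 0):
            raise ValueError("passable cells must have positive speed")
        # normal form: impassable cells carry speed 0
        self.speed = np.where(self.passable, self.speed, 0.0)


def supercover_cells(x0, y0, x1, y1):
    """All integer cells ``(row=y, col=x)`` whose interior a segment crosses.

    A supercover traversal (Amanatides & Woo): unlike Bresenham it returns
    *every* cell the segment passes through, so a rasterized road stays
    connected for 8-neighbor movement with no diagonal gaps. Coordinates are
    in cell units (col = x, row = y).
    """
    cells = []
    x, y = x0, y0
    cx, cy = int(np.floor(x0)), int(np.floor(y0))
    ex, ey = int(np.floor(x1)), int(np.floor(y1))
    dx, dy = x1 - x0, y1 - y0
    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    # parametric distance to the next vertical / horizontal cell boundary
    t_max_x = np.inf if dx == 0 else ((cx + (step_x > 0)) - x0) / dx
    t_max_y = np.inf if dy == 0 else ((cy + (step_y > 0)) - y0) / dy
    t_delta_x = np.inf if dx == 0 else abs(1.0 / dx)
    t_delta_y = np.inf if dy == 0 else abs(1.0 / dy)
    cells.append((cy, cx))
    guard = 0
    limit = 4 * (abs(ex - cx) + abs(ey - cy) + 2)
    while (cx, cy) != (ex, ey) and guard < limit:
        guard += 1
        if t_max_x < t_max_y:
            t_max_x += t_delta_x
            cx += step_x
        elif t_max_y < t_max_x:
            t_max_y += t_delta_y
            cy += step_y
        else:  # exact corner crossing: include both side cells (supercover)
            cells.append((cy, cx + step_x))
            cells.append((cy + step_y, cx))
            t_max_x += t_delta_x
            t_max_y += t_delta_y
            cx += step_x
            cy += step_y
        cells.append((cy, cx))
    return cells


def rasterize_roads(roads, grid: GridSpec):
    """Burn classed polylines into a categorical road raster.

    Parameters
    ----------
    roads : iterable of (geometry, class)
        ``geometry`` a shapely LineString (planar meters), ``class`` one of
        ``primary | secondary | tertiary``.
    grid : GridSpec

    Returns
    -------
    ndarray of int
        Per cell, the highest-priority road class code present
        (primary > secondary > tertiary) or :data:`ROAD_NONE`.
    """
    out = np.full(grid.shape, ROAD_NONE, dtype=np.int16)
    # priority: lower code wins; ROAD_NONE treated as +inf
    best = np.full(grid.shape, np.iinfo(np.int16).max, dtype=np.int32)
    x0, y0 = grid.origin
    cs = grid.cell_size
    for geom, cls in roads:
        if cls not in ROAD_CODES:
            raise ValueError(f"unknown road class {cls!r}")
        code = ROAD_CODES[cls]
        coords = np.asarray(geom.coords, dtype=float)
        # to cell units with y counted downward from the top edge
        cx = (coords[:, 0] - x0) / cs
        cy = grid.nrows - (coords[:, 1] - y0) / cs
        for i in range(len(coords) - 1):
            for r, c in supercover_cells(cx[i], cy[i], cx[i + 1], cy[i + 1]):
                if 0 <= r < grid.nrows and 0 <= c < grid.ncols and code < best[r, c]:
                    best[r, c] = code
    hit = best < np.iinfo(np.int16).max
    out[hit] = best[hit]
    return out


def build_friction(
    landcover: np.ndarray,
    road_raster: np.ndarray,
    barrier_mask: np.ndarray | None,
    scenario: ScenarioSpec,
    grid: GridSpec,
    study_mask: np.ndarray | None = None,
) -> FrictionSurface:
    """Compile the per-cell speed surface for one scenario.

    Cell speed is ``multiplier × table[road class]`` where a road is present,
    else ``multiplier × table[landcover class]``. Zero-speed classes are
    impassable. Barrier cells are impassable unless crossed by an exempt
    (by default primary or secondary) road; cells outside ``study_mask`` are
    always impassable.
    """
    landcover = np.asarray(landcover)
    road_raster = np.asarray(road_raster)
    if landcover.shape != grid.shape or road_raster.shape != grid.shape:
        raise ValueError("landcover/road raster shape does not match grid")

    code_to_name = {v: k for k, v in LANDCOVER_CODES.items()}
    present = np.unique(landcover)
    lut = np.zeros(int(max(present.max(), 1)) + 1, dtype=float)
    for code in present:
        name = code_to_name.get(int(code))
        if name is None or name not in scenario.speed_table:
            raise KeyError(
                f"landcover class code {int(code)}"
                + (f" ({name})" if name else "")
                + " has no entry in the speed table"
            )
        lut[int(code)] = scenario.speed_table[name]
    speed = lut[landcover]

    for code, key in _ROAD_CLASS_KEY.items():
        if key not in scenario.speed_table:
            raise KeyError(f"road class {key} has no entry in the speed table")
        speed = np.where(road_raster == code, scenario.speed_table[key], speed)

    speed = speed * scenario.multiplier
    passable = speed > 0

    if barrier_mask is not None:
        barrier_mask = np.asarray(barrier_mask, dtype=bool)
        exempt_codes = [ROAD_CODES[c] for c in scenario.barrier_exempt_roads]
        exempt = np.isin(road_raster, exempt_codes)
        passable &= ~barrier_mask | exempt
    if study_mask is not None:
        passable &= np.asarray(study_mask, dtype=bool)
    speed = np.where(passable, speed, 0.0)
    return FrictionSurface(grid=grid, speed=speed, passable=passable, scenario=scenario)
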