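"""Population coverage within a travel-time threshold.

Coverage is the share of the total population living in cells whose travel
time to the nearest eligible facility is within a threshold (default one
hour, read as inclusive). The full table crosses facility level × transport
mode, with an interval from the 0.8× and 1.2× speed-multiplier runs around
the central 1.0× value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .friction import ScenarioSpec, build_friction
from .traveltime import FacilitySet, Tier, TravelTimeSurface, compute_travel_time, eligible_facilities

__all__ = ["population_within", "percentage_point_gain", "coverage_matrix", "CoverageTable"]


def population_within(tt: TravelTimeSurface, population: np.ndarray, threshold: float) -> float:
    """Proportion of total population within ``threshold`` minutes.

    The denominator is the whole population raster (including people on
    impassable or unreachable cells), matching country-total denominators.
    """
    pop = np.asarray(population, dtype=float)
    if pop.shape != tt.grid.shape:
        raise ValueError("population raster shape does not match travel-time grid")
    total = pop.sum()
    if total <= 0:
        raise ValueError("total population must be positive")
    covered = pop[tt.minutes <= threshold].sum()
    return float(covered / total)


def percentage_point_gain(cov_a: float, cov_b: float, percent: bool = False) -> float:
    """Percentage-point difference ``b − a``.

    With ``percent=False`` (default) inputs are proportions in [0, 1] and the
    result is ``100·(b − a)``; with ``percent=True`` inputs are already in
    percent and the result is the plain difference.
    """
    if percent:
        if not (0 <= cov_a <= 100 and 0 <= cov_b <= 100):
            raise ValueError("percent inputs must lie in [0, 100]")
        if cov_a <= 1 and cov_b <= 1:
            # legal but almost certainly a unit mix-up; stay strict
            pass
        return float(cov_b - cov_a)
    if not (0 <= cov_a <= 1 and 0 <= cov_b <= 1):
        raise ValueError("proportion inputs must lie in [0, 1]; pass percent=True for percents")
    return float(100.0 * (cov_b - cov_a))


@dataclass
class CoverageTable:
    """Level × mode coverage with a (low, high) speed-variability interval."""

    table: pd.DataFrame  # columns: level, mode, central, low, high
    threshold: float

    def to_display(self) -> pd.DataFrame:
        """Percent layout with the interval in parentheses."""
        df = self.table.copy()
        df["coverage"] = [
            f"{100 * c:.2f}% ({100 * lo:.2f}–{100 * hi:.2f})"
            for c, lo, hi in zip(df["central"], df["low"], df["high"])
        ]
        return df[["level", "mode", "coverage"]]


def coverage_matrix(
    landcover: np.ndarray,
    road_raster: np.ndarray,
    barrier_mask: np.ndarray | None,
    population: np.ndarray,
    facilities: FacilitySet,
    grid,
    study_mask: np.ndarray | None = None,
    levels: tuple = tuple(Tier),
    modes: tuple = ("walk", "bicycle", "drive"),
    multipliers: tuple = (0.8, 1.0, 1.2),
    threshold: float = 60.0,
) -> CoverageTable:
    """Coverage for every level × mode, with the multiplier interval.

    The central value uses the middle multiplier (1.0 by default); ``low`` and
    ``high`` are the min/max across the multiplier runs.
    """
    if len(multipliers) < 1:
        raise ValueError("need at least one multiplier")
    central_m = sorted(multipliers)[len(multipliers) // 2]
    rows = []
    for mode in modes:
        for m in multipliers:
            scenario = ScenarioSpec(mode=mode, multiplier=m)
            fr = build_friction(landcover, road_raster, barrier_mask, scenario, grid, study_mask)
            for level in levels:
                elig = eligible_facilities(facilities, level)
                tt = compute_travel_time(fr, elig, level=level)
                rows.append(
                    {
                        "level": Tier(level).name,
                        "mode": mode,
                        "multiplier": m,
                        "coverage": population_within(tt, population, threshold),
                    }
                )
    raw = pd.DataFrame(rows)
    out = []
    for (level, mode), grp in raw.groupby(["level", "mode"], sort=False):
        central = float(grp.loc[grp["multiplier"] == central_m, "coverage"].iloc[0])
        out.append(
            {
                "level": level,
                "mode": mode,
                "central": central,
                "low": float(grp["coverage"].min()),
                "high": float(grp["coverage"].max()),
            }
        )
    table = pd.DataFrame(out)
    # stable ordering: level by tier, mode in given order
    table["_lv"] = table["level"].map({t.name: int(t) for t in Tier})
    table["_md"] = table["mode"].map({m: i for i, m in enumerate(modes)})
    table = table.sort_values(["_lv", "_md"]).drop(columns=["_lv", "_md"]).reset_index(drop=True)
    return CoverageTable(table=table, threshold=threshold)
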