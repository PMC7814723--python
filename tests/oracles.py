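"""Independent oracles used only by the test suite.

These deliberately avoid the package's computational paths: travel times come
from synchronous Bellman-Ford-style relaxation to a fixed point (plus a
literal simple-path enumerator for tiny grids), and Gi* z-values from a
per-zone scalar loop over the textbook formula.
"""

from __future__ import annotations

import math

import numpy as np

SQRT2 = math.sqrt(2.0)
OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def edge_minutes(speed_a, speed_b, cell_size_m, diagonal):
    d_km = cell_size_m / 1000.0 * (SQRT2 if diagonal else 1.0)
    return 60.0 * (d_km / 2.0) * (1.0 / speed_a + 1.0 / speed_b)


def relaxation_times(speed, passable, cell_size_m, source_cells):
    """Fixed-point synchronous relaxation of the shortest-path equations."""
    nr, nc = speed.shape
    t = np.full((nr, nc), np.inf)
    for r, c in source_cells:
        if not passable[r, c]:
            raise ValueError("source on impassable cell")
        t[r, c] = 0.0
    for _ in range(nr * nc + 1):
        changed = False
        for r in range(nr):
            for c in range(nc):
                if not passable[r, c]:
                    continue
                for dr, dc in OFFSETS:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and passable[rr, cc]:
                        cand = t[rr, cc] + edge_minutes(
                            speed[rr, cc], speed[r, c], cell_size_m, dr != 0 and dc != 0
                        )
                        if cand < t[r, c] - 1e-15:
                            t[r, c] = cand
                            changed = True
        if not changed:
            break
    return t


def enumerate_path_times(speed, passable, cell_size_m, source_cells, target):
    """Minimum travel time to ``target`` over ALL simple paths (tiny grids only)."""
    nr, nc = speed.shape
    best = [np.inf]
    sources = set(source_cells)

    def dfs(cell, time, visited):
        if time >= best[0]:
            return
        if cell in sources:
            best[0] = time
            return
        r, c = cell
        for dr, dc in OFFSETS:
            rr, cc = r + dr, c + dc
            nxt = (rr, cc)
            if 0 <= rr < nr and 0 <= cc < nc and passable[rr, cc] and nxt not in visited:
                step = edge_minutes(
                    speed[r, c], speed[rr, cc], cell_size_m, dr != 0 and dc != 0
                )
                dfs(nxt, time + step, visited | {nxt})

    dfs(target, 0.0, {target})
    return best[0]


def gi_star_reference(values, neighbor_lists):
    """Per-zone scalar-loop Gi* (self term included, binary weights)."""
    x = [float(v) for v in values]
    n = len(x)
    xbar = sum(x) / n
    s = math.sqrt(sum(v * v for v in x) / n - xbar * xbar)
    out = []
    for i, neigh in enumerate(neighbor_lists):
        w = len(neigh) + 1
        lag = x[i] + sum(x[j] for j in neigh)
        denom = s * math.sqrt((n * w - w * w) / (n - 1))
        # neighborhood covering every zone: statistic undefined
        out.append((lag - xbar * w) / denom if denom > 0 else math.nan)
    return np.array(out)
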