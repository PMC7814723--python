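"""Scene and result serialization: ASCII-grid rasters, GeoJSON vectors, YAML params."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml
from shapely.geometry import mapping

from .grids import write_ascii_grid

__all__ = ["features_to_geojson", "write_geojson", "write_scene"]


def features_to_geojson(geometries, properties=None) -> dict:
    """Build a GeoJSON FeatureCollection from shapely geometries."""
    if properties is None:
        properties = [{} for _ in geometries]
    feats = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(path, geometries, properties=None) -> None:
    with open(path, "w") as fh:
        json.dump(features_to_geojson(geometries, properties), fh)


def write_scene(scene, outdir) -> Path:
    """Persist a synthetic scene as text artifacts (rasters, GeoJSON, YAML)."""
    from shapely.geometry import Point

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    g = scene.grid
    write_ascii_grid(out / "landcover.asc", scene.landcover, g)
    write_ascii_grid(out / "population.asc", scene.population, g)
    write_ascii_grid(out / "poverty.asc", scene.poverty, g)
    write_ascii_grid(out / "parish_labels.asc", scene.parishes.labels, g)
    write_ascii_grid(out / "subregion_labels.asc", scene.subregions.labels, g)
    write_ascii_grid(out / "barrier_mask.asc", scene.barrier_mask.astype(float), g)
    write_geojson(
        out / "roads.geojson",
        [geom for geom, _ in scene.roads],
        [{"class": cls} for _, cls in scene.roads],
    )
    write_geojson(out / "barriers.geojson", scene.barriers)
    from healthreach.traveltime import Tier

    write_geojson(
        out / "facilities.geojson",
        [Point(xy) for xy in scene.facilities.xy],
        [{"tier": Tier(int(t)).name} for t in scene.facilities.tier],
    )
    write_geojson(
        out / "parishes.geojson",
        scene.parishes.polygons,
        [{"parish_id": int(i), "subregion_id": int(s)}
         for i, s in zip(scene.parishes.ids, scene.subregion_of_parish)],
    )
    write_geojson(
        out / "subregions.geojson",
        scene.subregions.polygons,
        [{"subregion_id": int(i)} for i in scene.subregions.ids],
    )
    params = dataclasses.asdict(scene.params)
    params["seed"] = scene.seed
    params["grid"] = {
        "nrows": g.nrows, "ncols": g.ncols,
        "cell_size": g.cell_size, "origin": list(g.origin),
    }
    with open(out / "scene.yaml", "w") as fh:
        yaml.safe_dump(_plain(params), fh)
    return out


def _plain(obj):
    """Recursively coerce numpy scalars/tuples for YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
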