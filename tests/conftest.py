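import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

import healthreach as hr
from healthreach import modeling as M

SMALL_PARAMS = hr.SceneParams(
    n_clusters=4,
    facility_counts=(12, 6, 3, 2, 1, 1),
    n_parishes=36,
    n_subregions=4,
    total_population=2e5,
)


@pytest.fixture(scope="session")
def small_scene():
    """A compact scene exercising every landscape feature (60x60, 1 km cells)."""
    return hr.generate_scene(11, hr.GridSpec(60, 60, 1000.0), SMALL_PARAMS)


@pytest.fixture(scope="session")
def small_surfaces(small_scene):
    """Walk + bicycle travel-time surfaces per tier for the small scene."""
    scene = small_scene
    out = {}
    for mode in ("walk", "bicycle"):
        fr = hr.build_friction(
            scene.landcover, scene.road_raster, scene.barrier_mask,
            hr.ScenarioSpec(mode), scene.grid, scene.study_mask,
        )
        out[mode] = {
            t: hr.compute_travel_time(fr, hr.eligible_facilities(scene.facilities, t), level=t)
            for t in hr.Tier
        }
    return out


RECOVERY_PARAMS = hr.SceneParams(
    facility_counts=(64, 32, 12, 6, 3, 1),
    n_parishes=100,
    n_subregions=8,
    total_population=1e6,
)


@pytest.fixture(scope="session")
def recovery_scene():
    """Scene sized so the generated effects are statistically recoverable
    (130x130, 800 m cells, 64 lowest-tier facilities)."""
    return hr.generate_scene(4, hr.GridSpec(130, 130, 800.0), RECOVERY_PARAMS)


@pytest.fixture(scope="session")
def recovery_table(recovery_scene):
    """Sampled covariate table (walk + saved, all tiers) from the recovery scene."""
    scene = recovery_scene
    walk, bike = {}, {}
    for mode, store in (("walk", walk), ("bicycle", bike)):
        fr = hr.build_friction(
            scene.landcover, scene.road_raster, scene.barrier_mask,
            hr.ScenarioSpec(mode), scene.grid, scene.study_mask,
        )
        for t in hr.Tier:
            store[t] = hr.compute_travel_time(
                fr, hr.eligible_facilities(scene.facilities, t), level=t
            )
    return M.sample_points(scene, walk, bike, n=4000, seed=4)


def toy_friction(speed_array, cell_size=1000.0, scenario=None):
    """FrictionSurface from a raw speed array (0 = impassable)."""
    speed = np.asarray(speed_array, dtype=float)
    grid = hr.GridSpec(*speed.shape, cell_size)
    return hr.FrictionSurface(grid=grid, speed=speed, passable=speed > 0,
                              scenario=scenario)


@pytest.fixture
def toy_friction_factory():
    return toy_friction
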