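"""Shared fixtures: synthetic study-condition plans, logs, and volumes.

The demo arc mirrors the typical study delivery: a single 360-degree VMAT
arc with 91 control points (4 degrees per control point), 600 MU, a 10 cm
field with sliding-window modulation, delivered in 2 minutes (6000 trajectory
records at 20 ms).  Heavier derived objects are session-scoped because
several tests reuse them.
"""

import numpy as np
import pytest

from fluqa import (
    PlanRecipe,
    compute_volume_bounds,
    fluence_from_log,
    fluence_from_plan,
    generate_matched_log,
    generate_synthetic_plan,
)
from fluqa.fluence import GridSpec

DEMO_SEED = 3


@pytest.fixture(scope="session")
def demo_beams():
    recipe = PlanRecipe(n_arcs=1, cps_per_arc=91, arc_span_deg=360.0,
                        total_mu=600.0, field_size_cm=10.0,
                        pattern="sliding-window", seed=DEMO_SEED)
    return generate_synthetic_plan(recipe)


@pytest.fixture(scope="session")
def demo_log(demo_beams):
    return generate_matched_log(demo_beams[0], duration_s=120.0)


@pytest.fixture(scope="session")
def demo_grid(demo_beams):
    return compute_volume_bounds(demo_beams)


@pytest.fixture(scope="session")
def demo_plan_volume(demo_beams, demo_grid):
    return fluence_from_plan(demo_beams, demo_grid)


@pytest.fixture(scope="session")
def demo_log_volume(demo_log, demo_grid):
    return fluence_from_log(demo_log, demo_grid)


@pytest.fixture(scope="session")
def small_beams():
    """Half-arc, small-field plan for sweep-style tests (cheap grids)."""
    recipe = PlanRecipe(n_arcs=1, cps_per_arc=37, arc_span_deg=180.0,
                        total_mu=300.0, field_size_cm=6.0,
                        pattern="sliding-window", seed=11)
    return generate_synthetic_plan(recipe)


@pytest.fixture()
def grid20():
    """20^3 voxel grid at 3 mm covering +/-3 cm around the isocenter."""
    return GridSpec(origin=(-3.0, -3.0, -3.0), voxel_size=0.3, dims=(20, 20, 20))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
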