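import numpy as np
import pytest
from hypothesis import settings

from gridforage import (
    GridGeometry,
    GridWorld,
    LearningConfig,
    build_geocache_model,
    run_foraging_trial,
    run_navigation_trial,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# reference study conditions for the shared trial fixtures
NAV_START, NAV_TARGET = 90, 54  # bottom-left corner; Manhattan distance 8
PATCH_ENTRANCE = 55


@pytest.fixture(scope="session")
def geometry():
    return GridGeometry(10, 10)


@pytest.fixture(scope="session")
def nav_record(geometry):
    """One default navigation trial: 10 moves, known map, distance-8 target."""
    model = build_geocache_model(geometry, NAV_TARGET, start_location=NAV_START)
    world = GridWorld(geometry, NAV_START, NAV_TARGET)
    return run_navigation_trial(model, world, 10, seed=1)


@pytest.fixture(scope="session")
def forage_run(geometry):
    """One default foraging trial (30 moves, 1/100 priors) plus its model."""
    hidden = 23
    model = build_geocache_model(
        geometry,
        hidden,
        dirichlet_prior_scale=0.01,
        transition_prior_scale=2.0,
        proximity_weight=0.0,
        start_location=PATCH_ENTRANCE,
    )
    prior_a = {m: v.copy() for m, v in model.likelihood.a.items()}
    world = GridWorld(geometry, PATCH_ENTRANCE, hidden)
    record = run_foraging_trial(model, world, 30, LearningConfig(), seed=0)
    return {"model": model, "record": record, "prior_a": prior_a, "hidden": hidden}
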