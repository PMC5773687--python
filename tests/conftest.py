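import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sdmrisk as sr

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def small_grid():
    """A 6x6 grid of 1-degree cells over lon [100, 106), lat [20, 26)."""
    return sr.Grid.from_origin(x_min=100.0, y_min=20.0, cell_size=1.0,
                               n_rows=6, n_cols=6)


@pytest.fixture(scope="session")
def demo():
    """One fully simulated study: landscape, species, occurrences, truth."""
    scfg = sr.default_scenario_config(seed=0)
    vcfg = sr.default_species_config(seed=100, n_presences=300)
    stacks = sr.simulate_landscape(scfg)
    suit = sr.true_suitability(stacks["current"], vcfg)
    occ = sr.sample_presences(suit, vcfg)
    truth = sr.ground_truth(stacks, vcfg)
    return {
        "scenario_config": scfg,
        "species_config": vcfg,
        "stacks": stacks,
        "suitability": suit,
        "occurrences": occ,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def demo_training(demo):
    """Filtered occurrences, prune result and 3 pseudo-absence replicates."""
    stack = demo["stacks"]["current"]
    filtered = sr.spatial_filter(demo["occurrences"], stack.grid)
    prune = sr.pearson_prune(stack, seed=1)
    training_sets = sr.build_training_sets(
        filtered, stack, prune, n_replicates=3, base_seed=2
    )
    return {"filtered": filtered, "prune": prune, "training_sets": training_sets}


@pytest.fixture
def dummy_learner():
    """Register a constant-0.5 learner for the duration of one test."""
    fit_fn, predict_fn = sr.make_constant_learner(0.5)
    sr.register_adapter("DUMMY", fit_fn, predict_fn, overwrite=True)
    yield "DUMMY"
    sr.unregister("DUMMY")


def random_binary_map(grid, species, scenario_id, rng):
    values = (rng.random(grid.shape) < 0.4).astype(float)
    return sr.BinaryRangeMap(
        layer=sr.RasterLayer(grid, f"{species}_bin", values),
        threshold=0.5,
        species=species,
        scenario_id=scenario_id,
    )
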