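import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from dimorph.simulate import (Scenario, TraitEffects, generate_individuals,
                              generate_populations, generate_traits,
                              populations_frame)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_scenario() -> Scenario:
    """A small two-trait scenario (8 populations) for fast end-to-end runs."""
    traits = {
        "height": TraitEffects(
            family="gaussian", stages=["wk4", "wk8"], intercept=50.0,
            stage_effects={"wk8": 12.0},
            sex_stage={"wk4": -8.0, "wk8": 6.0},
            sd_population=2.0, sd_family=1.5, sd_residual=6.0,
        ),
        "leaf_number": TraitEffects(
            family="poisson", stages=["wk4", "wk8"], intercept=np.log(10),
            stage_effects={"wk8": np.log(1.6)},
            sex_stage={"wk8": np.log(1.2)},
            sd_population=0.05, sd_family=0.04,
        ),
    }
    return Scenario(n_pops=8, n_families=8, traits=traits)


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    """(observations with race column, populations frame) for the small scenario."""
    pops = generate_populations(small_scenario.n_pops, seed=11)
    inds = generate_individuals(pops, small_scenario.n_families,
                                small_scenario.n_per_family, seed=12)
    obs = generate_traits(inds, pops, small_scenario, seed=13)
    pf = populations_frame(pops)
    obs = obs.merge(pf[["pop_id", "race"]], on="pop_id")
    return obs, pf
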