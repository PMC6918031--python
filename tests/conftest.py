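import numpy as np
import pytest

from fluxvar.chemostat import CommunityState, SimParams, run_simulation
from fluxvar.experiments import BenchmarkConfig, run_benchmark
from fluxvar.model_io import MetabolicModel, make_toy_community


@pytest.fixture(scope="session")
def toy_community():
    """The 4-species / 8-metabolite reference community with 50% cross-feeding."""
    return make_toy_community(4, 8, 0.5, seed=7)


@pytest.fixture(scope="session")
def mini_traces(toy_community):
    """Five short chemostat runs over varied compositions (shared universe)."""
    models, env = toy_community
    params = SimParams(n_steps=30, carrying_capacity=0.1, rng_seed=0)
    rng = np.random.default_rng(11)
    traces = []
    for _ in range(5):
        rel = rng.dirichlet(np.ones(len(models)))
        init = CommunityState(
            t=0.0, bio=rel * 0.1, conc=env.initial_concentrations.copy()
        )
        traces.append(run_simulation(models, init, env, params))
    return traces


@pytest.fixture(scope="session")
def toy_benchmark():
    """The 13-composition x 100-step toy benchmark (default configuration)."""
    return run_benchmark(BenchmarkConfig())


def linear_chain_model(uptake_coef: float = 1.0) -> MetabolicModel:
    """Substrate -> biomass with the given substrate requirement per unit
    growth; exchange uptake is the only supply."""
    return MetabolicModel(
        species_id="chain",
        metabolite_ids=["sub_c"],
        reaction_ids=["EX_sub", "biomass"],
        S=np.array([[-1.0, -uptake_coef]]),
        lower_bounds=np.array([-1000.0, 0.0]),
        upper_bounds=np.array([0.0, 1000.0]),
        biomass_reaction="biomass",
        exchange_map={"EX_sub": "sub"},
    )
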