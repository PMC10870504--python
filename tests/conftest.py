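import numpy as np
import pytest

from hybridm6a import pipeline, simdata


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default study conditions (3 replicates,
    50x input depth, 8x IP enrichment), shared across tests."""
    rc = pipeline.RunConfig(simulation=simdata.SimulationConfig(seed=1))
    return pipeline.run_full(rc)


@pytest.fixture(scope="session")
def small_experiment():
    """A small simulated hybrid used by module-level tests."""
    cfg = simdata.SimulationConfig(seed=3, n_genes=10)
    return simdata.simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
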