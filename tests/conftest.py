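import numpy as np
import pytest
from hypothesis import settings

from irriheat import pipeline
from irriheat.synthetic_world import InjectedSignal, WorldConfig, generate_world

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_config() -> WorldConfig:
    return WorldConfig.toy(rng_seed=7)


@pytest.fixture(scope="session")
def toy_world(toy_config):
    return generate_world(toy_config)


@pytest.fixture(scope="session")
def noiseless_world():
    return generate_world(WorldConfig.toy(rng_seed=11),
                          InjectedSignal.noiseless())


@pytest.fixture(scope="session")
def toy_run(tmp_path_factory):
    """One full toy run-all, shared by pipeline and invariant tests."""
    outdir = tmp_path_factory.mktemp("run") / "out"
    manifest = pipeline.run_all(pipeline.RunConfig(), outdir, seed=3)
    return outdir, manifest


def random_feasible_instance(rng: np.random.Generator):
    """A random (shares, cft) pair satisfying the suitability caps."""
    from irriheat.its_engine import baseline_assign

    cft = rng.dirichlet((2.0, 2.0, 2.0))
    country = rng.dirichlet((1.5, 1.5, 3.0))
    return baseline_assign(country, cft), cft
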