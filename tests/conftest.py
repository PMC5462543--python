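import warnings

import pytest

from paleoplastid.core_io import default_taxonomy
from paleoplastid.pipeline import RunConfig, run_pipeline
from paleoplastid.synthetic_data import SimulationParams, simulate_dataset

warnings.filterwarnings("ignore", message=".*unrooted tree.*")

PIPELINE_SEED = 1


@pytest.fixture(scope="session")
def taxonomy():
    return default_taxonomy()


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """One full pipeline run on the default synthetic dataset, shared by the
    integration and acceptance tests."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    return run_pipeline(RunConfig(seed=PIPELINE_SEED), outdir=outdir)


@pytest.fixture(scope="session")
def dataset(pipeline_result):
    return pipeline_result.dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A reduced dataset for generator-level tests."""
    params = SimulationParams(
        seed=7,
        families_per_origin={"red algae": 3, "green algae": 2,
                             "aplastidic stramenopiles": 1, "prokaryotes": 1},
        fusion_count=2)
    return simulate_dataset(params)
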