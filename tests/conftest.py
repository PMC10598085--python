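import pytest

from clp1kit import (PipelineConfig, SimulationConfig, run_pipeline_on_dataset,
                     simulate_dataset)


@pytest.fixture(scope="session")
def dataset():
    """The default 8-species study dataset (seed 1), generated once."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    """Full pipeline run over the session dataset."""
    return run_pipeline_on_dataset(dataset, PipelineConfig(seed=1))
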