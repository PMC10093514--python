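import time

import pytest

from hsq import PipelineConfig, SimConfig, make_dataset, run_pipeline, trim_bands


@pytest.fixture(scope="session")
def default_dataset():
    """The default 96-sample synthetic acquisition (master seed 42)."""
    return make_dataset(SimConfig())


@pytest.fixture(scope="session")
def trimmed(default_dataset):
    """Default dataset trimmed to the 401-2450 nm analysis range."""
    spectra, analytes = default_dataset
    return trim_bands(spectra, 401.0, 2450.0), analytes


@pytest.fixture(scope="session")
def pipeline_run():
    """One full default study run (52 models) shared across tests."""
    t0 = time.perf_counter()
    result = run_pipeline(PipelineConfig())
    return result, time.perf_counter() - t0
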