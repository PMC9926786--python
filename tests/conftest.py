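import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default planted layout, shared by the
    end-to-end suites (DMR calling dominates the cost)."""
    from regenmeth.pipeline import run_pipeline

    out = tmp_path_factory.mktemp("run")
    summary = run_pipeline({"seed": 7}, out)
    return out, summary
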