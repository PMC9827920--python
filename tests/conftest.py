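import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scenario():
    """Jar-coffin scenario at reduced size for pipeline-level tests."""
    from paleokin import pipeline
    return pipeline.simulate_jar_coffin_scenario(
        seed=7, n_snps=30_000, missingness=0.3, panel_size=40, mean_depth=2.0)
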