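import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=20,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from sersvoc import synthetic_data as sd
from sersvoc import featurize as fz
from sersvoc.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def easy_dataset():
    """Default discrimination dataset: 108 spectra/class at 100 ppb."""
    return sd.generate_dataset(seed=42)


@pytest.fixture(scope="session")
def easy_features(easy_dataset):
    return fz.featurize_dataset(easy_dataset, normalize=True)


@pytest.fixture(scope="session")
def easy_report():
    """Full easy-preset pipeline run with a fixed seed."""
    return run_pipeline(PipelineConfig(preset="easy", seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
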