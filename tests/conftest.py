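import numpy as np
import pytest

from avprosody import PipelineConfig, SyntheticConfig, generate_dataset
from avprosody.pipeline import run_synthetic_pipeline


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    """3 speakers x 20 segments: enough structure for every stage, runs in seconds."""
    return SyntheticConfig(seed=202, n_speakers=3, segments_per_speaker=20)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_bundle(small_config):
    """Pipeline run on the small dataset, fitting only the reporting sizes."""
    cfg = PipelineConfig(sweep_sizes=(17, 19), seed=small_config.seed)
    bundle, truth = run_synthetic_pipeline(small_config, cfg)
    return bundle, truth


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
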