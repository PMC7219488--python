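from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from mrcprel import (
    HEALTHY_VOLUNTARY,
    SimulationConfig,
    default_condition_params,
)

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_params():
    """Healthy-voluntary parameters with every variability source disabled."""
    return replace(
        default_condition_params()[HEALTHY_VOLUNTARY],
        pn_amplitude_sd=0.0,
        pn_latency_dataset_sd_ms=0.0,
        pn_latency_jitter_sd_ms=0.0,
        background_noise_sd=0.0,
        epoch_scale_sd=0.0,
        artefact_prob=0.0,
    )


@pytest.fixture
def small_config():
    return SimulationConfig(seed=7, n_datasets_per_condition=3, n_epochs=12)
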