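import numpy as np
import pytest

from meginet.spectral import decompose_recording, resample_to_analysis_rate
from meginet.synthetic import (
    CohortConfig,
    GroupParams,
    generate_layout,
    generate_subject,
)


@pytest.fixture(scope="session")
def layout12():
    return generate_layout(12, seed=7)


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(
        n_subjects_per_group=2,
        n_sensors=12,
        n_blocks=2,
        sets_per_block=3,
        master_seed=11,
    )


@pytest.fixture(scope="session")
def small_decomp(layout12, small_config):
    """One subject's four-band decomposition: 12 sensors x 6 trials x 216."""
    rec = generate_subject(
        GroupParams(), small_config, layout12, seed=5, subject_id="s0"
    )
    rec = resample_to_analysis_rate(rec, small_config.analysis_rate)
    return decompose_recording(rec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
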