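import numpy as np
import pytest

from harpipe.synthetic import (
    DefectSpec,
    default_activity_models,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_defective_dataset():
    """5 classes x 8 windows of 64 samples with all three defect kinds."""
    return generate_dataset(
        default_activity_models(),
        n_windows_per_class=8,
        window_len=64,
        n_channels=3,
        defects=DefectSpec(missing_rate=0.02, duplicate_rate=0.02, corrupt_rate=0.02),
        seed=99,
    )


@pytest.fixture(scope="session")
def clean_dataset():
    """Defect-free stream: 5 classes x 6 windows of 64 samples."""
    records, gt = generate_dataset(
        default_activity_models(),
        n_windows_per_class=6,
        window_len=64,
        n_channels=3,
        defects=DefectSpec(),
        seed=7,
    )
    return records, gt
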