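import numpy as np
import pytest

from cortexdecorr import GenerationConfig, StudyGeometry, generate_study


@pytest.fixture(scope="session")
def geometry():
    return StudyGeometry()


@pytest.fixture(scope="session")
def clean_cd_study():
    """Noiseless CD-rule study with a known interaction strength."""
    cfg = GenerationConfig(
        n_subjects=3, voxels_per_ring_per_area=20, noise_sd=0.0, d_true=0.3, seed=11
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def noisy_cd_study():
    """CD-rule study at the default 10%-of-peak measurement noise."""
    cfg = GenerationConfig(
        n_subjects=4, voxels_per_ring_per_area=30, noise_sd=0.1, d_true=0.3, seed=21
    )
    return generate_study(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
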