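import numpy as np
import pytest

from senescreen import synthetic_data as synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def pose_truth():
    """One planted 3-cluster ensemble shared across pose tests."""
    return synth.gen_poses(3, [50, 30, 20], n_residues=20,
                           intra_sigma=0.5, inter_sep=15.0, seed=5)


@pytest.fixture(scope="session")
def image_truth():
    return synth.gen_images((256, 256), [5, 5, 5], coloc=1.0,
                            noise_sigma=0.0, seed=2)
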