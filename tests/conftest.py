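import numpy as np
import pytest

from patchflow import GridImage, LabelMap, SyntheticCohortSpec, make_manifest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_image(rng):
    """A 2-channel 2D image with generic random intensities."""
    return GridImage(rng.normal(size=(2, 12, 10)), spacing=(1.0, 1.0))


@pytest.fixture
def small_volume(rng):
    """A single-channel 3D volume."""
    return GridImage(rng.normal(size=(1, 8, 8, 8)), spacing=(1.0, 1.0, 2.0))


@pytest.fixture(scope="session")
def tiny_cohort_dir(tmp_path_factory):
    """A 12-subject noiseless segmentation cohort written to disk once."""
    out = tmp_path_factory.mktemp("cohort")
    spec = SyntheticCohortSpec(n_subjects=12, shape=(16, 16, 16), noise_std=0.0, seed=5)
    manifest = make_manifest(spec, out)
    return spec, manifest
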