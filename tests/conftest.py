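import numpy as np
import pytest

from vstain.fixtures import SyntheticSlideSpec, generate_slide_pair


@pytest.fixture(scope="session")
def slide_pair():
    """Default misaligned pseudo-H&E/MT pair with ground truth."""
    return generate_slide_pair(SyntheticSlideSpec(seed=7))


@pytest.fixture(scope="session")
def aligned_pair():
    """Identity-transform pair: both stains on the same pixel grid."""
    spec = SyntheticSlideSpec(global_shift=(0.0, 0.0), global_rotation=0.0,
                              warp_amplitude=0.0, artifact_fraction=0.0, seed=7)
    return generate_slide_pair(spec)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def textured_patch(slide_pair):
    """A 64x64 tissue-rich grayscale-textured RGB patch."""
    from vstain.fixtures import generate_patch_set
    patches = generate_patch_set(slide_pair, 1, {}, patch_size=64, seed=3)
    return patches[0].mt_patch
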