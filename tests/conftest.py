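import numpy as np
import pytest

from plantar.io import combine_frame, grid_to_image
from plantar.synthetic import SyntheticFootParams, generate_foot


@pytest.fixture(scope="session")
def clean_params():
    """Noiseless, unjittered default foot parameters."""
    return SyntheticFootParams(noise_cv=0.0, rotation_jitter=0.0, translation_jitter=0)


@pytest.fixture(scope="session")
def clean_frame(clean_params):
    """Noiseless both-feet frame (left + right of the default foot)."""
    from dataclasses import replace

    left, _ = generate_foot(replace(clean_params, side="left"))
    right, _ = generate_foot(replace(clean_params, side="right"))
    return combine_frame(left, right)


@pytest.fixture(scope="session")
def clean_image(clean_frame):
    """Device-style 918x918 render of the noiseless frame."""
    return grid_to_image(clean_frame)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
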