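import numpy as np
import pytest

from chromadiet.chromaticity import CalibrationMatrix, DiagramConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def identity_cal():
    return CalibrationMatrix.identity()


@pytest.fixture
def diagram():
    """A synthetic diagram config used throughout the tests."""
    return DiagramConfig(white_point=(0.7, 1.0), axis_scale_x=1.0, axis_scale_y=1.0)
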