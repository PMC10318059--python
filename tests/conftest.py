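import numpy as np
import pytest

from gutperm import Capsule, MovieSpec


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def small_movie_spec(**overrides) -> MovieSpec:
    """A quarter-size chamber phantom for fast unit tests."""
    defaults = dict(
        height=120,
        width=240,
        capsule=Capsule(center_row=60, center_col=120, half_length=80, radius=20),
        duration_hours=2.0,
        interval_minutes=15.0,
        noise_sigma=0.0,
        quantize=False,
        seed=0,
    )
    defaults.update(overrides)
    return MovieSpec(**defaults)


@pytest.fixture
def small_spec():
    return small_movie_spec()
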