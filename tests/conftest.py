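import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from ctbodycomp.phantom import DEFAULT_TISSUE_HU, PhantomSpec


def noise_free_hu():
    return {k: (v[0], 0.0) for k, v in DEFAULT_TISSUE_HU.items()}


@pytest.fixture(scope="session")
def noise_free_spec():
    """Default-geometry phantom with all tissue sds at zero."""
    return PhantomSpec(tissue_hu=noise_free_hu())


@pytest.fixture(scope="session")
def tiny_spec():
    """Coarse 64x64 phantom for brute-force pixel-loop comparisons."""
    return PhantomSpec(
        image_size=(64, 64),
        pixel_spacing=(5.5, 5.5),
        tissue_hu=noise_free_hu(),
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20190427)
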