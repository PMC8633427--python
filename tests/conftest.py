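import numpy as np
import pytest

from swmprofile import CohortConfig, METRICS, generate_cohort


def tiny_config(**overrides):
    """A small spherical cohort that keeps volume grids cheap."""
    kwargs = dict(
        n_control=4,
        n_case=4,
        roi_count=3,
        vertices_per_hemi=120,
        radius_mm=8.0,
        seed=7,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


ZERO_NOISE = dict(
    noise_sd={m: 0.0 for m in METRICS},
    random_sd={"control": (0.0, 0.0), "case": (0.0, 0.0)},
)


@pytest.fixture(scope="session")
def tiny_cfg():
    return tiny_config()


@pytest.fixture(scope="session")
def tiny_bundle(tiny_cfg):
    return generate_cohort(tiny_cfg)


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate_cohort(tiny_config(**ZERO_NOISE))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
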