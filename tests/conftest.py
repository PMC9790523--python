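import numpy as np
import pytest

from lgedixon import (
    AcquisitionParams,
    PhantomSpec,
    generate_phantom,
    simulate_echoes,
)


def small_spec(**overrides) -> PhantomSpec:
    """A compact scene (48 x 48 x 24) that runs every stage in ~1 s."""
    base = dict(
        shape=(48, 48, 24),
        blood_semiaxes_mm=(16.0, 14.0, 12.0),
        wall_thickness_mm=3.0,
        eat_thickness_mm=5.0,
        scar_fraction=0.30,
        mv_radius_mm=7.0,
        mv_height_mm=6.0,
        pv_radius_mm=5.0,
        appendage_radius_mm=4.0,
        seed=1,
    )
    base.update(overrides)
    return PhantomSpec(**base)


@pytest.fixture(scope="session")
def acq() -> AcquisitionParams:
    return AcquisitionParams()


@pytest.fixture(scope="session")
def small_gt(acq):
    return generate_phantom(small_spec())


@pytest.fixture(scope="session")
def small_echoes(small_gt, acq):
    return simulate_echoes(small_gt, acq, noise_sigma=0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
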