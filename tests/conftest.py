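import numpy as np
import pytest
from hypothesis import settings

import dermaflim as dm
from dermaflim import phantom as ph

settings.register_profile("default", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom_cfg():
    """Mid-size phantom: big enough for meaningful region statistics,
    small enough to fit in seconds."""
    return ph.PhantomConfig(
        image_size=96,
        papilla_radius=36.0,
        inner_radius=15.0,
        capillary_spot_radius=4.0,
        rng_seed=3,
    )


@pytest.fixture(scope="session")
def phantom_data(phantom_cfg):
    """(cube, channels, truth_maps, truth_labels) for the session phantom."""
    return ph.simulate_dataset(phantom_cfg)


@pytest.fixture(scope="session")
def fitmaps(phantom_data):
    cube = phantom_data[0]
    return dm.fit_image(cube)


@pytest.fixture(scope="session")
def saaid_map(phantom_data):
    channels = phantom_data[1]
    return dm.compute_saaid(dm.normalize_channels(channels))


@pytest.fixture(scope="session")
def labelmap(phantom_data, fitmaps, saaid_map):
    channels = phantom_data[1]
    return dm.segment_image(channels, fitmaps, saaid_map)


@pytest.fixture(scope="session")
def summary(fitmaps, labelmap):
    return dm.region_summary(fitmaps, labelmap)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
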