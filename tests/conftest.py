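import numpy as np
import pytest

from oarseg.core import CTVolume, HUWindow, SegCase, default_roi_spec
from oarseg.phantom import PhantomConfig, generate_cohort, generate_phantom


def make_ball_case(shape=(32, 32, 16), center=None, radius=5.0, organ="SMG",
                   inside_hu=55.0, body_hu=40.0) -> SegCase:
    """A noiseless case with a spherical organ — geometry fully known."""
    center = center or tuple((s - 1) / 2.0 for s in shape)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    organ_mask = (r2 < radius ** 2).astype(np.uint8)
    body_mask = np.ones(shape, dtype=np.uint8)
    image = np.full(shape, body_hu, dtype=np.float32)
    image[organ_mask > 0] = inside_hu
    return SegCase(image=CTVolume(image), organ_mask=organ_mask, body_mask=body_mask,
                   organ=organ, laterality="left", case_id="ball")


@pytest.fixture(scope="session")
def desk_config():
    return PhantomConfig.desk_scale()


@pytest.fixture(scope="session")
def phantom_case(desk_config):
    return generate_phantom(desk_config, seed=123, laterality="left")


@pytest.fixture(scope="session")
def small_cohort(desk_config):
    return generate_cohort(12, desk_config, seed=321)


@pytest.fixture(scope="session")
def smg_spec():
    return default_roi_spec("SMG", crop_shape=(12, 12, 8))


@pytest.fixture
def ball_case():
    return make_ball_case()
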