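import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rendered_sample():
    """A mid-size rendered plant with its ground-truth mask."""
    from plantnni.synthetic import render_plant, state_from_record

    state = state_from_record(biomass_dm=0.6, n_conc=60.0, nni_true=0.9)
    return render_plant(state, canvas_px=(240, 240), seed=3)


@pytest.fixture()
def disc_mask():
    from skimage.draw import disk

    mask = np.zeros((128, 128), dtype=bool)
    rr, cc = disk((64, 64), 50)
    mask[rr, cc] = True
    return mask


@pytest.fixture()
def green_disc_image():
    """A green disc (60, 160, 60) on a white background."""
    from skimage.draw import disk

    img = np.full((120, 120, 3), 255, dtype=np.uint8)
    rr, cc = disk((60, 60), 40)
    img[rr, cc] = (60, 160, 60)
    mask = np.zeros((120, 120), dtype=bool)
    mask[rr, cc] = True
    return img, mask
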