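import numpy as np
import pytest
from hypothesis import settings

import hemoflow as hf
from hemoflow import synthetic as syn

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def piv_params():
    """PIV parameters scaled so an 8-px window searches a +/-4 px radius at
    0.1 µm/px, leaving room for the test translations."""
    return hf.PIVParams(window_area=0.64, window_overlap=0.4, search_area=2.56)


@pytest.fixture
def translation_movie(piv_params):
    movie, gt = syn.make_speckle_movie(
        "uniform", 2.0, frame_size=(64, 64), pixel_size=0.1, n_frames=4,
        frame_interval=5.0, seed=1,
    )
    return movie, gt


@pytest.fixture
def two_channel_cell():
    return syn.make_two_channel_cell(
        body_radius=5.0, lamella_extent=12.0, ring_width=2.0, ring_amplitude=2.0,
        pixel_size=0.1, seed=2,
    )


@pytest.fixture
def linear_sink_field():
    """Analytic linear sink v = -a*r sampled on an 11x11 node grid, a = 0.05/min."""
    a = 0.05
    x = np.arange(11, dtype=float)
    xx, yy = np.meshgrid(x, x)
    u = -a * (xx - 5.0)
    v = -a * (yy - 5.0)
    return (
        hf.FlowField(
            x=x, y=x, u=u[None], v=v[None], valid=np.ones((1, 11, 11), bool),
            grid_spacing=1.0, frame_interval=5.0,
        ),
        a,
    )
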