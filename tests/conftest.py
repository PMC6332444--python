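
import numpy as np
import pytest

import sasmd
from sasmd.landscape import Channel, FunnelParams, make_funnel_landscape


@pytest.fixture(scope="session")
def standard_land():
    return sasmd.standard_landscape()


@pytest.fixture(scope="session")
def standard_cfg():
    return sasmd.standard_controller()


@pytest.fixture(scope="session")
def quick_cfg():
    """Controller with a short clock for cheap driver tests."""
    return sasmd.standard_controller(max_time=40.0, equil_time=2.0)


@pytest.fixture(scope="session")
def plain_two_channel():
    """Well + shell only (no guide wall), two well-separated channels of
    heights 10 and 30 kJ/mol, far enough out that the well tail is
    negligible at the shell."""
    params = FunnelParams(
        well_depth=40.0, well_width=0.15,
        background_barrier=60.0, barrier_radius=0.9, barrier_width=0.12,
        guide_amp=0.0,
        channels=(
            Channel((0.0, 0.0, 1.0), 10.0, 0.18),
            Channel((1.0, 0.0, 0.0), 30.0, 0.18),
        ),
    )
    return make_funnel_landscape(params)


def directional_profile(land, direction, d_max=2.0, resolution=0.001):
    """1-D oracle: energies along a ray from the well centre."""
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    d = np.arange(0.0, d_max, resolution)
    pos = land.well_center + d[:, None] * direction
    return d, land.energy_batch(pos)


@pytest.fixture(scope="session")
def profile_oracle():
    return directional_profile
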