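import numpy as np
import pytest

from litt import (
    LaserSource,
    PhantomModel,
    ScanProtocol,
    ThermoParams,
    run_shot,
)

GEL = dict(alpha=0.35, diffusion=0.23)
MUSCLE = dict(alpha=0.65, diffusion=0.18)


@pytest.fixture(scope="session")
def protocol():
    return ScanProtocol()


def make_shot_setup(alpha, diffusion, grid=(64, 64, 8), voxel=(1.4, 1.4, 3.0),
                    boundary="insulated_z"):
    phantom = PhantomModel(
        shape=grid, voxel_size=voxel,
        params=ThermoParams(alpha, diffusion), boundary=boundary,
    )
    tip = tuple((n // 2) * d for n, d in zip(grid, voxel))
    source = LaserSource(tip_position=tip)
    return phantom, source


@pytest.fixture(scope="session")
def gel_shot_frames(protocol):
    """Noiseless simulated gel test shot: 3 W for 20 s, 110 s recorded."""
    phantom, source = make_shot_setup(**GEL)
    frames = run_shot(phantom, source, 3.0, 30.0, 20.0, 110.0, protocol)
    return frames, phantom, source
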