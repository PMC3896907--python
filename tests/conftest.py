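import numpy as np
import pytest

from nightglow.composites import AnnualComposite
from nightglow.synth import GainCurve, SatelliteSpec, SceneSpec


def make_composite(grid, year=2000, sat="F12", nodata=None, calibrated=False):
    grid = np.asarray(grid)
    if not calibrated and not np.issubdtype(grid.dtype, np.integer):
        grid = grid.astype(np.int16)
    return AnnualComposite(
        year=year, satellite_id=sat, grid=grid, nodata_mask=nodata, calibrated=calibrated
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    """A fast 96x96 single-satellite benchmark with planted changes."""
    return SceneSpec(
        shape=(96, 96),
        years=(1994, 2003),
        satellites=[SatelliteSpec("F12", 1994, 2003, GainCurve(80.0, 60.0))],
        jitter_max=2,
        noise_sd=0.3,
        seed=11,
    )


@pytest.fixture
def null_spec():
    """No events, one satellite, zero noise, zero jitter: the null scene."""
    return SceneSpec(
        shape=(96, 96),
        years=(1994, 2003),
        change_events=[],
        satellites=[SatelliteSpec("F12", 1994, 2003, GainCurve(80.0, 60.0))],
        jitter_max=0,
        noise_sd=0.0,
        seed=5,
    )
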