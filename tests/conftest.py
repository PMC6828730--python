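import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from cmscreen.platemodel import PlateMap, WellCondition, WellTimeSeries
from cmscreen.simulate import ImagingParams, SimulationConfig


@pytest.fixture
def toy_platemap() -> PlateMap:
    """384-format plate: 2 vehicle controls + 2 treated wells at 333 cells/mm^2."""
    return PlateMap(
        plate_id="toy",
        plate_format=384,
        wells={
            "A01": WellCondition(role="control", compound_id="DMSO", plating_density=333),
            "A02": WellCondition(role="control", compound_id="DMSO", plating_density=333),
            "A03": WellCondition(role="treated", compound_id="CMPD-1",
                                 concentration_um=10.0, plating_density=333),
            "A04": WellCondition(role="treated", compound_id="CMPD-2",
                                 concentration_um=10.0, plating_density=333),
        },
    )


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """Simulation config with a ~0.59 mm^2 arena (~200 cells at 333/mm^2)."""
    return SimulationConfig(
        seed=11,
        n_timepoints=7,
        imaging=ImagingParams(tile_grid=(2, 2), tile_px=200, tile_overlap_px=16),
    )


def series(counts, well="A01", dt=12.0):
    """Shorthand to build a WellTimeSeries from a count list."""
    counts = list(counts)
    return WellTimeSeries(
        well=well, times_h=np.arange(len(counts)) * dt, counts=np.asarray(counts)
    )


@pytest.fixture
def make_series():
    return series
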