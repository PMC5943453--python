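import numpy as np
import pytest

from mapsdemog import data_io
from mapsdemog.data_io import CaptureHistory, StationRecord


def make_station(
    station_id="W01",
    region="west",
    longitude=-114.0,
    latitude=55.2,
    hf=10.0,
    active_years=range(1993, 2017),
    effort=500.0,
):
    active = frozenset(active_years)
    return StationRecord(
        station_id=station_id,
        region=region,
        longitude=longitude,
        latitude=latitude,
        hf_1993_1km=hf,
        hf_2009_1km=hf,
        hf_1993_10km=hf,
        hf_2009_10km=hf,
        active_years=active,
        effort_by_year={y: effort for y in sorted(active)},
        hf_1km=hf,
        hf_10km=hf,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def tiny_stations():
    """Two west stations with different footprints (so z-scoring works)."""
    return [
        make_station("W01", hf=8.0),
        make_station("W02", hf=12.0, longitude=-113.0, latitude=54.0),
    ]


def make_history(detections, first=None, sex=0, station_id="W01",
                 predetermined=0, individual_id="i1"):
    y = tuple(detections)
    if first is None:
        first = y.index(1)
    return CaptureHistory(
        individual_id=individual_id,
        station_id=station_id,
        sex=sex,
        first_year=first,
        detections=y,
        predetermined=predetermined,
    )
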