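import numpy as np
import pandas as pd
import pytest

from ternflight import synthetic as syn
from ternflight import tracks as trk


@pytest.fixture(scope="session")
def coarse_landscape():
    """2500 km square, 5 km pixels, 30% uniform-random water."""
    return syn.generate_landscape(syn.LandscapeSpec(
        seed=1, width=500, height=500, resolution=5000.0, water_fraction=0.3))


@pytest.fixture(scope="session")
def fine_landscape():
    """200 km square, 500 m pixels (the MODIS-like scale)."""
    return syn.generate_landscape(syn.LandscapeSpec(
        seed=2, width=400, height=400, resolution=500.0, water_fraction=0.3))


@pytest.fixture(scope="session")
def flat_dem(coarse_landscape):
    return syn.generate_dem(3, coarse_landscape, relief_m=0.0, base_m=100.0)


@pytest.fixture(scope="session")
def rough_dem(coarse_landscape):
    return syn.generate_dem(3, coarse_landscape, relief_m=200.0)


@pytest.fixture(scope="session")
def std_trackspec():
    """8-day southbound track with one 2-day stopover on days 3-4."""
    return syn.TrackSpec(seed=3, n_days=8, stopover_schedule=((3, 2),),
                         start=(11.0, 21.5), heading=180.0, cruise_speed=30.0,
                         flight_prob_day=1.0, flight_prob_night=0.0)


@pytest.fixture(scope="session")
def std_track(std_trackspec, coarse_landscape, rough_dem):
    return syn.generate_track(std_trackspec, coarse_landscape, rough_dem)


@pytest.fixture(scope="session")
def processed_track(std_track):
    fixes, _ = std_track
    return trk.process_tracks(fixes)
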