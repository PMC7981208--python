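from datetime import date

import numpy as np
import pytest

from seaconnect.flowfield import AnalyticField, GriddedVelocityField


def make_uniform_field(u=0.1, v=0.0, lon0=0.0, lon1=10.0, lat0=-45.0, lat1=-35.0,
                       spacing=0.5, depth=4000.0):
    """Steady spatially uniform gridded field, all ocean."""
    lon = np.arange(lon0, lon1 + 1e-9, spacing)
    lat = np.arange(lat0, lat1 + 1e-9, spacing)
    shape = (lat.size, lon.size)
    return GriddedVelocityField(
        lon=lon, lat=lat, time_days=[0.0],
        u=np.full((1,) + shape, float(u)), v=np.full((1,) + shape, float(v)),
        mask=np.ones(shape, dtype=bool), bathymetry_m=np.full(shape, depth),
        time_origin=date(2000, 1, 1),
    )


@pytest.fixture
def uniform_field():
    return make_uniform_field()


@pytest.fixture
def still_field():
    return make_uniform_field(u=0.0, v=0.0)


@pytest.fixture
def analytic_uniform():
    return AnalyticField(u_fn=lambda lon, lat, t: 0.1, v_fn=lambda lon, lat, t: 0.0)
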