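"""Idealized ocean basins for driving the larval transport model.

The synthetic circulation is the analytic sum of three components that stand
in for the large-scale features relevant to inter-island larval transport in
a subtropical basin: a closed anticyclonic gyre (counterclockwise in the
Southern Hemisphere), an eastward zonal frontal jet with a Gaussian
cross-front profile, and an optional weak westward leakage corridor. Islands
are circular land masks ringed by shallow (spawning-eligible) bathymetry.

The gyre is realized through a smooth streamfunction so that its velocity has
an analytic oracle (divergence-free by construction)::

    psi(lon, lat) = A * sin^2(pi * X) * sin^2(pi * Y)     inside the gyre box
    u = -dpsi/dy,   v = +dpsi/dx                           (x, y in metres)

with X, Y the normalized box coordinates. The squared-sine profile makes the
velocity vanish smoothly on the box edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np

from ..flowfield import GriddedVelocityField
from ..geo import M_PER_DEG, haversine_km


@dataclass
class IslandSpec:
    """Circular island: land inside ``radius_km``; if ``shallow``, bathymetry is
    set shallower than 1000 m out to ``shallow_radius_km`` (spawning habitat)."""

    lon: float
    lat: float
    radius_km: float = 30.0
    shallow: bool = True
    shallow_radius_km: float = 90.0


@dataclass
class FlowFieldSpec:
    """Parameters of the synthetic basin. All speeds in m/s, lengths in degrees
    unless suffixed otherwise."""

    lon_min: float = 0.0
    lon_max: float = 60.0
    lat_min: float = -48.0
    lat_max: float = -25.0
    spacing_deg: float = 0.5
    time_span_days: float = 30.0
    time_interval_days: float = 5.0
    time_origin: date = field(default_factory=lambda: date(2000, 1, 1))
    # gyre
    gyre_center: tuple[float, float] | None = (20.0, -33.0)
    gyre_halfwidth_deg: tuple[float, float] = (18.0, 7.0)
    gyre_strength: float = 0.15
    # zonal jet
    jet_lat: float = -38.0
    jet_width_deg: float = 2.0
    jet_speed: float = 0.10
    # westward leakage corridor
    leakage: bool = False
    leakage_lat: float = -30.0
    leakage_width_deg: float = 1.5
    leakage_speed: float = 0.03
    # bathymetry
    islands: list[IslandSpec] = field(default_factory=list)
    deep_depth_m: float = 4000.0
    shallow_depth_m: float = 500.0
    seed: int = 0

    def validate(self) -> None:
        if self.spacing_deg <= 0:
            raise ValueError("grid spacing must be > 0")
        if self.jet_width_deg <= 0 or self.leakage_width_deg <= 0:
            raise ValueError("jet/corridor width must be > 0")
        for s in (self.gyre_strength, self.jet_speed, self.leakage_speed):
            if not np.isfinite(s):
                raise ValueError("component speeds must be finite")
        if self.lon_max - self.lon_min < 2 * self.spacing_deg or self.lat_max - self.lat_min < 2 * self.spacing_deg:
            raise ValueError("degenerate grid: fewer than 2 nodes on an axis")


def gyre_streamfunction(spec: FlowFieldSpec):
    """Return psi(lon, lat) in m^2/s for the spec's gyre (vectorized callable).

    The amplitude is calibrated so the peak gyre speed approximately equals
    ``spec.gyre_strength``.
    """
    if spec.gyre_center is None:
        return lambda lon, lat: np.zeros(np.broadcast(np.asarray(lon), np.asarray(lat)).shape)
    cx, cy = spec.gyre_center
    rx, ry = spec.gyre_halfwidth_deg
    lx_m = 2 * rx * M_PER_DEG * np.cos(np.deg2rad(cy))
    ly_m = 2 * ry * M_PER_DEG
    # negative extremum: counterclockwise rotation, the Southern-Hemisphere
    # anticyclonic sense (eastward flow on the gyre's southern limb)
    amp = -spec.gyre_strength / (np.pi * max(1.0 / lx_m, 1.0 / ly_m))

    def psi(lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        x = (lon - (cx - rx)) / (2 * rx)
        y = (lat - (cy - ry)) / (2 * ry)
        inside = (x >= 0) & (x <= 1) & (y >= 0) & (y <= 1)
        out = np.where(inside, amp * np.sin(np.pi * np.clip(x, 0, 1)) ** 2 * np.sin(np.pi * np.clip(y, 0, 1)) ** 2, 0.0)
        return out

    return psi


def velocity_components(spec: FlowFieldSpec, lon, lat):
    """Analytic (u, v) in m/s of the gyre + jet + leakage sum at (lon, lat)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    u = np.zeros(np.broadcast(lon, lat).shape)
    v = np.zeros_like(u)
    if spec.gyre_center is not None and spec.gyre_strength != 0:
        psi = gyre_streamfunction(spec)
        cx, cy = spec.gyre_center
        rx, ry = spec.gyre_halfwidth_deg
        # analytic derivatives of sin^2 profiles
        x = (lon - (cx - rx)) / (2 * rx)
        y = (lat - (cy - ry)) / (2 * ry)
        inside = (x >= 0) & (x <= 1) & (y >= 0) & (y <= 1)
        lx_m0 = 2 * rx * M_PER_DEG * np.cos(np.deg2rad(cy))
        ly_m = 2 * ry * M_PER_DEG
        amp = -spec.gyre_strength / (np.pi * max(1.0 / lx_m0, 1.0 / ly_m))
        # local metric for the zonal derivative (consistent with a
        # finite-difference of psi on the sphere)
        lx_m = 2 * rx * M_PER_DEG * np.cos(np.deg2rad(lat))
        sx2 = np.sin(np.pi * np.clip(x, 0, 1)) ** 2
        sy2 = np.sin(np.pi * np.clip(y, 0, 1)) ** 2
        dsx = np.pi * np.sin(2 * np.pi * np.clip(x, 0, 1)) / lx_m
        dsy = np.pi * np.sin(2 * np.pi * np.clip(y, 0, 1)) / ly_m
        u = u + np.where(inside, -amp * sx2 * dsy, 0.0)
        v = v + np.where(inside, amp * dsx * sy2, 0.0)
    if spec.jet_speed != 0:
        u = u + spec.jet_speed * np.exp(-0.5 * ((lat - spec.jet_lat) / spec.jet_width_deg) ** 2)
    if spec.leakage and spec.leakage_speed != 0:
        u = u - spec.leakage_speed * np.exp(-0.5 * ((lat - spec.leakage_lat) / spec.leakage_width_deg) ** 2)
    return u, v


def make_flow_field(spec: FlowFieldSpec) -> GriddedVelocityField:
    """Realize the spec on a regular grid (time-constant archived means)."""
    spec.validate()
    lon = np.arange(spec.lon_min, spec.lon_max + 1e-9, spec.spacing_deg)
    lat = np.arange(spec.lat_min, spec.lat_max + 1e-9, spec.spacing_deg)
    glon, glat = np.meshgrid(lon, lat)
    u, v = velocity_components(spec, glon, glat)

    mask = np.ones(glon.shape, dtype=bool)
    bathy = np.full(glon.shape, spec.deep_depth_m)
    for isl in spec.islands:
        d = haversine_km(glon, glat, isl.lon, isl.lat)
        if isl.shallow:
            bathy = np.where(d <= isl.shallow_radius_km, spec.shallow_depth_m, bathy)
        mask &= d > isl.radius_km
    if not mask.any():
        raise ValueError("no ocean cell remains unmasked")

    times = np.arange(0.0, spec.time_span_days + 1e-9, spec.time_interval_days)
    if times.size == 0:
        times = np.array([0.0])
    u3 = np.broadcast_to(u, (times.size,) + u.shape).copy()
    v3 = np.broadcast_to(v, (times.size,) + v.shape).copy()
    return GriddedVelocityField(
        lon=lon, lat=lat, time_days=times, u=u3, v=v3, mask=mask,
        bathymetry_m=bathy, time_origin=spec.time_origin,
    )
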