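"""Gridded ocean-velocity fields and analytic test fields.

The transport model is driven by time series of gridded horizontal velocity
(archived multi-day means, 5-day by convention). A field carries u/v on a
regular lon/lat grid, a land mask, and bathymetry. Velocities are multilinearly
interpolated in space and linearly in time; land cells carry zero velocity so
interpolation decays smoothly toward the coast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import xarray as xr


class OutOfDomainError(ValueError):
    """Query point outside the field's spatial hull or fully on land."""


@dataclass
class GriddedVelocityField:
    """Time-stamped u/v on a regular lon/lat grid with land mask and bathymetry.

    Parameters
    ----------
    lon, lat : 1-D arrays, strictly monotonic increasing (degrees E / N).
    time_days : 1-D array of time stamps in days since ``time_origin``
        (strictly increasing). A single stamp denotes a steady field.
    u, v : arrays of shape (nt, nlat, nlon), m/s; zero on land cells.
    mask : bool array (nlat, nlon), True where ocean.
    bathymetry_m : array (nlat, nlon), water depth in metres (positive down).
    time_origin : calendar date of day 0 on the time axis.
    """

    lon: np.ndarray
    lat: np.ndarray
    time_days: np.ndarray
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    bathymetry_m: np.ndarray
    time_origin: date = field(default_factory=lambda: date(2000, 1, 1))

    def __post_init__(self):
        self.lon = np.asarray(self.lon, dtype=float)
        self.lat = np.asarray(self.lat, dtype=float)
        self.time_days = np.atleast_1d(np.asarray(self.time_days, dtype=float))
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.bathymetry_m = np.asarray(self.bathymetry_m, dtype=float)
        if self.lon.size <= 1 or self.lat.size <= 1:
            raise ValueError("degenerate grid: need at least 2 nodes per axis")
        for name, arr in (("lon", self.lon), ("lat", self.lat)):
            if not np.all(np.diff(arr) > 0):
                raise ValueError(f"{name} must be strictly increasing")
        if self.time_days.size > 1 and not np.all(np.diff(self.time_days) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if self.u.ndim == 2:
            self.u = self.u[None]
        if self.v.ndim == 2:
            self.v = self.v[None]
        shape = (self.time_days.size, self.lat.size, self.lon.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError(f"u/v must have shape {shape}")
        if not (np.all(np.isfinite(self.u[:, self.mask])) and np.all(np.isfinite(self.v[:, self.mask]))):
            raise ValueError("non-finite velocity on ocean cells")
        # masked cells carry no velocity
        self.u = np.where(self.mask[None], self.u, 0.0)
        self.v = np.where(self.mask[None], self.v, 0.0)

    # -- geometry -----------------------------------------------------------

    @property
    def steady(self) -> bool:
        return self.time_days.size == 1

    def contains(self, lon, lat):
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (
            (lon >= self.lon[0]) & (lon <= self.lon[-1])
            & (lat >= self.lat[0]) & (lat <= self.lat[-1])
        )

    def cell_index(self, lon, lat):
        """Nearest-node (row, col) index; used for visit logging and land tests."""
        lat_mid = 0.5 * (self.lat[:-1] + self.lat[1:])
        lon_mid = 0.5 * (self.lon[:-1] + self.lon[1:])
        i = np.searchsorted(lat_mid, np.atleast_1d(lat))
        j = np.searchsorted(lon_mid, np.atleast_1d(lon))
        return i, j

    def is_land(self, lon, lat):
        i, j = self.cell_index(np.atleast_1d(lon), np.atleast_1d(lat))
        return ~self.mask[i, j]

    # -- interpolation ------------------------------------------------------

    def _time_bracket(self, t):
        if self.steady:
            return 0, 0, 0.0
        tt = np.clip(t, self.time_days[0], self.time_days[-1])
        k = int(np.searchsorted(self.time_days, tt, side="right") - 1)
        k = min(max(k, 0), self.time_days.size - 2)
        w = (tt - self.time_days[k]) / (self.time_days[k + 1] - self.time_days[k])
        return k, k + 1, float(w)

    def velocity(self, lon, lat, t):
        """Vectorized (u, v) in m/s at points (lon, lat) and scalar time t (days).

        Points outside the hull get zero velocity (callers apply the boundary
        policy separately); land proximity decays to zero via the masked grid.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        inside = self.contains(lon, lat)
        x = np.clip(lon, self.lon[0], self.lon[-1])
        y = np.clip(lat, self.lat[0], self.lat[-1])
        j = np.clip(np.searchsorted(self.lon, x, side="right") - 1, 0, self.lon.size - 2)
        i = np.clip(np.searchsorted(self.lat, y, side="right") - 1, 0, self.lat.size - 2)
        fx = (x - self.lon[j]) / (self.lon[j + 1] - self.lon[j])
        fy = (y - self.lat[i]) / (self.lat[i + 1] - self.lat[i])
        k0, k1, wt = self._time_bracket(float(t))

        def bilin(a2d):
            return (
                a2d[i, j] * (1 - fx) * (1 - fy)
                + a2d[i, j + 1] * fx * (1 - fy)
                + a2d[i + 1, j] * (1 - fx) * fy
                + a2d[i + 1, j + 1] * fx * fy
            )

        uu = (1 - wt) * bilin(self.u[k0]) + wt * bilin(self.u[k1])
        vv = (1 - wt) * bilin(self.v[k0]) + wt * bilin(self.v[k1])
        uu = np.where(inside, uu, 0.0)
        vv = np.where(inside, vv, 0.0)
        return uu, vv

    # -- calendar -----------------------------------------------------------

    def day_of(self, when: date) -> float:
        return float((when - self.time_origin).days)

    def date_of(self, day: float) -> date:
        return self.time_origin + timedelta(days=float(day))

    # -- I/O ----------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "u": (("time", "lat", "lon"), self.u, {"units": "m s-1"}),
                "v": (("time", "lat", "lon"), self.v, {"units": "m s-1"}),
                "mask": (("lat", "lon"), self.mask.astype(np.int8), {"long_name": "ocean mask (1=ocean)"}),
                "bathymetry": (("lat", "lon"), self.bathymetry_m, {"units": "m", "positive": "down"}),
            },
            coords={
                "lon": ("lon", self.lon, {"units": "degrees_east"}),
                "lat": ("lat", self.lat, {"units": "degrees_north"}),
                "time": ("time", self.time_days, {"units": f"days since {self.time_origin.isoformat()}"}),
            },
        )

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_netcdf(cls, path, names=None) -> "GriddedVelocityField":
        """Read a field written by :meth:`to_netcdf` or any CF-style file.

        ``names`` maps the canonical variable names (u, v, mask, bathymetry,
        lon, lat, time) to the names used in the file.
        """
        names = {**{k: k for k in ("u", "v", "mask", "bathymetry", "lon", "lat", "time")}, **(names or {})}
        ds = xr.open_dataset(path, engine="scipy", decode_times=False)
        tvar = ds[names["time"]]
        units = tvar.attrs.get("units", "days since 2000-01-01")
        origin = date.fromisoformat(units.split("since", 1)[1].strip().split()[0])
        return cls(
            lon=ds[names["lon"]].values,
            lat=ds[names["lat"]].values,
            time_days=tvar.values,
            u=ds[names["u"]].values,
            v=ds[names["v"]].values,
            mask=ds[names["mask"]].values.astype(bool),
            bathymetry_m=ds[names["bathymetry"]].values,
            time_origin=origin,
        )


@dataclass
class AnalyticField:
    """Velocity field defined by callables u(lon, lat, t), v(lon, lat, t).

    Used for closed-form trajectory oracles (uniform flow, solid-body
    rotation) where grid interpolation error would mask time-stepping error.
    """

    u_fn: callable
    v_fn: callable
    time_origin: date = field(default_factory=lambda: date(2000, 1, 1))

    def velocity(self, lon, lat, t):
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        return (
            np.broadcast_to(np.asarray(self.u_fn(lon, lat, t), dtype=float), lon.shape).copy(),
            np.broadcast_to(np.asarray(self.v_fn(lon, lat, t), dtype=float), lon.shape).copy(),
        )

    def contains(self, lon, lat):
        return np.ones(np.shape(np.atleast_1d(lon)), dtype=bool)

    def is_land(self, lon, lat):
        return np.zeros(np.shape(np.atleast_1d(lon)), dtype=bool)


def interpolate_velocity(f, lon, lat, depth=None, time=0.0):
    """Interpolated (u, v) at a single query point, m/s.

    Raises :class:`OutOfDomainError` for points outside the grid hull or in a
    cell whose four surrounding nodes are all land. ``depth`` is accepted for
    interface compatibility; fields are depth-independent (larvae are confined
    to the surface layer, where the archived means apply).
    """
    if isinstance(f, AnalyticField):
        uu, vv = f.velocity(lon, lat, time)
        return float(uu[0]), float(vv[0])
    if not bool(np.all(f.contains(lon, lat))):
        raise OutOfDomainError(f"point ({lon}, {lat}) outside field domain")
    j = int(np.clip(np.searchsorted(f.lon, lon, side="right") - 1, 0, f.lon.size - 2))
    i = int(np.clip(np.searchsorted(f.lat, lat, side="right") - 1, 0, f.lat.size - 2))
    if not f.mask[i : i + 2, j : j + 2].any():
        raise OutOfDomainError(f"point ({lon}, {lat}) lies in an all-land cell")
    uu, vv = f.velocity(lon, lat, time)
    return float(uu[0]), float(vv[0])
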