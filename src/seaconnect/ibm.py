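"""Lagrangian individual-based larval transport.

Particles representing phyllosoma larvae are released daily over a spawning
window from shallow (< 1000 m) grid cells near each population site, advected
by archived mean currents with a midpoint second-order Runge-Kutta scheme at a
30-minute time step, dispersed by a random-walk parameterization of
unresolved turbulence, and confined vertically to the upper 200 m by
reflection. A larva that enters a recruitment zone (grid cells within 100 km
of a population site) once competent (age >= 15 months) is recruited there
and removed; larvae that exhaust the maximum planktonic duration (22 months)
expire. There is no mortality and no behaviour (no vertical migration or
swimming): connectivity is purely physical transport.

Ages are gated in 30.44-day months (15 months = 456.6 d, 22 months = 669.7 d)
for calendar-free reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np

from .flowfield import AnalyticField, GriddedVelocityField
from .geo import haversine_km, meters_to_degrees

DAYS_PER_MONTH = 30.44

# particle states
ACTIVE, RECRUITED, EXPIRED, LOST = 0, 1, 2, 3
STATE_NAMES = {ACTIVE: "active", RECRUITED: "recruited", EXPIRED: "expired", LOST: "lost"}


@dataclass
class ReleaseSite:
    site_id: str
    lon: float
    lat: float


@dataclass
class ReleaseSpec:
    """Release scheduling: daily cohorts from every eligible grid cell.

    Eligible cells are ocean cells shallower than ``shallow_criterion_m``
    within ``association_radius_km`` of the site coordinate.
    """

    sites: list[ReleaseSite]
    particles_per_cell_per_day: int = 100
    spawning_months: tuple[int, ...] = (8, 9, 10)
    years: tuple[int, ...] = (2000,)
    shallow_criterion_m: float = 1000.0
    association_radius_km: float = 100.0
    depth_range_m: tuple[float, float] = (0.0, 200.0)
    seed: int = 0

    def validate(self) -> None:
        if self.particles_per_cell_per_day < 1:
            raise ValueError("particles per cell per day must be >= 1")
        if not self.spawning_months:
            raise ValueError("spawning window is empty")
        if not (0 <= self.depth_range_m[0] < self.depth_range_m[1] <= 200.0 + 1e-9):
            raise ValueError("initial depth range must lie within the 0-200 m layer")


@dataclass
class RecruitmentZone:
    site_id: str
    lon: float
    lat: float
    radius_km: float = 100.0

    def __post_init__(self):
        if self.radius_km <= 0:
            raise ValueError("zone radius must be > 0")


@dataclass
class PldWindow:
    """Competency window in months (30.44-day blocks)."""

    min_months: float = 15.0
    max_months: float = 22.0

    def __post_init__(self):
        if not 0 < self.min_months < self.max_months:
            raise ValueError("require 0 < min < max competency months")

    @property
    def min_days(self) -> float:
        return self.min_months * DAYS_PER_MONTH

    @property
    def max_days(self) -> float:
        return self.max_months * DAYS_PER_MONTH


@dataclass
class DiffusionSpec:
    kh_m2s: float = 100.0      # horizontal eddy diffusivity
    kv_m2s: float = 1e-4       # vertical eddy diffusivity
    dt_minutes: float = 30.0
    seed: int = 0

    def __post_init__(self):
        if self.kh_m2s < 0 or self.kv_m2s < 0:
            raise ValueError("diffusivities must be >= 0")
        if self.dt_minutes <= 0:
            raise ValueError("time step must be > 0")

    @property
    def dt_seconds(self) -> float:
        return self.dt_minutes * 60.0


@dataclass
class ParticleEnsemble:
    """Columnar particle store (one entry per particle)."""

    source: np.ndarray          # index into site_ids
    release_day: np.ndarray     # days on the field time axis
    lon: np.ndarray
    lat: np.ndarray
    depth: np.ndarray
    age_days: np.ndarray
    state: np.ndarray           # ACTIVE/RECRUITED/EXPIRED/LOST
    recruit_zone: np.ndarray    # index into zone ids, -1 if none
    recruit_day: np.ndarray     # nan if none
    site_ids: list[str] = field(default_factory=list)
    time_origin: date = field(default_factory=lambda: date(2000, 1, 1))

    def __len__(self) -> int:
        return self.source.size

    def counts(self) -> dict[str, int]:
        return {name: int(np.sum(self.state == code)) for code, name in STATE_NAMES.items()}

    def to_frame(self, zone_ids: list[str] | None = None):
        import pandas as pd

        rec = np.asarray(zone_ids, dtype=object)[self.recruit_zone] if zone_ids is not None else self.recruit_zone
        rec = np.where(self.recruit_zone >= 0, rec, None)
        return pd.DataFrame(
            {
                "source": np.asarray(self.site_ids, dtype=object)[self.source],
                "release_date": [self.time_origin + timedelta(days=float(d)) for d in self.release_day],
                "fate": [STATE_NAMES[s] for s in self.state],
                "age_days": self.age_days,
                "recruit_zone": rec,
                "recruit_day": self.recruit_day,
            }
        )


class ReleaseSiteError(ValueError):
    """A release site has no eligible (shallow, ocean) grid cell."""


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

def advect_rk2(fld, lon, lat, t_days, dt_s):
    """Midpoint RK2 step. Positions in degrees, dt in seconds, t in days.

    The ODE is integrated in degree coordinates: velocities (m/s) are
    converted to deg/s at the latitude of each evaluation point, which keeps
    the scheme second-order through the metric factor.
    """
    u1, v1 = fld.velocity(lon, lat, t_days)
    dlon1, dlat1 = meters_to_degrees(u1 * dt_s * 0.5, v1 * dt_s * 0.5, lat)
    mid_lon, mid_lat = lon + dlon1, lat + dlat1
    t_mid = t_days + dt_s / 86400.0 / 2.0
    u2, v2 = fld.velocity(mid_lon, mid_lat, t_mid)
    dlon, dlat = meters_to_degrees(u2 * dt_s, v2 * dt_s, mid_lat)
    return lon + dlon, lat + dlat


def random_walk_step(spec: DiffusionSpec, rng: np.random.Generator, n: int):
    """Gaussian displacements (metres) with per-axis variance 2*K*dt."""
    dt = spec.dt_seconds
    dx = rng.normal(0.0, np.sqrt(2.0 * spec.kh_m2s * dt), size=n)
    dy = rng.normal(0.0, np.sqrt(2.0 * spec.kh_m2s * dt), size=n)
    dz = rng.normal(0.0, np.sqrt(2.0 * spec.kv_m2s * dt), size=n)
    return dx, dy, dz


def reflect_depth(depth, max_depth=200.0):
    """Reflect depths into [0, max_depth] (triangle-wave fold)."""
    d = np.mod(np.asarray(depth, dtype=float), 2.0 * max_depth)
    return np.where(d > max_depth, 2.0 * max_depth - d, d)


# ---------------------------------------------------------------------------
# release scheduling
# ---------------------------------------------------------------------------

def eligible_cells(fld: GriddedVelocityField, site: ReleaseSite, spec: ReleaseSpec):
    glon, glat = np.meshgrid(fld.lon, fld.lat)
    d = haversine_km(glon, glat, site.lon, site.lat)
    ok = fld.mask & (fld.bathymetry_m < spec.shallow_criterion_m) & (d <= spec.association_radius_km)
    return np.flatnonzero(ok.ravel())


def _spawning_days(fld, spec: ReleaseSpec):
    days = []
    for year in spec.years:
        d = date(year, min(spec.spawning_months), 1)
        while d.year == year and d.month in spec.spawning_months:
            days.append(fld.day_of(d))
            d += timedelta(days=1)
    return np.asarray(days, dtype=float)


def schedule_releases(fld: GriddedVelocityField, spec: ReleaseSpec) -> ParticleEnsemble:
    """Initial ensemble: ``rate`` particles per eligible cell per spawning day,
    positioned at the cell node with uniform-random initial depth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    glon, glat = np.meshgrid(fld.lon, fld.lat)
    flat_lon, flat_lat = glon.ravel(), glat.ravel()

    days = _spawning_days(fld, spec)
    src, rel, lons, lats = [], [], [], []
    for si, site in enumerate(spec.sites):
        cells = eligible_cells(fld, site, spec)
        if cells.size == 0:
            raise ReleaseSiteError(f"release site {site.site_id!r} has no eligible grid cell")
        n_per_day = cells.size * spec.particles_per_cell_per_day
        for day in days:
            src.append(np.full(n_per_day, si, dtype=np.int32))
            rel.append(np.full(n_per_day, day))
            lons.append(np.repeat(flat_lon[cells], spec.particles_per_cell_per_day))
            lats.append(np.repeat(flat_lat[cells], spec.particles_per_cell_per_day))
    src = np.concatenate(src)
    n = src.size
    d0, d1 = spec.depth_range_m
    return ParticleEnsemble(
        source=src,
        release_day=np.concatenate(rel),
        lon=np.concatenate(lons),
        lat=np.concatenate(lats),
        depth=rng.uniform(d0, d1, size=n),
        age_days=np.zeros(n),
        state=np.full(n, ACTIVE, dtype=np.int8),
        recruit_zone=np.full(n, -1, dtype=np.int32),
        recruit_day=np.full(n, np.nan),
        site_ids=[s.site_id for s in spec.sites],
        time_origin=fld.time_origin,
    )


# ---------------------------------------------------------------------------
# main loop
# ---------------------------------------------------------------------------

@dataclass
class VisitLog:
    """Decimated cell-visit log: unique (particle, cell) pairs."""

    particle: np.ndarray
    cell: np.ndarray
    grid_shape: tuple[int, int]


def _apply_boundary(fld, lon0, lat0, lon1, lat1, policy):
    """Resolve proposed moves that land on land or leave the domain.

    slide: try the zonal-only then meridional-only move, else stay put.
    reflect: bounce back to the start position.
    halt: freeze at the start position.
    Leaving the domain marks the particle lost under every policy.
    """
    lost = ~fld.contains(lon1, lat1)
    on_land = np.zeros_like(lost)
    inb = ~lost
    if np.any(inb):
        on_land[inb] = fld.is_land(lon1[inb], lat1[inb])
    bad = on_land & ~lost
    if np.any(bad):
        if policy == "slide":
            # zonal-only candidate
            cand_lon, cand_lat = lon1.copy(), lat0.copy()
            ok_z = np.zeros_like(bad)
            ok_z[bad] = fld.contains(cand_lon[bad], cand_lat[bad]) & ~fld.is_land(cand_lon[bad], cand_lat[bad])
            take = bad & ok_z
            lat1[take] = lat0[take]
            rem = bad & ~ok_z
            if np.any(rem):
                ok_m = np.zeros_like(bad)
                ok_m[rem] = fld.contains(lon0[rem], lat1[rem]) & ~fld.is_land(lon0[rem], lat1[rem])
                take_m = rem & ok_m
                lon1[take_m] = lon0[take_m]
                stay = rem & ~ok_m
                lon1[stay], lat1[stay] = lon0[stay], lat0[stay]
        elif policy in ("reflect", "halt"):
            lon1[bad], lat1[bad] = lon0[bad], lat0[bad]
        else:
            raise ValueError(f"unknown boundary policy {policy!r}")
    return lon1, lat1, lost


def run_simulation(
    fld,
    ensemble: ParticleEnsemble,
    zones: list[RecruitmentZone],
    pld: PldWindow,
    diffusion: DiffusionSpec,
    boundary: str = "slide",
    record_visits: bool = False,
    visit_interval_hours: float = 12.0,
    max_depth_m: float = 200.0,
):
    """Advance the ensemble to its final fates. Returns (ensemble, VisitLog|None).

    Per step and per active, already-released particle: RK2 advection,
    random-walk diffusion (vertical reflection at the surface and at the
    confinement depth), boundary policy, ageing, then recruitment/expiry
    checks. Particle conservation (released = active + recruited + expired +
    lost) is asserted every step.
    """
    gridded = isinstance(fld, GriddedVelocityField)
    if gridded and not fld.steady:
        need = ensemble.release_day.max() + pld.max_days
        if fld.time_days[-1] < need:
            raise ValueError(
                f"field time coverage ends at day {fld.time_days[-1]:.1f} but the run needs day {need:.1f}"
            )
    rng = np.random.default_rng(diffusion.seed)
    dt_s = diffusion.dt_seconds
    dt_d = dt_s / 86400.0
    t = float(ensemble.release_day.min())
    t_end = float(ensemble.release_day.max() + pld.max_days)
    n = len(ensemble)

    zlon = np.array([z.lon for z in zones])
    zlat = np.array([z.lat for z in zones])
    zrad = np.array([z.radius_km for z in zones])

    visits_p: list[np.ndarray] = []
    visits_c: list[np.ndarray] = []
    visit_every = max(int(round(visit_interval_hours * 3600.0 / dt_s)), 1)
    step = 0
    while t < t_end - 1e-9:
        live = (ensemble.state == ACTIVE) & (ensemble.release_day <= t + 1e-9)
        if np.any(live):
            idx = np.flatnonzero(live)
            lon0, lat0 = ensemble.lon[idx], ensemble.lat[idx]
            lon1, lat1 = advect_rk2(fld, lon0, lat0, t, dt_s)
            dx, dy, dz = random_walk_step(diffusion, rng, idx.size)
            dlon, dlat = meters_to_degrees(dx, dy, lat1)
            lon1, lat1 = lon1 + dlon, lat1 + dlat
            lon1, lat1, lost = _apply_boundary(fld, lon0, lat0, lon1, lat1, boundary)
            ensemble.lon[idx] = lon1
            ensemble.lat[idx] = lat1
            ensemble.depth[idx] = reflect_depth(ensemble.depth[idx] + dz, max_depth_m)
            ensemble.age_days[idx] += dt_d
            ensemble.state[idx[lost]] = LOST

            if record_visits and gridded and step % visit_every == 0:
                keep = idx[~lost]
                ii, jj = fld.cell_index(ensemble.lon[keep], ensemble.lat[keep])
                visits_p.append(keep.astype(np.int64))
                visits_c.append((ii * fld.lon.size + jj).astype(np.int64))

            # recruitment: competent particle inside any zone
            comp = idx[(ensemble.state[idx] == ACTIVE) & (ensemble.age_days[idx] >= pld.min_days - 1e-9)]
            if comp.size:
                d = haversine_km(
                    ensemble.lon[comp][:, None], ensemble.lat[comp][:, None], zlon[None, :], zlat[None, :]
                )
                inzone = d <= zrad[None, :]
                hit = inzone.any(axis=1)
                if np.any(hit):
                    first = np.argmax(inzone[hit], axis=1)
                    who = comp[hit]
                    ensemble.state[who] = RECRUITED
                    ensemble.recruit_zone[who] = first
                    ensemble.recruit_day[who] = t + dt_d

            # expiry
            old = idx[(ensemble.state[idx] == ACTIVE) & (ensemble.age_days[idx] >= pld.max_days - 1e-9)]
            ensemble.state[old] = EXPIRED

        c = ensemble.counts()
        assert sum(c.values()) == n, "particle conservation violated"
        t += dt_d
        step += 1

    log = None
    if record_visits and gridded:
        if visits_p:
            p = np.concatenate(visits_p)
            cc = np.concatenate(visits_c)
            uniq = np.unique(np.stack([p, cc], axis=1), axis=0)
            log = VisitLog(particle=uniq[:, 0], cell=uniq[:, 1], grid_shape=(fld.lat.size, fld.lon.size))
        else:
            log = VisitLog(
                particle=np.empty(0, dtype=np.int64),
                cell=np.empty(0, dtype=np.int64),
                grid_shape=(fld.lat.size, fld.lon.size),
            )
    return ensemble, log
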