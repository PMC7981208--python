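"""Connectivity products derived from particle fates.

Annual matrices give, for each spawning year, the percentage of particles
released at a source site (columns) that recruited to each destination site
(rows); summary matrices give the across-year mean, standard deviation
(population convention: the simulated years are the whole population of
years) and the number of years with nonzero connectivity. Display values use
the log10(10x + 1) transform so percentages spanning orders of magnitude
remain distinguishable. Pathway densities are per-cell percentages of
successful source-to-target particles that visited the cell at least once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ibm import RECRUITED, ParticleEnsemble, VisitLog


@dataclass
class ConnectivitySummary:
    mean: pd.DataFrame
    sd: pd.DataFrame
    nonzero_years: pd.DataFrame


def _release_year(ensemble: ParticleEnsemble) -> np.ndarray:
    origin = np.datetime64(ensemble.time_origin, "D")
    dates = origin + ensemble.release_day.astype("timedelta64[D]")
    return dates.astype("datetime64[Y]").astype(int) + 1970


def build_annual_matrix(ensemble: ParticleEnsemble, sites: list[str], year: int, zone_ids: list[str] | None = None) -> pd.DataFrame:
    """Destination x source matrix of recruitment percentages for one
    release year. A site with zero releases that year gets a NaN column
    (undefined, not silently zero)."""
    zone_ids = zone_ids or sites
    years = _release_year(ensemble)
    mat = pd.DataFrame(np.nan, index=list(zone_ids), columns=list(sites))
    for j, src in enumerate(sites):
        si = ensemble.site_ids.index(src)
        rel = (ensemble.source == si) & (years == year)
        n_rel = int(rel.sum())
        if n_rel == 0:
            continue  # column stays NaN
        rec = rel & (ensemble.state == RECRUITED)
        for i, dst in enumerate(zone_ids):
            n_rec = int(np.sum(rec & (ensemble.recruit_zone == i)))
            mat.loc[dst, src] = 100.0 * n_rec / n_rel
    return mat


def summarize(matrices: list[pd.DataFrame]) -> ConnectivitySummary:
    """Element-wise mean, population SD and count of years with entry > 0."""
    if not matrices:
        raise ValueError("need at least one annual matrix")
    ref = matrices[0]
    for m in matrices[1:]:
        if not (m.index.equals(ref.index) and m.columns.equals(ref.columns)):
            raise ValueError("annual matrices have mismatched site sets")
    stack = np.stack([m.values for m in matrices])
    mean = pd.DataFrame(stack.mean(axis=0), index=ref.index, columns=ref.columns)
    sd = pd.DataFrame(stack.std(axis=0, ddof=0), index=ref.index, columns=ref.columns)
    nonzero = pd.DataFrame((stack > 0).sum(axis=0), index=ref.index, columns=ref.columns)
    return ConnectivitySummary(mean=mean, sd=sd, nonzero_years=nonzero)


def log_transform(x):
    """log10(10x + 1): maps 0 -> 0 and compresses large percentages."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("percentages must be >= 0")
    return np.log10(10.0 * x + 1.0)


def pathway_density(log: VisitLog, ensemble: ParticleEnsemble, source: str, target: str, zone_ids: list[str]) -> np.ndarray:
    """Per-cell percentage of successful source->target particles that passed
    through each grid cell (counted once per particle)."""
    si = ensemble.site_ids.index(source)
    zi = zone_ids.index(target)
    ok = (ensemble.source == si) & (ensemble.state == RECRUITED) & (ensemble.recruit_zone == zi)
    winners = np.flatnonzero(ok)
    if winners.size == 0:
        raise ValueError(f"no successful {source}->{target} particles")
    sel = np.isin(log.particle, winners)
    counts = np.bincount(log.cell[sel], minlength=log.grid_shape[0] * log.grid_shape[1])
    dens = 100.0 * counts.reshape(log.grid_shape) / winners.size
    return dens
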