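"""Frozen simulation-study protocols for the divergence-model machinery.

Two desk-scale studies validate the JSFS inference stack end to end:

* the **recovery study** simulates a folded JSFS under isolation-with-
  migration (IM) at known parameters (10,000 unlinked RAD-like loci,
  moderate asymmetric migration), fits IM with 20 replicate restarts, and
  reports relative errors on the split time and both migration rates;
* the **selection-consistency study** simulates replicate datasets under IM
  at reduced scale and checks how often IM attains the best AIC against the
  nested strict-isolation (SI) and secondary-contact (SC) alternatives.

Both use the absolute-rate (anchored) composite likelihood: the synthetic
data's per-locus mutation rate is known by design, so the spectrum total
legitimately anchors the time/size scale. Replicate datasets in the
selection study are fitted with warm starts from the previous dataset's
fits (all datasets share one generating truth), which keeps every fit
locally optimized at a fraction of the cold-start cost; a full cold-start
fit is used for the first dataset.

All seeds are fixed protocol constants; results are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .demography import ModelFitResult, fit_model, fit_scenarios
from .synth import ScenarioSimSpec, simulate_jsfs

#: generating truth for both studies: moderate asymmetric gene flow since
#: divergence (T in 2*N_ref generations; M in 2*N_ref*m units)
IM_TRUTH: dict[str, float] = {"nu1": 1.0, "nu2": 1.0, "T_S": 2.0, "M12": 1.0, "M21": 0.4}

#: per-locus scaled mutation rate of the synthetic RAD loci
LOCUS_THETA: float = 0.1


@dataclass
class RecoveryResult:
    true_params: dict[str, float]
    fit: ModelFitResult
    relative_errors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not self.relative_errors:
            self.relative_errors = {
                k: abs(self.fit.params[k] - v) / v for k, v in self.true_params.items()
            }


def recovery_study(n_loci: int = 10_000, n_haploid: int = 14, data_seed: int = 11,
                   fit_seed: int = 1, n_replicates: int = 20) -> RecoveryResult:
    """Simulate an IM dataset at known parameters and fit IM back."""
    spec = ScenarioSimSpec("IM", IM_TRUTH, n1=n_haploid, n2=n_haploid,
                           n_loci=n_loci, seed=data_seed, locus_theta=LOCUS_THETA)
    observed = simulate_jsfs(spec)
    anchor = n_loci * LOCUS_THETA / 4.0
    fit = fit_model(observed, "IM", n_replicates=n_replicates, seed=fit_seed,
                    anchor=anchor, n_reps_rank=6000, n_reps_final=12_000)
    return RecoveryResult(true_params=IM_TRUTH, fit=fit)


def selection_study(n_datasets: int = 20, n_loci: int = 700, n_haploid: int = 8,
                    base_seed: int = 200, scenarios=("SI", "IM", "SC")) -> pd.DataFrame:
    """Replicate model-selection experiment at reduced scale.

    The dataset size balances two discriminations: the gap to the badly
    wrong SI model grows with the number of sites, while the IM-vs-SC
    comparison is decided by a fixed AIC penalty of 2, so Monte-Carlo
    evaluation noise (which grows with the number of sites at fixed
    replication) must stay well below it.

    Returns one row per dataset with each scenario's AIC and the winner.
    """
    anchor = n_loci * LOCUS_THETA / 4.0
    cold = dict(n_replicates=3, n_scan=60, scan_reps=150,
                candidate_schedule=[(0.4, 200, 14)] * 2,
                polish_schedule=[(0.25, 300, 12), (0.12, 600, 12)],
                block_cycles=1, block_schedule=[(0.18, 1000, 8)],
                n_reps_rank=1500, n_reps_final=5000, anchor=anchor)
    warm = dict(cold, n_replicates=1, n_scan=0,
                candidate_schedule=[],
                polish_schedule=[],
                block_schedule=[(0.15, 500, 8)])
    rows = []
    prev: dict[str, ModelFitResult] | None = None
    for r in range(n_datasets):
        seed = base_seed + r
        obs = simulate_jsfs(ScenarioSimSpec("IM", IM_TRUTH, n1=n_haploid, n2=n_haploid,
                                            n_loci=n_loci, seed=seed,
                                            locus_theta=LOCUS_THETA))
        extra = None if prev is None else {s: [f.params] for s, f in prev.items()}
        fits = fit_scenarios(obs, scenarios, seed=seed, extra_warm=extra,
                             **(cold if prev is None else warm))
        prev = fits
        row = {"dataset": r, "seed": seed}
        row.update({f"AIC_{s}": f.aic for s, f in fits.items()})
        row["winner"] = min(fits, key=lambda s: fits[s].aic)
        rows.append(row)
    return pd.DataFrame(rows).set_index("dataset")


# ---------------------------------------------------------------------------
# Lagrangian two-island dispersal study
# ---------------------------------------------------------------------------

def two_island_dispersal_study(seed: int = 0, particles_per_cell_per_day: int = 1,
                               record_visits: bool = False):
    """Gyre-plus-jet basin with two island sites in the eastward jet.

    Island A sits ~46 degrees upstream of island B at the jet core latitude,
    so the jet transit time (~0.1 m/s) lands arrivals just inside the
    15-22-month competency window; the anticyclonic gyre occupies the basin
    north of the jet. The run demonstrates jet-direction asymmetry: A seeds
    B's recruitment zone, while B's larvae exit the basin downstream.

    Returns (annual connectivity matrix, final ensemble, field, visit log).
    """
    from .connectivity import build_annual_matrix
    from .ibm import (DiffusionSpec, PldWindow, RecruitmentZone, ReleaseSite,
                      ReleaseSpec, run_simulation, schedule_releases)
    from .synth import FlowFieldSpec, IslandSpec, make_flow_field

    site_a = (6.0, -38.0)
    site_b = (52.0, -38.0)
    spec = FlowFieldSpec(
        lon_min=0.0, lon_max=60.0, lat_min=-48.0, lat_max=-25.0, spacing_deg=0.5,
        time_span_days=0.0,  # steady circulation: a single archived mean
        gyre_center=(20.0, -30.0), gyre_halfwidth_deg=(16.0, 5.0), gyre_strength=0.15,
        jet_lat=-38.0, jet_width_deg=2.0, jet_speed=0.10,
        islands=[IslandSpec(*site_a), IslandSpec(*site_b)],
    )
    field = make_flow_field(spec)
    release = ReleaseSpec(
        sites=[ReleaseSite("A", *site_a), ReleaseSite("B", *site_b)],
        particles_per_cell_per_day=particles_per_cell_per_day,
        spawning_months=(8, 9, 10), years=(2000,), seed=seed,
    )
    ensemble = schedule_releases(field, release)
    zones = [RecruitmentZone("A", *site_a), RecruitmentZone("B", *site_b)]
    diffusion = DiffusionSpec(kh_m2s=100.0, kv_m2s=1e-4, dt_minutes=30.0, seed=seed)
    ensemble, log = run_simulation(field, ensemble, zones, PldWindow(), diffusion,
                                   record_visits=record_visits)
    matrix = build_annual_matrix(ensemble, ["A", "B"], 2000)
    return matrix, ensemble, field, log


# ---------------------------------------------------------------------------
# first-generation migrant detection studies
# ---------------------------------------------------------------------------

def assignment_null_study(n_per_pop: int = 50, n_loci: int = 300, n_sim: int = 10_000,
                          alpha: float = 0.01, seed: int = 7):
    """Type-I calibration: one panmictic pool split arbitrarily in two.

    Returns the per-individual assignment table; the flagged fraction should
    sit inside the binomial band around alpha.
    """
    from .assignment import detect_migrants
    from .synth import GenotypeSimSpec, make_genotypes

    g = make_genotypes(GenotypeSimSpec(n_populations=2,
                                       sample_sizes=(n_per_pop, n_per_pop),
                                       n_loci=n_loci, target_fst=0.0, seed=seed))
    return detect_migrants(g, alpha=alpha, n_sim=n_sim, seed=seed + 1)


def assignment_power_study(n_migrants: int = 20, fst: float = 0.2, n_per_pop: int = 50,
                           n_loci: int = 300, n_sim: int = 10_000, alpha: float = 0.01,
                           seed: int = 17):
    """Power: planted first-generation migrants at a known F_ST.

    Returns (assignment table, planted subset) — power is the planted
    subset's flagged fraction.
    """
    from .assignment import detect_migrants
    from .synth import GenotypeSimSpec, PlantedMigrant, make_genotypes

    migrants = [PlantedMigrant(sink="pop2", source="pop1")] * n_migrants
    g = make_genotypes(GenotypeSimSpec(n_populations=2,
                                       sample_sizes=(n_per_pop, n_per_pop),
                                       n_loci=n_loci, target_fst=fst,
                                       migrants=migrants, seed=seed))
    res = detect_migrants(g, alpha=alpha, n_sim=n_sim, seed=seed + 1)
    planted = res[res["individual"].str.contains("mig")]
    return res, planted
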