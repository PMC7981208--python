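"""Genotype assignment, migrant detection, directional aggregation."""

import numpy as np
import pandas as pd
import pytest

from seaconnect import datasets
from seaconnect.assignment import (aggregate_directional,
                                   aggregate_table_set, detect_migrants,
                                   genotype_likelihood, genotype_log_probs,
                                   migrant_table, migrants_per_generation, subset_loci)
from seaconnect.genio import MISSING, GenotypeMatrix
from seaconnect.synth import GenotypeSimSpec, PlantedMigrant, make_genotypes


# ---------------------------------------------------------------------------
# Dirichlet posterior-predictive genotype likelihood
# ---------------------------------------------------------------------------

def test_likelihood_single_locus_brute_force():
    """Reference counts (A:1, B:1), prior 1/2 per allele, query AA:
    P = (1.5/3) * (2.5/4) = 0.3125."""
    counts = np.array([[1.0, 1.0]])
    ll = genotype_likelihood(np.array([0], dtype=np.int8), counts)
    assert 10**ll == pytest.approx(0.3125)


def test_likelihood_heterozygote_brute_force():
    # P(AB) = 2 * (1.5/3) * (1.5/4)
    counts = np.array([[1.0, 1.0]])
    ll = genotype_likelihood(np.array([1], dtype=np.int8), counts)
    assert 10**ll == pytest.approx(2 * (1.5 / 3) * (1.5 / 4))


def test_leave_one_out_of_single_member_equals_prior_predictive():
    """Removing the only reference individual leaves the bare prior."""
    empty = np.array([[0.0, 0.0]])
    ll = genotype_likelihood(np.array([0], dtype=np.int8), empty)
    # prior predictive with tau = 1/2: (0.5/1) * (1.5/2)
    assert 10**ll == pytest.approx(0.375)


def test_absent_allele_has_prior_mass_increasing_in_tau():
    counts = np.array([[10.0, 0.0]])
    g = np.array([2], dtype=np.int8)  # homozygous for the unseen allele
    p_small = 10 ** genotype_likelihood(g, counts, tau=0.1)
    p_big = 10 ** genotype_likelihood(g, counts, tau=1.0)
    assert 0 < p_small < p_big


def test_missing_loci_skipped():
    counts = np.array([[1.0, 1.0], [1.0, 1.0]])
    with_missing = genotype_likelihood(np.array([0, MISSING], dtype=np.int8), counts)
    single = genotype_likelihood(np.array([0], dtype=np.int8), counts[:1])
    assert with_missing == pytest.approx(single)


def test_log_probs_rows_are_distributions():
    counts = np.array([[7.0, 3.0], [0.0, 5.0]])
    probs = 10 ** genotype_log_probs(counts)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0)


# ---------------------------------------------------------------------------
# migrant detection
# ---------------------------------------------------------------------------

def test_lambda_zero_iff_home_is_best():
    g = make_genotypes(GenotypeSimSpec(n_populations=2, sample_sizes=(20, 20),
                                       n_loci=120, target_fst=0.15, seed=4))
    res = detect_migrants(g, alpha=0.01, n_sim=500, seed=1)
    lam = res["lambda"].values
    assert np.all(lam >= 0)
    home_best = res["best"].values == res["home"].values
    assert np.array_equal(home_best, lam == 0)


def test_single_population_degenerate_rejected():
    g = make_genotypes(GenotypeSimSpec(n_populations=1, sample_sizes=(10,),
                                       n_loci=50, target_fst=0.0, seed=0))
    with pytest.raises(ValueError):
        detect_migrants(g, n_sim=500)


def test_small_nsim_rejected():
    g = make_genotypes(GenotypeSimSpec(seed=0))
    with pytest.raises(ValueError):
        detect_migrants(g, n_sim=50)


def test_planted_migrants_detected_and_assigned_to_source():
    """At F_ST 0.2 with 300 loci, planted migrants should be flagged and
    traced to their true source population."""
    migrants = [PlantedMigrant(sink="pop2", source="pop1")] * 5
    g = make_genotypes(GenotypeSimSpec(n_populations=2, sample_sizes=(40, 40),
                                       n_loci=300, target_fst=0.2,
                                       migrants=migrants, seed=9))
    res = detect_migrants(g, alpha=0.01, n_sim=2000, seed=2)
    planted = res[res["individual"].str.contains("mig")]
    assert len(planted) == 5
    assert planted["migrant"].mean() >= 0.8
    assert (planted["best"] == "pop1").mean() >= 0.8
    tab = migrant_table(res, ["pop1", "pop2"])
    assert tab.loc["pop2", "pop1"] >= 4


# ---------------------------------------------------------------------------
# directional aggregation against the published migration tables
# ---------------------------------------------------------------------------

def directional_totals(summaries):
    """Totals keyed by explicit direction labels."""
    out = {}
    for s in summaries:
        out.setdefault(s.forward_label, []).append(s.forward_total)
        out.setdefault(s.backward_label, []).append(s.backward_total)
    return out


def test_contemporary_tables_reproduce_reported_totals():
    """First-generation migrants move mostly Atlantic -> Indian (west to
    east): totals 12/12/17 against 2/4/7, spanning 71-86%."""
    summaries = [aggregate_directional(t, datasets.SPECIES_GROUPS)
                 for t in datasets.contemporary_migrant_tables()]
    tot = directional_totals(summaries)
    assert [round(v) for v in tot["Atlantic->Indian"]] == [12, 12, 17]
    assert [round(v) for v in tot["Indian->Atlantic"]] == [2, 4, 7]
    pcts = [round(100 * a / (a + b)) for a, b in
            zip(tot["Atlantic->Indian"], tot["Indian->Atlantic"])]
    assert min(pcts) == 71 and max(pcts) == 86


def test_historical_tables_reproduce_reported_totals():
    """Historical migrants per generation move mostly Indian -> Atlantic
    (east to west): totals spanning 62-107 against 13-19, 82-86%."""
    summaries = [aggregate_directional(t, datasets.SPECIES_GROUPS)
                 for t in datasets.historical_migrant_tables()]
    tot = directional_totals(summaries)
    assert [round(v) for v in tot["Indian->Atlantic"]] == [80, 107, 62]
    assert [round(v) for v in tot["Atlantic->Indian"]] == [13, 19, 13]
    pcts = [round(100 * i / (i + a)) for i, a in
            zip(tot["Indian->Atlantic"], tot["Atlantic->Indian"])]
    assert min(pcts) == 82 and max(pcts) == 86


def test_symmetric_table_gives_fifty_percent():
    pops = ["x1", "x2", "y1"]
    tab = pd.DataFrame([[np.nan, 1.0, 3.0], [1.0, np.nan, 3.0], [3.0, 3.0, np.nan]],
                       index=pops, columns=pops)
    s = aggregate_directional(tab, {"x1": "X", "x2": "X", "y1": "Y"})
    assert s.forward_percent == pytest.approx(50.0)


def test_aggregation_invariant_to_within_group_permutation():
    tables = datasets.contemporary_migrant_tables()
    t = tables[0]
    perm = ["JPA_SP", "JPA_Am", "JTR_Tr", "JTR_Go", "JTR_NI"]
    s1 = aggregate_directional(t, datasets.SPECIES_GROUPS)
    s2 = aggregate_directional(t.loc[perm, perm], datasets.SPECIES_GROUPS)
    assert s1.forward_total == s2.forward_total
    assert s1.backward_total == s2.backward_total


def test_aggregation_requires_two_complete_groups():
    t = datasets.contemporary_migrant_tables()[0]
    with pytest.raises(ValueError):
        aggregate_directional(t, {p: "one" for p in t.index})
    with pytest.raises(ValueError):
        aggregate_directional(t, {"JPA_Am": "a"})


def test_table_set_min_max_rows():
    df = aggregate_table_set(datasets.historical_migrant_tables(), datasets.SPECIES_GROUPS)
    col = [c for c in df.columns if c.startswith("Indian->") or c.startswith("Atlantic->")]
    assert "min" in df.index and "max" in df.index
    assert len(col) == 2


# ---------------------------------------------------------------------------
# small operations
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("theta,M,expected", [(0.0, 7.0, 0.0), (0.5, 10.0, 5.0), (1.0, 1.0, 1.0)])
def test_migrants_per_generation(theta, M, expected):
    assert migrants_per_generation(theta, M) == expected


def test_migrants_per_generation_rejects_negative():
    with pytest.raises(ValueError):
        migrants_per_generation(-1.0, 2.0)


def test_subset_loci_deterministic_and_distinct():
    g = make_genotypes(GenotypeSimSpec(n_loci=500, seed=0))
    s1 = subset_loci(g, 100, seed=5)
    s2 = subset_loci(g, 100, seed=5)
    assert s1.loci == s2.loci
    assert len(set(s1.loci)) == 100
    with pytest.raises(ValueError):
        subset_loci(g, 501, seed=5)
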