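"""Divergence models, composite likelihood, information criteria, conversions."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln

from seaconnect import datasets
from seaconnect.demography import (ConversionInputs, DivergenceModel, ModelFitResult,
                                   SCENARIO_K, SCENARIO_PARAMS, aic, akaike_weights,
                                   ancestral_ne, composite_loglik, convert_units,
                                   effective_length, expected_jsfs, fit_model, fit_report,
                                   model_scores)
from seaconnect.jsfs import FoldedJSFS
from seaconnect.synth import ScenarioSimSpec, simulate_jsfs

IM_PARAMS = dict(nu1=1.0, nu2=1.0, T_S=1.0, M12=1.0, M21=1.0)


# ---------------------------------------------------------------------------
# scenario structure
# ---------------------------------------------------------------------------

def test_parameter_counts_per_scenario():
    assert {s: SCENARIO_K[s] for s in SCENARIO_K} == \
        {"SI": 3, "IM": 5, "AM": 6, "SC": 6, "PAM": 6, "PSC": 8}


def test_epoch_ordering_validation():
    with pytest.raises(ValueError):
        DivergenceModel("SC", dict(nu1=1, nu2=1, T_S=1, T_SC=-1, M12=1, M21=1))
    with pytest.raises(ValueError):
        DivergenceModel("IM", dict(nu1=0, nu2=1, T_S=1, M12=1, M21=1))


def test_psc_epoch_structure():
    m = DivergenceModel("PSC", dict(nu1=1, nu2=1, T_S=2.0, T_SC=1.0,
                                    mA=1.0, mB=2.0, mC=3.0, mD=4.0))
    epochs, t_div = m.epochs()
    assert t_div == 3.0
    # most recent epoch carries the second event's rates (mC, mD)
    assert epochs[0] == (0.0, 0.5, 3.0, 4.0)
    assert epochs[1] == (0.5, 1.0, 1.0, 2.0)


# ---------------------------------------------------------------------------
# expected spectra (Monte-Carlo coalescent)
# ---------------------------------------------------------------------------

def test_expected_jsfs_symmetric_under_symmetric_im():
    m = DivergenceModel("IM", IM_PARAMS)
    fs = expected_jsfs(m, 8, 8, n_reps=3000, seed=1)
    keep = ~fs.mask & ~fs.mask.T
    diff = np.abs(fs.data - fs.data.T)[keep]
    assert diff.max() < 0.02


def test_sc_with_zero_contact_matches_si():
    si = expected_jsfs(DivergenceModel("SI", dict(nu1=1, nu2=1, T_S=1.0)),
                       8, 8, n_reps=4000, seed=2)
    sc = expected_jsfs(DivergenceModel("SC", dict(nu1=1, nu2=1, T_S=1.0, T_SC=0.0,
                                                  M12=5.0, M21=5.0)),
                       8, 8, n_reps=4000, seed=3)
    assert np.abs(si.data - sc.data).sum() < 0.05


def test_im_with_zero_migration_matches_si():
    si = expected_jsfs(DivergenceModel("SI", dict(nu1=1, nu2=1, T_S=1.0)),
                       8, 8, n_reps=4000, seed=4)
    im = expected_jsfs(DivergenceModel("IM", dict(nu1=1, nu2=1, T_S=1.0, M12=0.0, M21=0.0)),
                       8, 8, n_reps=4000, seed=5)
    assert np.abs(si.data - im.data).sum() < 0.05


def test_single_population_limit_watterson_shape():
    """T_S -> 0: the pooled marginal of the expected spectrum is ~ 1/i."""
    fs = expected_jsfs(DivergenceModel("SI", dict(nu1=1, nu2=1, T_S=1e-6)),
                       5, 5, n_reps=4000, seed=6, ascertained=False)
    pooled = np.zeros(11)
    for i in range(6):
        for j in range(6):
            if not fs.mask[i, j]:
                pooled[i + j] += fs.data[i, j]
    k = np.arange(1, 6)
    expected = 1.0 / k + 1.0 / (10 - k)
    expected[-1] /= 2.0
    expected /= expected.sum()
    np.testing.assert_allclose(pooled[1:6], expected, rtol=0.08)


# ---------------------------------------------------------------------------
# composite likelihood
# ---------------------------------------------------------------------------

def test_loglik_perfect_fit_recovers_scale():
    rel = np.array([[0.0, 0.3], [0.5, 0.2]])
    mask = np.array([[True, False], [False, False]])
    expected = FoldedJSFS(data=rel, mask=mask)
    observed = FoldedJSFS(data=rel * 1000.0, mask=mask)
    logl, theta = composite_loglik(observed, expected)
    assert theta == pytest.approx(1000.0)
    lam = rel[~mask] * 1000.0
    obs = lam
    saturated = np.sum(obs * np.log(lam) - lam - gammaln(obs + 1.0))
    assert logl == pytest.approx(saturated)


def test_loglik_hand_poisson_sum():
    expected = FoldedJSFS(data=np.array([[0.0, 0.25], [0.75, 0.0]]),
                          mask=np.array([[True, False], [False, True]]))
    observed = FoldedJSFS(data=np.array([[0.0, 3.0], [5.0, 0.0]]),
                          mask=expected.mask)
    logl, theta = composite_loglik(observed, expected)
    assert theta == pytest.approx(8.0)
    by_hand = (3 * np.log(2.0) - 2.0 - gammaln(4.0)) + (5 * np.log(6.0) - 6.0 - gammaln(6.0))
    assert logl == pytest.approx(by_hand)


def test_loglik_mask_invariance():
    data = np.array([[0.0, 0.4], [0.6, 0.0]])
    mask = np.array([[True, False], [False, True]])
    obs = FoldedJSFS(data=np.array([[0.0, 4.0], [6.0, 0.0]]), mask=mask)
    base = composite_loglik(obs, FoldedJSFS(data=data, mask=mask))[0]
    # growing the mask over an empty cell leaves logL unchanged
    bigger = np.array([[0.0, 8.0], [12.0, 0.0]])
    obs2 = FoldedJSFS(data=np.array([[0.0, 4.0], [6.0, 0.0]]), mask=mask)
    assert composite_loglik(obs2, FoldedJSFS(data=data, mask=mask))[0] == pytest.approx(base)


def test_loglik_all_masked_rejected():
    mask = np.ones((2, 2), dtype=bool)
    fs = FoldedJSFS(data=np.zeros((2, 2)), mask=mask)
    with pytest.raises(ValueError):
        composite_loglik(fs, fs)


# ---------------------------------------------------------------------------
# information criteria against the published model-comparison table
# ---------------------------------------------------------------------------

def test_aic_from_reported_loglik_values():
    tab = datasets.divergence_model_table()
    assert aic(tab.loc["PSC", "LogL"], int(tab.loc["PSC", "K"])) == 4448.0
    assert aic(tab.loc["SI", "LogL"], int(tab.loc["SI", "K"])) == 4780.0
    assert aic(0.0, 1) == 2.0


def test_scores_reproduce_reported_column():
    tab = datasets.divergence_model_table()
    aics = np.array([aic(l, int(k)) for k, l in zip(tab["K"], tab["LogL"])])
    scores = model_scores(aics)
    reported = {"PSC": 1.00, "SI": 0.93, "SC": 0.70, "IM": 0.64, "PAM": 0.00, "AM": 0.10}
    for model, s in zip(tab.index, scores):
        assert round(s, 2) == reported[model]


def test_scores_hand_case_and_invariance():
    np.testing.assert_allclose(model_scores([10.0, 20.0, 30.0]), [1.0, 0.5, 0.0])
    np.testing.assert_allclose(model_scores([110.0, 120.0, 130.0]), [1.0, 0.5, 0.0])
    with pytest.raises(ValueError):
        model_scores([5.0, 5.0])


def test_akaike_weights_hand_cases():
    np.testing.assert_allclose(akaike_weights([4.0, 4.0]), [0.5, 0.5])
    w = akaike_weights([0.0, 2.0])
    np.testing.assert_allclose(w, [1 / (1 + np.exp(-1)), np.exp(-1) / (1 + np.exp(-1))])
    assert w.sum() == pytest.approx(1.0)


def test_akaike_weights_reported_best_model_weight():
    tab = datasets.divergence_model_table()
    aics = [aic(l, int(k)) for k, l in zip(tab["K"], tab["LogL"])]
    w = akaike_weights(aics)
    assert round(w[list(tab.index).index("PSC")], 1) == 1.0
    assert np.all(np.diff(w[np.argsort(aics)]) <= 0)  # decreasing in AIC


def test_weights_invariant_to_aic_shift():
    a = np.array([100.0, 104.0, 120.0])
    np.testing.assert_allclose(akaike_weights(a), akaike_weights(a + 55.0))


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def test_effective_length_arithmetic():
    # z = x and y = 1 -> L = 73
    inputs = ConversionInputs(x_snps_detected=500.0, y_rad_tags=1.0, z_snps_retained=500.0)
    assert effective_length(inputs) == pytest.approx(73.0)


def test_nref_inversion():
    # theta = 4 L mu exactly -> N_ref = 1
    L = 1e6
    mu = 2.3e-9
    assert ancestral_ne(4 * L * mu, L, mu) == pytest.approx(1.0)


def test_year_conversion_linear_in_generation_time():
    fit = ModelFitResult(scenario="SI", params=dict(nu1=1.0, nu2=2.0, T_S=0.5),
                         logl=-10.0, k=3, aic=26.0, theta=100.0)
    short = convert_units(fit, ConversionInputs(1000, 500, 800, generation_time_years=10))
    long = convert_units(fit, ConversionInputs(1000, 500, 800, generation_time_years=20))
    assert long["T_S_years"] == pytest.approx(2 * short["T_S_years"])
    assert short["N1_individuals"] == pytest.approx(short["N_ref"])
    assert short["N2_individuals"] == pytest.approx(2 * short["N_ref"])


def test_conversion_inputs_must_be_positive():
    with pytest.raises(ValueError):
        ConversionInputs(0.0, 1.0, 1.0)


def test_migration_conversion_divides_by_two_nref():
    fit = ModelFitResult(scenario="IM",
                         params=dict(nu1=1.0, nu2=1.0, T_S=1.0, M12=4.0, M21=1.0),
                         logl=-10.0, k=5, aic=30.0, theta=4 * 73.0 * 2.3e-9)
    out = convert_units(fit, ConversionInputs(500.0, 1.0, 500.0))  # L = 73, N_ref = 1
    assert out["M12_proportion_per_generation"] == pytest.approx(2.0)


# ---------------------------------------------------------------------------
# fitting mechanics (scaled down; accuracy is covered by the studies)
# ---------------------------------------------------------------------------

def test_fit_model_deterministic_given_seed():
    obs = simulate_jsfs(ScenarioSimSpec("SI", dict(nu1=1, nu2=1, T_S=0.5),
                                        n1=6, n2=6, n_loci=400, seed=1))
    kw = dict(n_replicates=1, n_scan=10, scan_reps=100,
              candidate_schedule=[(0.4, 150, 12)],
              polish_schedule=[(0.2, 300, 12)], block_cycles=0,
              n_reps_rank=500, n_reps_final=1000, anchor=400 * 0.1 / 4)
    f1 = fit_model(obs, "SI", seed=9, **kw)
    f2 = fit_model(obs, "SI", seed=9, **kw)
    assert f1.params == f2.params
    assert f1.logl == f2.logl
    assert f1.aic == pytest.approx(2 * f1.k - 2 * f1.logl)


def test_fit_report_layout():
    fits = [ModelFitResult("SI", dict(nu1=1, nu2=1, T_S=1), -100.0, 3, 206.0, 10.0),
            ModelFitResult("IM", dict(nu1=1, nu2=1, T_S=1, M12=1, M21=1), -90.0, 5, 190.0, 10.0)]
    rep = fit_report(fits)
    assert list(rep.index) == ["SI", "IM"]
    assert rep.loc["IM", "Score"] == pytest.approx(1.0)
    assert rep.loc["SI", "Score"] == pytest.approx(0.0)
    assert rep["W_AIC"].sum() == pytest.approx(1.0)
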