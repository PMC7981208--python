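"""Two-population divergence-mode inference on the folded joint SFS.

Six piecewise-constant divergence scenarios are compared: strict isolation
(SI), isolation-with-migration (IM), ancient migration (AM), secondary
contact (SC), and the two-event "periodic" variants PAM and PSC in which the
migration era is split into two epochs with separately estimated asymmetric
rate pairs (mA, mB) then (mC, mD), resolving changes in the direction of
gene flow over time.

Parameter conventions (dadi-style): population sizes nu1, nu2 are relative
to the ancestral size N_ref; times are in units of 2*N_ref generations;
migration rates M12, M21 are scaled per 2*N_ref generations, with M12 the
movement of genes from population 2 into population 1 (forward in time).

The expected folded JSFS under a scenario is computed by coalescent Monte
Carlo: replicate genealogies are simulated with msprime and the branch-mode
allele frequency spectrum (expected mutation density per frequency class) is
averaged, folded, and normalized. Fitting maximizes a Poisson composite
log-likelihood over unmasked entries with the multiplicative theta profiled
out analytically. Because the objective is itself a Monte-Carlo estimate,
optimization uses an iterative trust-region response surface (a quadratic
regression over batches of independently seeded evaluations) with a
second-order bias correction for the log of a noisy expectation, restarted
from multiple perturbed start points with the best replicate retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np
import pandas as pd
from scipy.special import gammaln

from .jsfs import FoldedJSFS

SCENARIOS = ("SI", "IM", "AM", "SC", "PAM", "PSC")

#: free parameters per scenario, in fitting order
SCENARIO_PARAMS: dict[str, tuple[str, ...]] = {
    "SI": ("nu1", "nu2", "T_S"),
    "IM": ("nu1", "nu2", "T_S", "M12", "M21"),
    "AM": ("nu1", "nu2", "T_S", "T_AM", "M12", "M21"),
    "SC": ("nu1", "nu2", "T_S", "T_SC", "M12", "M21"),
    "PAM": ("nu1", "nu2", "T_S", "T_AM", "mA", "mB", "mC", "mD"),
    "PSC": ("nu1", "nu2", "T_S", "T_SC", "mA", "mB", "mC", "mD"),
}

#: reported parameter counts (the published model-comparison convention;
#: PAM is conventionally reported with K=6)
SCENARIO_K: dict[str, int] = {"SI": 3, "IM": 5, "AM": 6, "SC": 6, "PAM": 6, "PSC": 8}


@dataclass
class DivergenceModel:
    scenario: str
    params: dict[str, float]

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}")
        need = SCENARIO_PARAMS[self.scenario]
        missing = [p for p in need if p not in self.params]
        if missing:
            raise ValueError(f"{self.scenario} missing parameters {missing}")
        p = self.params
        if p["nu1"] <= 0 or p["nu2"] <= 0:
            raise ValueError("population sizes must be > 0")
        for key in ("T_S", "T_SC", "T_AM"):
            if key in p and p[key] < 0:
                raise ValueError(f"epoch duration {key} must be >= 0 (epoch ordering)")
        for key in ("M12", "M21", "mA", "mB", "mC", "mD"):
            if key in p and p[key] < 0:
                raise ValueError("migration rates must be >= 0")

    @property
    def k(self) -> int:
        return SCENARIO_K[self.scenario]

    def epochs(self):
        """Backwards-time migration epochs: list of (t_start, t_end, M12, M21)
        in units of 2*N_ref generations, plus the total divergence time."""
        p = self.params
        s = self.scenario
        if s == "SI":
            return [], p["T_S"]
        if s == "IM":
            return [(0.0, p["T_S"], p["M12"], p["M21"])], p["T_S"]
        if s == "SC":
            return [(0.0, p["T_SC"], p["M12"], p["M21"])], p["T_S"] + p["T_SC"]
        if s == "AM":
            return [(p["T_S"], p["T_S"] + p["T_AM"], p["M12"], p["M21"])], p["T_S"] + p["T_AM"]
        if s == "PSC":
            h = p["T_SC"] / 2.0
            return (
                [(0.0, h, p["mC"], p["mD"]), (h, p["T_SC"], p["mA"], p["mB"])],
                p["T_S"] + p["T_SC"],
            )
        # PAM: two ancient epochs behind a recent isolation period
        h = p["T_AM"] / 2.0
        return (
            [(p["T_S"], p["T_S"] + h, p["mC"], p["mD"]), (p["T_S"] + h, p["T_S"] + p["T_AM"], p["mA"], p["mB"])],
            p["T_S"] + p["T_AM"],
        )

    def to_msprime(self, n_ref: float = 1.0) -> msprime.Demography:
        """msprime demography (times in generations = 2 * N_ref * T).

        Forward migration of genes from population 2 into population 1 at
        scaled rate M12 is a backwards movement of population-1 lineages into
        population 2 at rate M12 / (2 * N_ref) per generation.
        """
        p = self.params
        epochs, t_div = self.epochs()
        dem = msprime.Demography()
        dem.add_population(name="P1", initial_size=n_ref * p["nu1"])
        dem.add_population(name="P2", initial_size=n_ref * p["nu2"])
        dem.add_population(name="ANC", initial_size=n_ref)
        g = 2.0 * n_ref  # generations per time unit

        def per_gen(M):
            return M / (2.0 * n_ref)

        # current-epoch rates, then changes backwards in time
        changes: list[tuple[float, float, float]] = []  # (time_gens, m12, m21)
        cur12 = cur21 = 0.0
        for (t0, t1, M12, M21) in epochs:
            if t1 <= t0:
                continue
            if t0 == 0.0:
                cur12, cur21 = per_gen(M12), per_gen(M21)
                changes.append((t1 * g, 0.0, 0.0))
            else:
                changes.append((t0 * g, per_gen(M12), per_gen(M21)))
                changes.append((t1 * g, 0.0, 0.0))
        dem.set_migration_rate(source="P1", dest="P2", rate=cur12)
        dem.set_migration_rate(source="P2", dest="P1", rate=cur21)
        for (tg, m12, m21) in sorted(changes):
            if tg >= t_div * g - 1e-12:
                continue
            dem.add_migration_rate_change(time=tg, source="P1", dest="P2", rate=m12)
            dem.add_migration_rate_change(time=tg, source="P2", dest="P1", rate=m21)
        dem.add_population_split(time=max(t_div * g, 1e-9), derived=["P1", "P2"], ancestral="ANC")
        dem.sort_events()
        return dem


class _FoldPlan:
    """Cached index plan to fold (n1+1)x(n2+1) spectra with two gathers."""

    _cache: dict[tuple[int, int], "_FoldPlan"] = {}

    def __init__(self, n1: int, n2: int):
        i = np.arange(n1 + 1)[:, None]
        j = np.arange(n2 + 1)[None, :]
        tot = i + j
        half = (n1 + n2) / 2.0
        mask = (tot > half)
        mask[0, 0] = True
        mask[n1, n2] = True
        self.mask = mask
        keep = ~mask
        ii, jj = np.nonzero(keep)
        self.keep_flat = ii * (n2 + 1) + jj
        self.comp_flat = (n1 - ii) * (n2 + 1) + (n2 - jj)
        self.weight = np.where(tot[keep] == half, 0.5, 1.0)
        self.shape = (n1 + 1, n2 + 1)

    @classmethod
    def get(cls, n1: int, n2: int) -> "_FoldPlan":
        key = (n1, n2)
        if key not in cls._cache:
            cls._cache[key] = cls(n1, n2)
        return cls._cache[key]

    def fold(self, unfolded: np.ndarray) -> np.ndarray:
        """Folded values on the kept cells only (1-D, aligned with keep_flat)."""
        flat = unfolded.ravel()
        return (flat[self.keep_flat] + flat[self.comp_flat]) * self.weight

    def expand(self, kept: np.ndarray) -> np.ndarray:
        out = np.zeros(self.shape[0] * self.shape[1])
        out[self.keep_flat] = kept
        return out.reshape(self.shape)


def _folded_moments(model: DivergenceModel, n1: int, n2: int, n_reps: int, seed: int,
                    ascertained: bool = True):
    """Per-cell mean and variance-of-the-mean of the folded spectrum over
    replicate genealogies (kept cells only), plus the fold plan."""
    plan = _FoldPlan.get(n1, n2)
    dem = model.to_msprime()
    samples = [
        msprime.SampleSet(n1, population="P1", ploidy=1),
        msprime.SampleSet(n2, population="P2", ploidy=1),
    ]
    sets = [list(range(n1)), list(range(n1, n1 + n2))]
    acc = np.zeros(plan.keep_flat.size)
    acc2 = np.zeros(plan.keep_flat.size)
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, ploidy=2, num_replicates=n_reps,
        random_seed=int(seed) % (2**31 - 1) + 1,
    )
    for ts in reps:
        afs = ts.allele_frequency_spectrum(sample_sets=sets, mode="branch", polarised=True, span_normalise=True)
        if ascertained:
            afs = afs / afs.sum()
        p = plan.fold(afs)
        acc += p
        acc2 += p * p
    mean = acc / n_reps
    var_mean = np.maximum(acc2 / n_reps - mean * mean, 0.0) / n_reps
    return mean, var_mean, plan


def expected_jsfs(
    model: DivergenceModel, n1: int, n2: int, n_reps: int = 200, seed: int = 0,
    ascertained: bool = False,
) -> FoldedJSFS:
    """Monte-Carlo expectation of the folded JSFS (normalized to sum 1).

    Averages the branch-mode joint allele frequency spectrum over ``n_reps``
    replicate single-locus genealogies of n1 + n2 haploid genomes.

    With ``ascertained=True`` each genealogy's spectrum is normalized by its
    own total branch length before averaging, giving the distribution of a
    single SNP placed uniformly on each genealogy — the expectation matching
    one-SNP-per-locus (polymorphism-ascertained) data; this also bounds each
    replicate's contribution, so the estimator has no heavy tail from deep
    genealogies. With ``ascertained=False`` the raw branch expectation is
    averaged (the mutation-density expectation matching Poisson numbers of
    SNPs per locus).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    mean, _, plan = _folded_moments(model, n1, n2, n_reps, seed, ascertained)
    folded = FoldedJSFS(data=plan.expand(mean), mask=plan.mask.copy())
    return folded.normalized()


# ---------------------------------------------------------------------------
# composite likelihood and fitting
# ---------------------------------------------------------------------------

def composite_loglik(observed: FoldedJSFS, expected: FoldedJSFS, n_reps: int = 200,
                     var: np.ndarray | None = None):
    """Poisson composite log-likelihood (natural log) over unmasked entries.

    The multiplicative scaling theta is profiled analytically:
    theta_hat = sum(obs) / sum(expected). Monte-Carlo zero cells in the
    expectation receive a floor of 1 / (10 * n_reps * sum(obs)) before
    renormalization. If ``var`` (per-cell variance of the Monte-Carlo mean,
    same shape as the spectrum) is given, the second-order bias of
    log(noisy expectation) is corrected by adding obs * var / (2 mean^2)
    per cell (capped at 2), which makes cheap evaluations comparable across
    parameter space. Returns (logL, theta_hat).
    """
    keep = ~(observed.mask | expected.mask)
    if not keep.any():
        raise ValueError("all spectrum entries are masked")
    obs = observed.data[keep]
    exp_rel = expected.data[keep].astype(float)
    s_obs = obs.sum()
    floor = 1.0 / (10.0 * n_reps * max(s_obs, 1.0))
    exp_rel = np.maximum(exp_rel, floor)
    exp_rel = exp_rel / exp_rel.sum()
    theta = s_obs / exp_rel.sum()  # = s_obs with normalized expectation
    lam = theta * exp_rel
    logl = float(np.sum(obs * np.log(lam) - lam - gammaln(obs + 1.0)))
    if var is not None:
        v = np.asarray(var, dtype=float)[keep] if var.shape == observed.data.shape else np.asarray(var, dtype=float)
        logl += float(np.sum(obs * np.minimum(v / (2.0 * exp_rel**2), 2.0)))
    return logl, float(theta)


def absolute_loglik(observed: FoldedJSFS, mean_branch: np.ndarray, rate: float,
                    plan: "_FoldPlan", var: np.ndarray | None = None) -> float:
    """Poisson composite log-likelihood with a known absolute mutation rate.

    ``mean_branch`` is the raw (unnormalized) Monte-Carlo mean folded branch
    spectrum on the plan's kept cells and ``rate`` the expected number of
    mutations per unit branch length summed over loci (n_loci * theta_locus
    / 4). Unlike the profiled form, the spectrum total is informative here:
    it anchors the absolute time/size scale, which resolves the
    size-time scaling ridge of shape-only fits. ``var`` enables the
    second-order bias correction used during optimization.
    """
    o = observed.data.ravel()[plan.keep_flat]
    lam = np.maximum(rate * mean_branch, 1e-6)
    ll = float(np.sum(o * np.log(lam) - lam - gammaln(o + 1.0)))
    if var is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.nan_to_num(rate**2 * var / (2.0 * lam**2), nan=0.0, posinf=2.0)
        ll += float(np.sum(o * np.minimum(corr, 2.0)))
    return ll


#: default fitting bounds per parameter kind
DEFAULT_BOUNDS = {"nu": (0.05, 20.0), "T": (0.005, 12.0), "M": (1e-3, 50.0)}


def _bounds_for(name: str):
    if name.startswith("nu"):
        return DEFAULT_BOUNDS["nu"]
    if name.startswith("T"):
        return DEFAULT_BOUNDS["T"]
    return DEFAULT_BOUNDS["M"]


@dataclass
class ModelFitResult:
    scenario: str
    params: dict[str, float]
    logl: float
    k: int
    aic: float
    theta: float
    replicates: pd.DataFrame | None = field(repr=False, default=None)


def evaluate_fit(observed: FoldedJSFS, scenario: str, params: dict[str, float],
                 n_reps: int = 20_000, seed: int = 0, ascertained: bool = False,
                 anchor: float | None = None) -> ModelFitResult:
    """Evaluate a parameter vector's composite logL (and AIC) at high
    replication. The Monte-Carlo seed is derived from ``seed`` exactly as in
    :func:`fit_model`, so results for different scenarios fitted with the
    same seed are directly comparable."""
    n1, n2 = observed.sample_sizes
    final_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    model = DivergenceModel(scenario, params)
    if anchor is not None:
        mean, _, plan = _folded_moments(model, n1, n2, n_reps, final_seed, ascertained)
        logl = absolute_loglik(observed, mean, anchor, plan)
        theta = anchor
    else:
        exp_fs = expected_jsfs(model, n1, n2, n_reps=n_reps, seed=final_seed, ascertained=ascertained)
        logl, theta = composite_loglik(observed, exp_fs, n_reps=n_reps)
    k = SCENARIO_K[scenario]
    return ModelFitResult(scenario=scenario, params=dict(params), logl=logl, k=k,
                          aic=aic(logl, k), theta=theta)


def _quadratic_argmax(X: np.ndarray, y: np.ndarray, x0: np.ndarray, h: float) -> np.ndarray:
    """Maximize a least-squares quadratic surrogate fitted to (X, y) inside
    the box x0 +/- h. Falls back to the best sampled point if the stationary
    point is not a maximum or escapes the box."""
    ok = np.isfinite(y)
    if ok.sum() < len(y):
        X, y = X[ok], y[ok]
    if y.size == 0:
        return x0
    d = X.shape[1]
    Z = X - x0
    cols = [np.ones(len(X))] + [Z[:, i] for i in range(d)]
    for i in range(d):
        for j in range(i, d):
            cols.append(Z[:, i] * Z[:, j])
    A = np.stack(cols, axis=1)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    g = coef[1 : d + 1]
    # coef[k] multiplies z_i z_j (i <= j); build symmetric H with
    # Q(z) = c0 + g.z + z'Hz
    H = np.zeros((d, d))
    k = d + 1
    for i in range(d):
        for j in range(i, d):
            if i == j:
                H[i, i] = coef[k]
            else:
                H[i, j] = H[j, i] = coef[k] / 2.0
            k += 1
    if not (np.all(np.isfinite(H)) and np.all(np.isfinite(g))):
        return X[np.argmax(y)]
    try:
        step = -np.linalg.solve(2.0 * H, g)
    except np.linalg.LinAlgError:
        return X[np.argmax(y)]
    eig = np.linalg.eigvalsh(H)
    if eig.max() >= 0 or np.any(np.abs(step) > h):
        return X[np.argmax(y)]
    return x0 + step


def fit_model(
    observed: FoldedJSFS,
    scenario: str,
    n_replicates: int = 20,
    seed: int = 0,
    n_scan: int = 300,
    scan_reps: int = 250,
    candidate_schedule: list[tuple[float, int, int]] | None = None,
    polish_schedule: list[tuple[float, int, int]] | None = None,
    n_reps_rank: int = 8000,
    n_reps_final: int = 20_000,
    block_cycles: int = 2,
    block_schedule: list[tuple[float, int, int]] | None = None,
    ascertained: bool = False,
    anchor: float | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    warm_starts: list[dict[str, float]] | None = None,
) -> ModelFitResult:
    """Multi-start composite-likelihood fit of one scenario.

    Because the objective is a Monte-Carlo estimate, plain local search is
    blind below the noise floor; the fit therefore proceeds in stages:

    1. global scan — the bias-corrected logL is evaluated at ``n_scan``
       random points of the log-parameter box (plus a fixed default start);
    2. replicate runs — the ``n_replicates`` best scan points each run a
       short trust-region chain (``candidate_schedule``): per step a batch of
       independently seeded evaluations around the centre is fitted with a
       quadratic response surface, whose maximum becomes the next centre;
    3. ranking — chain endpoints are re-scored at ``n_reps_rank`` Monte-Carlo
       replicates and the best endpoint retained;
    4. polish — the winner runs the longer ``polish_schedule`` and is
       reported with logL and theta evaluated at ``n_reps_final``.

    Schedules are lists of (box half-width in log units, Monte-Carlo
    replicates per evaluation, batch size). The response-surface regression,
    not the raw objective, absorbs the evaluation noise, and the second-order
    bias correction keeps cheap evaluations comparable between smooth and
    structured spectra.

    ``warm_starts`` (parameter dicts, typically best fits of nested simpler
    scenarios mapped into this scenario's parameter space) are added to the
    replicate-chain candidates, which equalizes convergence quality across
    nested models so AIC comparisons reflect fit, not optimizer luck.

    When the per-locus mutation rate of the data is known (a simulation
    study, or sequence data with a trusted rate), pass
    ``anchor = n_loci * theta_locus / 4``: the likelihood then uses absolute
    expected counts (:func:`absolute_loglik`), whose total anchors the
    time/size scale and removes the scaling ridge that makes shape-only
    fits ill-determined. Otherwise theta is profiled analytically.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate run")
    if candidate_schedule is None:
        candidate_schedule = [(0.45, 250, 24)] * 2 + [(0.30, 400, 24)]
    if polish_schedule is None:
        polish_schedule = [(0.30, 600, 30)] * 2 + [(0.18, 1200, 30)] * 2 + \
                          [(0.10, 2500, 36)] * 2
    if block_schedule is None:
        block_schedule = [(0.30, 4000, 16), (0.15, 7000, 16)]
    names = SCENARIO_PARAMS[scenario]
    d = len(names)
    bnds = [bounds.get(n, _bounds_for(n)) if bounds else _bounds_for(n) for n in names]
    lo = np.log([b[0] for b in bnds])
    hi = np.log([b[1] for b in bnds])
    n1, n2 = observed.sample_sizes
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    final_seed = int(ss.generate_state(1)[0] % (2**31 - 1))

    def corrected_logl(logx, reps):
        model = DivergenceModel(scenario, dict(zip(names, np.exp(logx))))
        s = int(rng.integers(1, 2**31 - 1))
        mean, var, plan = _folded_moments(model, n1, n2, reps, s, ascertained)
        if anchor is not None:
            return absolute_loglik(observed, mean, anchor, plan, var=var)
        tot = mean.sum()
        # variance rescaled to the normalized-spectrum scale used in the
        # likelihood (neglecting covariance with the normalizer)
        exp_fs = FoldedJSFS(data=plan.expand(mean / tot), mask=plan.mask.copy())
        logl, _ = composite_loglik(observed, exp_fs, n_reps=reps, var=var / tot**2)
        return logl

    def run_chain(centre, schedule, free=None):
        # noisy response-surface steps are not monotone; keep the better of
        # the chain's start and end under a common higher-replication check
        if not schedule:
            return centre
        start = centre.copy()
        free = list(range(d)) if free is None else free
        for (h, reps, pts) in schedule:
            X = np.repeat(centre[None, :], pts, axis=0)
            X[:, free] = np.clip(
                centre[free] + rng.uniform(-h, h, size=(pts, len(free))), lo[free], hi[free]
            )
            X[0] = centre
            y = np.array([corrected_logl(x, reps) for x in X])
            step = _quadratic_argmax(X[:, free], y, centre[free], h)
            centre = centre.copy()
            centre[free] = np.clip(step, lo[free], hi[free])
        cmp_reps = 2 * max(reps for (_, reps, _) in schedule)
        if corrected_logl(start, cmp_reps) > corrected_logl(centre, cmp_reps):
            return start
        return centre

    # stage 1: global scan
    init = np.log(np.array([1.0 if n.startswith("nu") else 0.5 if n.startswith("T") else 1.0 for n in names]))
    scan = np.vstack([init, rng.uniform(lo, hi, size=(n_scan, d))])
    scan_scores = np.array([corrected_logl(x, scan_reps) for x in scan])
    order = np.argsort(scan_scores)[::-1][:n_replicates]

    # stage 2: replicate chains from the best scan points plus warm starts
    starts = [scan[idx].copy() for idx in order]
    for w in warm_starts or []:
        starts.append(np.clip(np.log([max(w[n], 1e-12) for n in names]), lo, hi))
    rows, endpoints = [], []
    for r, centre0 in enumerate(starts):
        centre = run_chain(centre0, candidate_schedule)
        endpoints.append(centre)
        rows.append({"replicate": r, **dict(zip(names, np.exp(centre)))})

    # stage 3: rank endpoints at high replication
    rank_scores = np.array([corrected_logl(x, n_reps_rank) for x in endpoints])
    for row, sc in zip(rows, rank_scores):
        row["logl"] = sc
    rep = pd.DataFrame(rows)

    # stage 4: polish the winner
    x_best = run_chain(endpoints[int(np.argmax(rank_scores))], polish_schedule)

    # stage 5: block-coordinate refinement — the migration-rate pair and the
    # size/time block are each refined in their own low-dimensional subspace,
    # where high-replication quadratic batches resolve directions too soft
    # for the full-dimensional search
    mig = [i for i, n in enumerate(names) if n[0] in "Mm"]
    rest = [i for i in range(d) if i not in mig]
    if block_cycles and mig and rest:
        for _ in range(block_cycles):
            x_best = run_chain(x_best, block_schedule, free=mig)
            x_best = run_chain(x_best, block_schedule, free=rest)

    params = dict(zip(names, (float(v) for v in np.exp(x_best))))
    result = evaluate_fit(observed, scenario, params, n_reps=n_reps_final, seed=seed,
                          ascertained=ascertained, anchor=anchor)
    result.replicates = rep
    return result


def _warm_maps(scenario: str, fits: dict[str, "ModelFitResult"]) -> list[dict[str, float]]:
    """Best fits of scenarios nested in ``scenario``, mapped into its space."""
    return [p for s, f in fits.items()
            if (p := _project(s, f.params, scenario)) is not None and s != scenario]


def _project(src_scenario: str, params: dict[str, float], target: str) -> dict[str, float] | None:
    """Project a fitted parameter vector of one scenario into another
    scenario's parameter space, preserving total divergence time and the
    time-averaged migration rates. Used for warm starts; returns None for
    the identity projection."""
    if src_scenario == target:
        return None
    t_lo, m_lo = DEFAULT_BOUNDS["T"][0], DEFAULT_BOUNDS["M"][0]
    model = DivergenceModel(src_scenario, params)
    epochs, t_tot = model.epochs()
    t_tot = max(t_tot, 2 * t_lo)
    # preserve the total migrant flux: average each rate over the whole
    # divergence period when the target has migration throughout
    m12 = sum((t1 - t0) * M12 for (t0, t1, M12, _) in epochs) / t_tot
    m21 = sum((t1 - t0) * M21 for (t0, t1, _, M21) in epochs) / t_tot
    m12, m21 = max(m12, 10 * m_lo), max(m21, 10 * m_lo)
    nu = {"nu1": params["nu1"], "nu2": params["nu2"]}
    if target == "SI":
        return {**nu, "T_S": t_tot}
    if target == "IM":
        return {**nu, "T_S": t_tot, "M12": m12, "M21": m21}
    # duration of migration touching the present (for SC-like targets) or the
    # split (for AM-like targets)
    recent = sum(t1 - t0 for (t0, t1, _, _) in epochs if t0 < 1e-9)
    ancient = sum(t1 - t0 for (t0, t1, _, _) in epochs if abs(t1 - t_tot) < 1e-9 and t0 > 1e-9)
    if target in ("SC", "PSC"):
        t_c = min(max(recent, 2 * t_lo), t_tot - t_lo)
        base = {**nu, "T_S": t_tot - t_c, "T_SC": t_c}
        if target == "SC":
            return {**base, "M12": m12, "M21": m21}
        return {**base, "mA": m12, "mB": m21, "mC": m12, "mD": m21}
    if target in ("AM", "PAM"):
        t_a = min(max(ancient, 2 * t_lo), t_tot - t_lo)
        base = {**nu, "T_S": t_tot - t_a, "T_AM": t_a}
        if target == "AM":
            return {**base, "M12": m12, "M21": m21}
        return {**base, "mA": m12, "mB": m21, "mC": m12, "mD": m21}
    raise ValueError(f"unknown target scenario {target!r}")


#: nesting-aware fitting order
_FIT_ORDER = ("SI", "IM", "AM", "SC", "PAM", "PSC")


def fit_scenarios(observed: FoldedJSFS, scenarios=("SI", "IM", "SC"), seed: int = 0,
                  rescue_margin: float = 1.0, rescue_cap: float = 25.0,
                  extra_warm: dict[str, list[dict[str, float]]] | None = None,
                  **fit_kw) -> dict[str, ModelFitResult]:
    """Fit several scenarios to one spectrum with convergence safeguards.

    Scenarios are fitted in nesting order, each warm-started from the best
    fits of the scenarios nested within it. A reconciliation pass then gives
    every scenario whose logL trails the best model by more than
    ``rescue_margin`` one rescue refit (no global scan), warm-started from
    every other fitted model projected into its parameter space; the refit
    is kept if it improves. This equalizes convergence quality across
    models, so AIC differences reflect fit, not optimizer luck. All models
    share the same final-evaluation seed. ``extra_warm`` supplies additional
    warm starts per scenario (e.g. fits of a neighbouring replicate dataset
    in a simulation study).
    """
    todo = [s for s in _FIT_ORDER if s in scenarios]
    if set(todo) != set(scenarios):
        raise ValueError(f"unknown scenarios in {scenarios}")
    fits: dict[str, ModelFitResult] = {}
    for s in todo:
        warm = _warm_maps(s, fits) + list((extra_warm or {}).get(s, []))
        fits[s] = fit_model(observed, s, seed=seed, warm_starts=warm, **fit_kw)
    best_logl = max(f.logl for f in fits.values())
    rescue_kw = {**fit_kw, "n_scan": 0, "n_replicates": 1}
    for s in todo:
        deficit = best_logl - fits[s].logl
        # a deficit beyond the cap reflects a genuinely worse model, not an
        # under-converged fit; rescuing it would be wasted effort
        if not (rescue_margin < deficit < rescue_cap):
            continue
        if True:
            warm = [fits[s].params] + _warm_maps(s, fits)
            refit = fit_model(observed, s, seed=seed + 1, warm_starts=warm, **rescue_kw)
            if refit.logl > fits[s].logl:
                fits[s] = refit
    # projection coherence: every model is also offered every other model's
    # solution projected into its own space (e.g. an SC fit that collapsed
    # onto the IM boundary is credited to IM); evaluated at the shared final
    # seed and kept only if better
    eval_kw = {k: v for k, v in fit_kw.items()
               if k in ("n_reps_final", "ascertained", "anchor")}
    eval_kw = {"n_reps": eval_kw.get("n_reps_final", 20_000),
               "ascertained": eval_kw.get("ascertained", False),
               "anchor": eval_kw.get("anchor")}
    best_logl = max(f.logl for f in fits.values())
    for s in todo:
        if fits[s].logl < best_logl - rescue_cap:
            continue  # genuinely worse model; projections will not save it
        for other in todo:
            if other == s or fits[other].logl < best_logl - rescue_cap:
                continue
            cand = _project(other, fits[other].params, s)
            if cand is None:
                continue
            trial = evaluate_fit(observed, s, cand, seed=seed, **eval_kw)
            if trial.logl > fits[s].logl:
                fits[s] = trial
    return fits


# ---------------------------------------------------------------------------
# information criteria
# ---------------------------------------------------------------------------

def aic(logl: float, k: int) -> float:
    """Akaike information criterion, 2K - 2 logL."""
    if k < 1:
        raise ValueError("K must be >= 1")
    return 2.0 * k - 2.0 * logl


def model_scores(aics) -> np.ndarray:
    """Relative scores: (Dmax - dAIC_i) / Dmax, so the best model scores 1
    and the worst 0."""
    a = np.asarray(aics, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two models")
    dmax = a.max() - a.min()
    if dmax == 0:
        raise ValueError("all AIC values equal; scores undefined")
    return (dmax - (a - a.min())) / dmax


def akaike_weights(aics) -> np.ndarray:
    """w_i = exp(-dAIC_i/2) / sum_j exp(-dAIC_j/2) (max-subtracted)."""
    a = np.asarray(aics, dtype=float)
    d = a - a.min()
    w = np.exp(-d / 2.0)
    return w / w.sum()


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

@dataclass
class ConversionInputs:
    """Quantities needed to express scaled parameters in biological units.

    x: SNPs originally detected; y: number of RAD tags (of ``tag_length_bp``)
    in the initial data; z: SNPs retained for the spectrum. ``mu`` is the
    per-site per-generation mutation rate.
    """

    x_snps_detected: float
    y_rad_tags: float
    z_snps_retained: float
    mu: float = 2.3e-9
    generation_time_years: float = 10.0
    tag_length_bp: float = 73.0

    def __post_init__(self):
        for v in (self.x_snps_detected, self.y_rad_tags, self.z_snps_retained, self.mu,
                  self.generation_time_years, self.tag_length_bp):
            if v <= 0:
                raise ValueError("conversion inputs must be positive")


def effective_length(inputs: ConversionInputs) -> float:
    """Effective genome length explored: L = z * y * tag_length / x."""
    return inputs.z_snps_retained * inputs.y_rad_tags * inputs.tag_length_bp / inputs.x_snps_detected


def ancestral_ne(theta: float, L: float, mu: float) -> float:
    """Ancestral effective size before the split: N_ref = theta / (4 L mu)."""
    if L <= 0:
        raise ValueError("effective length must be > 0")
    return theta / (4.0 * L * mu)


def convert_units(fit: ModelFitResult, inputs: ConversionInputs) -> dict[str, float]:
    """Report the fit in biological units: N_ref individuals, epoch times in
    years, migration as proportion of migrants per generation."""
    L = effective_length(inputs)
    nref = ancestral_ne(fit.theta, L, inputs.mu)
    out = {"L_bp": L, "N_ref": nref}
    for name, val in fit.params.items():
        if name.startswith("T"):
            out[f"{name}_years"] = val * 2.0 * nref * inputs.generation_time_years
        elif name.startswith("M") or name.startswith("m"):
            out[f"{name}_proportion_per_generation"] = val / (2.0 * nref)
        elif name.startswith("nu"):
            out[f"N{name[2:]}_individuals"] = val * nref
    return out


def fit_report(fits: list[ModelFitResult]) -> pd.DataFrame:
    """One row per scenario: K, LogL, AIC, Score, W_AIC and parameters."""
    aics = [f.aic for f in fits]
    scores = model_scores(aics)
    weights = akaike_weights(aics)
    rows = []
    for f, s, w in zip(fits, scores, weights):
        rows.append({"model": f.scenario, "K": f.k, "LogL": f.logl, "AIC": f.aic,
                     "Score": s, "W_AIC": w, "theta": f.theta, **f.params})
    return pd.DataFrame(rows).set_index("model")
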