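# Methods

`seaconnect` implements a multidisciplinary connectivity analysis for a pair
of long-dispersing marine species — the rock lobsters *Jasus tristani*
(southern Atlantic) and *J. paulensis* (southern Indian Ocean) — combining a
Lagrangian larval-transport model, genotype-based first-generation migrant
detection, and divergence-with-migration model selection on the joint site
frequency spectrum (JSFS). Every input is generated synthetically at desk
scale; this note records the models, the parameter choices, the numerical
decisions, and what the synthetic studies do and do not show.

## Synthetic ocean forcing

The flow generator composes three analytic ingredients on a regular 0.5°
lon/lat grid:

* **Anticyclonic gyre.** A squared-sine basin-mode streamfunction
  ψ = A sin²(πX) sin²(πY) over the gyre box, with velocities taken as the
  spherical-metric derivatives (u = −∂ψ/∂y, v = +∂ψ/∂x). The squared-sine
  profile makes velocities vanish smoothly on the box edge, and the
  streamfunction construction gives an analytic oracle and
  divergence-free flow by construction. The amplitude is negative —
  a Southern-Hemisphere anticyclone rotates counterclockwise, i.e. eastward
  along its southern limb. Peak speed defaults to 0.15 m/s.
* **Zonal jet.** An eastward Gaussian jet u(φ) = U exp(−½((φ−φ₀)/σ)²),
  default U = 0.10 m/s, σ = 2°, at 38°S — the Subtropical-Front analogue.
* **Leakage corridor.** An optional weak westward Gaussian band
  (default 0.03 m/s) standing in for Agulhas-leakage transport.

Magnitudes are free choices (no quantitative values are available for the
real fronts at the level this model needs); they are typical of subtropical
gyre rims and frontal jets and were fixed once when the basin was designed.
Islands are circular land masks (default 30 km radius) ringed by shallow
(500 m) bathymetry out to 90 km — the spawning habitat — inside a 4000 m
deep basin. Fields are written as CF-style NetCDF (scipy backend,
NETCDF3).

What this forcing does **not** emulate: mesoscale eddies, Agulhas rings,
seasonality, or interannual variability. Passing transport tests on it
demonstrates kernel correctness (interpolation, integration, boundary
handling, age gating), not realism of any particular connectivity value.

## Lagrangian transport model

Particles represent phyllosoma larvae. Per 30-minute step (all defaults
configurable):

1. **Advection** by midpoint second-order Runge-Kutta on the interpolated
   velocity (multilinear in space, linear in time between archived means;
   land cells carry zero velocity so flow decays toward the coast). The
   ODE is integrated in degree coordinates with the metre-to-degree metric
   evaluated at each stage's own latitude, which preserves second-order
   accuracy through the cos-latitude factor. Earth radius 6371 km.
   A note on verification: for circular motion the *radial* drift of
   midpoint RK2 is third-order (the per-step amplification factor is
   1 + O(h⁴)); the second-order behaviour appears in the phase, so the
   convergence test measures total position error against the analytic
   trajectory.
2. **Random-walk diffusion** with per-axis variance 2KΔt; defaults
   K_h = 100 m²/s (mesoscale-unresolved stirring) and K_v = 10⁻⁴ m²/s.
   Vertical positions are confined to 0–200 m by reflection; there is no
   vertical advection and the archived velocities are depth-independent, so
   depth affects no horizontal displacement (it is carried for provenance
   and the reflection law is tested).
3. **Boundary policy**: default "slide" (try the zonal-only then the
   meridional-only component of a move that would land on land; stay put if
   both fail), with "reflect" and "halt" selectable; leaving the domain
   marks a particle lost under every policy.
4. **Ageing and fate.** Ages are gated in 30.44-day months: competency at
   15 months (456.6 d), maximum planktonic duration 22 months (669.7 d).
   A competent particle inside any recruitment zone (within 100 km of a
   population site) is recruited there and removed; over-age particles
   expire. There is no mortality and no larval behaviour.

Releases follow the survey protocol: every ocean grid cell shallower than
1000 m within 100 km of a site releases a fixed number of particles per day
(100/cell/day at full scale) across an August–October spawning window, with
uniform-random initial depths in 0–200 m. Particle conservation
(released = active + recruited + expired + lost) is asserted at every step.

Connectivity products: annual destination × source percentage matrices
(undefined, not zero, for a site with no releases that year; attribution by
release year), across-year mean/SD/nonzero-year summaries (population-SD
convention — the simulated years are the whole population of years), the
log₁₀(10x+1) display transform, and pathway-density grids (percentage of
successful source→target particles visiting each cell at least once,
counted from a 12-hourly decimated visit log).

The **two-island reference experiment** places islands 46° of longitude
apart in the jet, so the ~0.1 m/s transit arrives just inside the
competency window; it yields strong downstream connectivity (A→B ≈ 73% of
released particles in the reference run), none upstream, and recruitment
ages strictly within 15–22 months, with ~1,800 particles in under a minute.

## First-generation migrant detection

Assignment uses the Dirichlet posterior-predictive genotype likelihood
(prior concentration 1/k per allele, k = 2 for SNPs): per locus, the
probability of the query genotype given the reference allele counts;
independent loci multiply; missing loci are skipped; the home population's
likelihood removes the individual's own alleles from its reference
(leave-one-out). The statistic is Λ = log₁₀L_max − log₁₀L_home ≥ 0, and an
individual is flagged as a first-generation migrant when its Monte-Carlo
p-value falls below α (default 0.01) and its best-likelihood population is
not its sampling location.

The Monte-Carlo null is the part that required care. Simulated individuals
drawn from a population's estimated frequencies and scored *against those
same frequencies* are in-sample: their home likelihood is systematically
inflated relative to a real individual scored out-of-sample (leave-one-out),
and with hundreds of SNPs the resulting null is far too tight (a measured
22% type-I rate at nominal α = 0.01). The implemented null therefore
resamples the reference itself per replicate — query genotype ~ Binom(2, p̂)
and an independent leave-one-out home reference ~ Binom(2(n−1), p̂) per locus
— reproducing the out-of-sample structure of the observed statistic. With
this construction the flagged fraction under a panmictic null sits inside
the binomial band around α, and planted migrants at F_ST = 0.2 with 300 SNPs
are detected with essentially full power.

Directional source–sink aggregation sums the two cross-species blocks of a
sink × source migrant table and reports each direction's total and
percentage; the six published Jasus tables are carried in
`seaconnect.datasets` as inputs and reproduce the reported range endpoints
exactly. Historical (coalescent-sampler) tables are consumed as inputs
only; the sampler itself is out of scope, and migrants per generation are
the product Θ·M of the mutation-scaled size and immigration rate.

## Divergence-model selection on the folded JSFS

Six piecewise-constant two-population scenarios: SI (strict isolation), IM
(continuous migration), AM (ancient migration then isolation), SC
(isolation then secondary contact), and the two-event variants PAM/PSC in
which the migration era is split into two equal-duration epochs with
separate asymmetric rate pairs (mA, mB) then (mC, mD). Parameters follow
the diffusion-method conventions: sizes ν relative to the ancestral N_ref,
times in 2N_ref generations, migration rates per 2N_ref generations, with
M12 the movement of genes from population 2 into population 1. The
reported parameter count K per scenario follows the published
model-comparison convention (SI 3, IM 5, AM 6, SC 6, PAM 6, PSC 8); note
PAM's printed K = 6 undercounts its four migration rates, an inconsistency
of the source convention that is preserved for comparability (nothing here
fits PAM).

**Expected spectra.** The expected folded JSFS is computed by coalescent
Monte Carlo: replicate single-locus genealogies (msprime) and the
branch-mode joint allele frequency spectrum averaged, folded (complementary
cells pooled, the central ambiguity diagonal halved, monomorphic corners
masked), and normalized. This is a numerical-method substitution for a
diffusion PDE engine with the same expectation target; nested-limit
identities (SC at T_SC = 0 ≡ SI; IM at m = 0 ≡ SI; the single-population
1/i limit) are verified against it. An *ascertained* mode normalizes each
genealogy's spectrum by its own total branch length first, matching
one-SNP-per-locus data.

**Likelihood.** Poisson composite likelihood over unmasked cells. Two
conventions are provided: the profiled form (the multiplicative θ solved
analytically, θ̂ = Σobs/Σexp) for rate-free data, and an absolute-rate
("anchored") form λ = n_loci·θ_locus/4 × expected branch spectrum for data
whose per-locus mutation rate is known — as in the package's own synthetic
studies. The anchor matters: with the spectrum shape alone, a joint
rescaling of (ν₁, ν₂, T) compensated by migration is nearly flat (direct
probes found <1 log-unit between the truth and a 67%-displaced ridge
point), so split times cannot be recovered to 25%; the spectrum total,
which scales with expected tree length, removes that ridge.

**Optimization under Monte-Carlo noise.** The objective is itself an MC
estimate whose noise exceeds local parameter signals, and its bias (from
log of a noisy mean) is parameter-dependent — naive local search stalls or
drifts toward smooth-spectrum models. The fit therefore uses a stochastic
response-surface design: a global random scan; per-restart trust-region
chains in log-parameter space, each step fitting a least-squares quadratic
to a batch of independently seeded evaluations and jumping to its
constrained maximum; re-ranking of restart endpoints at high replication;
a polish schedule of shrinking boxes; and block-coordinate refinement (the
migration pair and the size/time block refined separately, where
low-dimensional quadratics resolve soft directions). Evaluations carry a
second-order bias correction obs·var/(2·mean²) (capped), and every chain
keeps the better of its start and end under a common higher-replication
check, so steps are never trusted blindly. When several scenarios are
fitted together, nested models warm-start their supersets, models trailing
the leader by more than a margin get one rescue refit, and a projection
coherence pass offers every model every other model's solution projected
into its own space (preserving total divergence time and time-averaged
rates) — so AIC differences reflect fit, not optimizer luck. All models
fitted with the same seed share their final-evaluation seed.

**Model comparison.** AIC = 2K − 2logL; relative scores
(Δmax − ΔAIC)/Δmax (best 1, worst 0); Akaike weights with max-subtraction.
Applied to the published six-scenario table these reproduce the printed
Score and weight columns; the printed integer log-likelihoods reproduce the
printed AIC column only to ±1 unit for two scenarios (a rounding artifact
of the source), so both columns are stored and the scores use the printed
AICs.

**Unit conversions.** Effective genome length L = z·y·73/x from the RAD-tag
accounting; N_ref = θ/(4Lμ) with μ = 2.3×10⁻⁹ per site per generation;
times in years as T·2N_ref·g with a 10-year generation time; migration as
proportion of migrants per generation, rate/(2N_ref). All are exact algebra
and tested as round-trips; no empirical value is claimed for the real
system's divergence date, whose published derivation depends on unprinted
inputs (x, y).

## The frozen simulation studies

* **Recovery** (`studies.recovery_study`): 10,000 unlinked RAD-like loci
  (θ_locus = 0.1, one realized SNP set of ~7,100 segregating sites),
  n = 14+14 haploid genomes, generated under IM at (ν₁ = ν₂ = 1, T_S = 2,
  M12 = 1, M21 = 0.4) — moderate asymmetric gene flow chosen for
  identifiability: ±25% perturbations of each target parameter must cost
  several log-likelihood units for a 25% recovery claim to be meaningful
  (strong migration hides T; near-zero migration hides the rates). Fitted
  with 20 replicate restarts under the anchored likelihood. Reference-run
  errors: ~1% (T_S), ~6% (M12), ~7% (M21).
* **Selection consistency** (`studies.selection_study`): 20 replicate
  datasets at reduced scale (700 loci, n = 8+8) fitted under {SI, IM, SC};
  each dataset warm-starts from the previous dataset's fits (one generating
  truth; a cold-start fit seeds the chain), and the winner is the lowest
  AIC. The dataset size balances the two discriminations: the gap to SI
  grows with the number of sites, while the IM-vs-SC comparison is decided
  by a fixed 2-unit AIC penalty that Monte-Carlo evaluation noise
  (proportional to the number of sites at fixed replication) must not
  swamp. Because IM is the boundary case of SC, SC can genuinely out-fit
  IM by more than the penalty with boundary probability ~½·P(χ²₁ > 2) ≈ 8%
  per replicate; occasional SC wins are expected behaviour of AIC itself,
  not an implementation defect.

Problem sizes throughout (grid resolutions, particle counts, locus numbers,
Monte-Carlo replication, restart budgets) are the package's desk-scale
choices: large enough for each statistical claim to be meaningful, small
enough that the complete test suite runs on one CPU in tens of minutes.
All seeds are explicit; every study is bit-reproducible.

## Known limitations

* The transport model is 2-D in effect (no vertical advection, no
  behaviour, no mortality); connectivity percentages are upper bounds on
  demographic connectivity.
* Annual matrices are single-generation: stepping-stone (multi-generation)
  transport is out of scope.
* The coalescent-MC likelihood remains noisy; fitted log-likelihoods carry
  an evaluation uncertainty of a fraction of a unit at the final
  replication, which is negligible for the score/weight arithmetic but
  would matter for likelihood-ratio tests at finer resolution.
* Genotype simulation is Balding-Nichols with unlinked biallelic loci and
  missing-at-random calls; real RAD data add linkage, allele dropout and
  depth-dependent missingness that the assignment calibration here does not
  probe.
* The diversity report's H_O/H_E conventions are standard (unbiased H_E,
  rarefied richness); no attempt is made to reproduce the real survey's
  absolute Table values, which depend on filtering details not derivable
  from the publication.
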