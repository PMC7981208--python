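"""Coalescent realization of folded joint SFS data under divergence scenarios.

Loci are unlinked: each is an independent single-locus genealogy simulated
under the scenario's piecewise history. By default each retained locus
carries exactly one SNP, placed on the genealogy with probability
proportional to branch length (an infinite-sites draw conditioned on the
locus being polymorphic, mimicking RAD-SNP ascertainment); the folded
spectrum's entry total then equals the number of retained loci exactly. A
free-mutation mode overlays Poisson mutations at a given per-locus theta and
keeps every segregating site instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

from ..demography import DivergenceModel
from ..jsfs import FoldedJSFS, fold_spectrum


@dataclass
class ScenarioSimSpec:
    scenario: str
    params: dict[str, float]
    n1: int = 20
    n2: int = 20
    n_loci: int = 1000
    seed: int = 0
    one_snp_per_locus: bool = False
    locus_theta: float = 0.1  # scaled mutation rate per locus (mutation-overlay mode)

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("need at least two haploid samples per population")
        if self.n_loci < 1:
            raise ValueError("need at least one locus")
        # delegates scenario/parameter validation
        self.model = DivergenceModel(self.scenario, self.params)


def simulate_jsfs(spec: ScenarioSimSpec) -> FoldedJSFS:
    """Deterministic given (spec, seed)."""
    ss = np.random.SeedSequence(spec.seed)
    msp_seed = int(ss.generate_state(1)[0] % (2**31 - 1)) + 1
    rng = np.random.default_rng(ss.spawn(1)[0])
    dem = spec.model.to_msprime()
    samples = [
        msprime.SampleSet(spec.n1, population="P1", ploidy=1),
        msprime.SampleSet(spec.n2, population="P2", ploidy=1),
    ]
    unfolded = np.zeros((spec.n1 + 1, spec.n2 + 1))
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, ploidy=2,
        num_replicates=spec.n_loci, random_seed=msp_seed,
    )
    if spec.one_snp_per_locus:
        for ts in reps:
            tree = ts.first()
            nodes = [u for u in tree.nodes() if tree.parent(u) != -1]
            lengths = np.array([tree.branch_length(u) for u in nodes])
            u = nodes[rng.choice(len(nodes), p=lengths / lengths.sum())]
            below = list(tree.samples(u))
            i = sum(1 for s in below if s < spec.n1)
            j = len(below) - i
            unfolded[i, j] += 1
    else:
        mut_seeds = rng.integers(1, 2**31 - 1, size=spec.n_loci)
        sets = [list(range(spec.n1)), list(range(spec.n1, spec.n1 + spec.n2))]
        for k, ts in enumerate(reps):
            mts = msprime.sim_mutations(
                ts, rate=spec.locus_theta / 4.0, random_seed=int(mut_seeds[k]),
                discrete_genome=False,
            )
            unfolded += mts.allele_frequency_spectrum(
                sample_sets=sets, mode="site", polarised=True, span_normalise=False
            )
    return fold_spectrum(unfolded)
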