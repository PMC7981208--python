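"""Structured multi-population genotype simulation with planted migrants.

Population structure follows the Balding-Nichols model: each locus has an
ancestral frequency p drawn from a truncated uniform, and each population
draws its own frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so the expected
Weir-Cockerham F_ST across populations is approximately the drift parameter
F. Individuals are Hardy-Weinberg draws from their population frequency;
planted first-generation migrants are drawn from their true source
population's frequencies but labelled with the sink population.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..genio import MISSING, GenotypeMatrix


@dataclass
class PlantedMigrant:
    sink: str   # population the individual is (mis)labelled with
    source: str  # population whose allele frequencies generated it


@dataclass
class GenotypeSimSpec:
    n_populations: int = 2
    sample_sizes: tuple[int, ...] = (50, 50)
    n_loci: int = 300
    target_fst: float = 0.1
    ancestral_freq_range: tuple[float, float] = (0.05, 0.95)
    migrants: list[PlantedMigrant] = field(default_factory=list)
    missing_rate: float = 0.0
    seed: int = 0

    def population_names(self) -> list[str]:
        return [f"pop{i + 1}" for i in range(self.n_populations)]

    def validate(self) -> None:
        if len(self.sample_sizes) != self.n_populations:
            raise ValueError("need one sample size per population")
        if any(n < 1 for n in self.sample_sizes):
            raise ValueError("sample sizes must be >= 1")
        if not 0.0 <= self.target_fst < 1.0:
            raise ValueError("target F_ST must be in [0, 1)")
        names = set(self.population_names())
        for m in self.migrants:
            if m.sink not in names or m.source not in names:
                raise ValueError(f"planted migrant references unknown population: {m}")
        from collections import Counter

        per_sink = Counter(m.sink for m in self.migrants)
        for pop, n in zip(self.population_names(), self.sample_sizes):
            if per_sink.get(pop, 0) > n:
                raise ValueError(f"more planted migrants than samples in {pop}")


def make_genotypes(spec: GenotypeSimSpec) -> GenotypeMatrix:
    """Deterministic given (spec, seed). Planted migrants replace the first
    individuals of their sink population (their ids carry a ``mig`` suffix)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pops = spec.population_names()
    lo, hi = spec.ancestral_freq_range
    p_anc = rng.uniform(lo, hi, size=spec.n_loci)
    F = spec.target_fst
    if F > 0:
        a = p_anc * (1.0 - F) / F
        b = (1.0 - p_anc) * (1.0 - F) / F
        freqs = {pop: rng.beta(a, b) for pop in pops}
    else:
        freqs = {pop: p_anc for pop in pops}

    codes, labels, ids = [], [], []
    migrant_queue: dict[str, list[PlantedMigrant]] = {}
    for m in spec.migrants:
        migrant_queue.setdefault(m.sink, []).append(m)
    for pop, n in zip(pops, spec.sample_sizes):
        planted = migrant_queue.get(pop, [])
        for k in range(n):
            if k < len(planted):
                src = planted[k].source
                ids.append(f"{pop}_mig{k:02d}_from_{src}")
                g = rng.binomial(2, freqs[src])
            else:
                ids.append(f"{pop}_ind{k:03d}")
                g = rng.binomial(2, freqs[pop])
            codes.append(g.astype(np.int8))
            labels.append(pop)
    codes = np.stack(codes)
    if spec.missing_rate > 0:
        drop = rng.random(codes.shape) < spec.missing_rate
        codes = np.where(drop, MISSING, codes).astype(np.int8)
    return GenotypeMatrix(codes=codes, populations=np.asarray(labels, dtype=object), individuals=ids)
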