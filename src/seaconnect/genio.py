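"""Diploid biallelic genotype matrices and their file formats.

Genotypes are stored as alternate-allele dosage codes: 0, 1, 2 and -1 for
missing. Individuals carry a population label. Matrices round-trip through
minimal GT-only VCF (read back with cyvcf2) and through Genepop (two-digit
allele coding, 0000 for missing), plus a two-column population map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = -1


@dataclass
class GenotypeMatrix:
    codes: np.ndarray                 # (n_individuals, n_loci) int8, -1/0/1/2
    populations: np.ndarray           # (n_individuals,) str labels
    individuals: list[str] = field(default_factory=list)
    loci: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.populations = np.asarray(self.populations, dtype=object)
        if self.codes.ndim != 2:
            raise ValueError("codes must be 2-D (individuals x loci)")
        if self.populations.size != self.codes.shape[0]:
            raise ValueError("every individual needs a population label")
        if not self.individuals:
            self.individuals = [f"ind{i:04d}" for i in range(self.codes.shape[0])]
        if not self.loci:
            self.loci = [f"locus{j:05d}" for j in range(self.codes.shape[1])]
        bad = ~np.isin(self.codes, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.codes.shape[1]

    @property
    def population_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def subset_individuals(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            codes=self.codes[idx],
            populations=self.populations[idx],
            individuals=[self.individuals[i] for i in idx],
            loci=list(self.loci),
        )

    def subset_loci(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            codes=self.codes[:, idx],
            populations=self.populations,
            individuals=list(self.individuals),
            loci=[self.loci[j] for j in idx],
        )

    def allele_counts(self, population: str | None = None, exclude: int | None = None) -> np.ndarray:
        """Per-locus (ref, alt) allele counts over non-missing calls.

        ``exclude`` removes one individual's alleles (leave-one-out).
        Returns an (n_loci, 2) float array.
        """
        sel = np.ones(self.n_individuals, dtype=bool) if population is None else self.populations == population
        if exclude is not None:
            sel = sel.copy()
            sel[exclude] = False
        sub = self.codes[sel]
        called = sub != MISSING
        alt = np.where(called, sub, 0).sum(axis=0).astype(float)
        tot = 2.0 * called.sum(axis=0)
        return np.stack([tot - alt, alt], axis=1)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.individuals) + "\n")
        for j, locus in enumerate(g.loci):
            row = "\t".join(_GT[int(c)] for c in g.codes[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\tPASS\t.\tGT\t{row}\n")


def read_vcf(path, populations) -> GenotypeMatrix:
    """Read a GT-only VCF with cyvcf2. ``populations`` maps individual id ->
    population label (or is a path to a two-column map file)."""
    from cyvcf2 import VCF

    if not isinstance(populations, dict):
        populations = read_population_map(populations)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, loci = [], []
    for var in vcf:
        gts = np.asarray(var.genotypes, dtype=object)
        a = np.array([g[0] for g in gts])
        b = np.array([g[1] for g in gts])
        code = np.where((a < 0) | (b < 0), MISSING, a + b)
        cols.append(code.astype(np.int8))
        loci.append(var.ID or f"{var.CHROM}:{var.POS}")
    return GenotypeMatrix(
        codes=np.stack(cols, axis=1),
        populations=np.array([populations[s] for s in samples], dtype=object),
        individuals=samples,
        loci=loci,
    )


# ---------------------------------------------------------------------------
# Genepop
# ---------------------------------------------------------------------------

def write_genepop(g: GenotypeMatrix, path, title="seaconnect export") -> None:
    code2 = {0: "0101", 1: "0102", 2: "0202", MISSING: "0000"}
    with open(path, "w") as fh:
        fh.write(title + "\n")
        fh.write("\n".join(g.loci) + "\n")
        for pop in g.population_ids:
            fh.write("POP\n")
            for i in np.flatnonzero(g.populations == pop):
                geno = " ".join(code2[int(c)] for c in g.codes[i])
                fh.write(f"{g.individuals[i]} ,  {geno}\n")


def read_genepop(path) -> GenotypeMatrix:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        loci.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    back = {"0101": 0, "0102": 1, "0201": 1, "0202": 2, "0000": MISSING}
    codes, pops, inds = [], [], []
    pop_no = 0
    while i < len(lines):
        if lines[i].strip().upper() == "POP":
            pop_no += 1
            i += 1
            continue
        if not lines[i].strip():
            i += 1
            continue
        name, geno = lines[i].split(",", 1)
        inds.append(name.strip())
        pops.append(f"pop{pop_no}")
        codes.append([back[tok] for tok in geno.split()])
        i += 1
    return GenotypeMatrix(
        codes=np.asarray(codes, dtype=np.int8),
        populations=np.asarray(pops, dtype=object),
        individuals=inds,
        loci=loci,
    )


# ---------------------------------------------------------------------------
# population map
# ---------------------------------------------------------------------------

def write_population_map(g: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for ind, pop in zip(g.individuals, g.populations):
            fh.write(f"{ind}\t{pop}\n")


def read_population_map(path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for ln in fh:
            if ln.strip():
                ind, pop = ln.split()[:2]
                out[ind] = pop
    return out
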