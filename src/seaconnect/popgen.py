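"""Per-population diversity and pairwise differentiation summaries.

Observed heterozygosity is the per-locus fraction of heterozygous calls among
non-missing genotypes, averaged over loci. Expected heterozygosity uses the
unbiased small-sample estimator 2n/(2n-1) * (1 - sum p^2). Allelic richness
is rarefied to a common number of gene copies with the standard
hypergeometric formula. Pairwise F_ST uses the Weir-Cockerham (1984)
variance-components estimator summed over loci, with label-permutation
p-values (add-one correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genio import MISSING, GenotypeMatrix


def _log_comb(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return np.where(k > n, -np.inf, out)


def rarefied_richness(counts: np.ndarray, g: int) -> np.ndarray:
    """Expected number of distinct alleles per locus in a draw of ``g`` gene
    copies, from per-locus allele counts (n_loci, n_alleles)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        miss = np.exp(_log_comb(n - counts, g) - _log_comb(n, g))
    miss = np.where(np.isfinite(miss), miss, 0.0)
    return (1.0 - miss).sum(axis=1)


def diversity(gmat: GenotypeMatrix, rarefaction_size: int | None = None) -> pd.DataFrame:
    """Per-population sample size, H_O, H_E (unbiased) and rarefied A_R.

    Rarefaction defaults to twice the smallest per-locus complete-genotype
    count over populations and loci.
    """
    pops = gmat.population_ids
    called = gmat.codes != MISSING
    n_called = {p: called[gmat.populations == p].sum(axis=0) for p in pops}
    min_complete = min(int(n_called[p].min()) for p in pops)
    if min_complete == 0:
        raise ValueError("a population has zero non-missing calls at some locus")
    g = rarefaction_size if rarefaction_size is not None else 2 * min_complete

    rows = []
    for p in pops:
        sub = gmat.codes[gmat.populations == p]
        callp = sub != MISSING
        n_loc = callp.sum(axis=0).astype(float)
        het = ((sub == 1) & callp).sum(axis=0)
        ho = np.mean(het / n_loc)
        alt = np.where(callp, sub, 0).sum(axis=0) / (2.0 * n_loc)
        ssq = alt**2 + (1.0 - alt) ** 2
        he = np.mean((2.0 * n_loc / (2.0 * n_loc - 1.0)) * (1.0 - ssq))
        counts = gmat.allele_counts(p)
        ar = np.mean(rarefied_richness(counts, g))
        rows.append({"population": p, "n": int((gmat.populations == p).sum()), "H_O": ho, "H_E": he, "A_R": ar})
    return pd.DataFrame(rows).set_index("population")


# ---------------------------------------------------------------------------
# Weir-Cockerham F_ST
# ---------------------------------------------------------------------------

def _wc_components(codes_a: np.ndarray, codes_b: np.ndarray):
    """Per-locus Weir-Cockerham (1984) variance components (a, b, c) for two
    samples of dosage-coded genotypes. Returns (n_loci,) arrays."""
    comps = []
    for sub in (codes_a, codes_b):
        callp = sub != MISSING
        n = callp.sum(axis=0).astype(float)  # diploid individuals called
        alt = np.where(callp, sub, 0).sum(axis=0) / np.maximum(2.0 * n, 1.0)
        hobs = ((sub == 1) & callp).sum(axis=0) / np.maximum(n, 1.0)
        comps.append((n, alt, hobs))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    valid = (n1 > 0) & (n2 > 0) & (nbar > 1)
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0) / (nbar - 1.0))
        b = (nbar / (nbar - 1.0)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar)
    c = hbar / 2.0
    a = np.where(valid, a, 0.0)
    b = np.where(valid, b, 0.0)
    c = np.where(valid, c, 0.0)
    return a, b, c


def wc_fst(codes_a: np.ndarray, codes_b: np.ndarray) -> float:
    """Multilocus Weir-Cockerham theta: sum(a) / sum(a + b + c)."""
    a, b, c = _wc_components(codes_a, codes_b)
    denom = np.sum(a + b + c)
    if denom == 0:
        return np.nan
    return float(np.sum(a) / denom)


@dataclass
class FstReport:
    """Pairwise matrix with F_ST below the diagonal (reporting floor at 0)
    and permutation p-values above."""

    matrix: pd.DataFrame
    n_permutations: int
    seed: int


def pairwise_fst(gmat: GenotypeMatrix, n_permutations: int = 999, seed: int = 0) -> FstReport:
    if n_permutations < 99:
        raise ValueError("need at least 99 permutations")
    pops = gmat.population_ids
    if len(pops) < 2:
        raise ValueError("need at least two populations")
    for p in pops:
        if (gmat.populations == p).sum() < 2:
            raise ValueError(f"population {p} has fewer than 2 individuals")
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(np.nan, index=list(pops), columns=list(pops))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            ca = gmat.codes[gmat.populations == pops[i]]
            cb = gmat.codes[gmat.populations == pops[j]]
            obs = wc_fst(ca, cb)
            pooled = np.concatenate([ca, cb])
            na = ca.shape[0]
            exceed = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pooled.shape[0])
                if wc_fst(pooled[perm[:na]], pooled[perm[na:]]) >= obs:
                    exceed += 1
            pval = (exceed + 1.0) / (n_permutations + 1.0)
            mat.iloc[j, i] = max(obs, 0.0)
            mat.iloc[i, j] = pval
    return FstReport(matrix=mat, n_permutations=n_permutations, seed=seed)
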