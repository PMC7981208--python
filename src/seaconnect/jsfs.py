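"""Folded two-population joint site frequency spectra.

The joint SFS is an (n1+1) x (n2+1) array of SNP counts indexed by derived
(or, after folding, minor) allele counts in each population. Folding pools
each entry (i, j) with its complement (n1-i, n2-j); entries with
i + j > (n1+n2)/2 are masked, and the central ambiguity diagonal
(i + j == (n1+n2)/2) is halved after pooling so the total is conserved. The
two monomorphic corners are always masked. Text I/O follows the dadi flat
format: a dimensions line (with "folded"/"unfolded"), a line of flattened
entries, and a mask line of 0/1 flags (1 = masked).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class FoldedJSFS:
    data: np.ndarray   # (n1+1, n2+1) nonnegative
    mask: np.ndarray   # True = excluded from likelihood

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")
        if np.any(self.data[~self.mask] < 0):
            raise ValueError("negative spectrum entries")

    @property
    def sample_sizes(self) -> tuple[int, int]:
        return self.data.shape[0] - 1, self.data.shape[1] - 1

    @property
    def total(self) -> float:
        """Total count over unmasked entries (segregating sites retained)."""
        return float(self.data[~self.mask].sum())

    def normalized(self) -> "FoldedJSFS":
        tot = self.total
        out = np.where(self.mask, 0.0, self.data / tot)
        return FoldedJSFS(data=out, mask=self.mask.copy())


def corner_mask(n1: int, n2: int) -> np.ndarray:
    m = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    m[0, 0] = True
    m[n1, n2] = True
    return m


def fold_spectrum(unfolded: np.ndarray) -> FoldedJSFS:
    """Fold an unfolded joint spectrum (monomorphic corners masked)."""
    s = np.asarray(unfolded, dtype=float)
    n1, n2 = s.shape[0] - 1, s.shape[1] - 1
    i = np.arange(n1 + 1)[:, None]
    j = np.arange(n2 + 1)[None, :]
    tot = i + j
    half = (n1 + n2) / 2.0
    pooled = s + s[::-1, ::-1]
    folded = np.where(tot < half, pooled, np.where(tot == half, pooled / 2.0, 0.0))
    mask = (tot > half) | corner_mask(n1, n2)
    folded = np.where(mask, 0.0, folded)
    return FoldedJSFS(data=folded, mask=mask)


def to_dadi_text(fs: FoldedJSFS, path, pop_ids=("pop1", "pop2")) -> None:
    n1, n2 = fs.sample_sizes
    with open(path, "w") as fh:
        fh.write(f"{n1 + 1} {n2 + 1} folded \"{pop_ids[0]}\" \"{pop_ids[1]}\"\n")
        fh.write(" ".join(f"{v:.6g}" for v in fs.data.ravel()) + "\n")
        fh.write(" ".join("1" if m else "0" for m in fs.mask.ravel()) + "\n")


def from_dadi_text(path) -> FoldedJSFS:
    with open(path) as fh:
        header = fh.readline().split()
        d1, d2 = int(header[0]), int(header[1])
        data = np.array(fh.readline().split(), dtype=float).reshape(d1, d2)
        mask = np.array(fh.readline().split(), dtype=float).astype(bool).reshape(d1, d2)
    return FoldedJSFS(data=np.where(mask, 0.0, data), mask=mask)
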