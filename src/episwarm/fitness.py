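"""Mutual-information fitness over K-way genotype combinations.

The fitness of a candidate SNP set X against the binary phenotype Y is the
plug-in mutual information MI(X;Y) = H(X) + H(Y) - H(X,Y) computed from the
empirical joint distribution over the 3^K genotype cells and the two phenotype
classes. MI is reported in bits (log base 2), so for a binary phenotype the
fitness is bounded by H(Y) <= 1 bit. The association p-value is a
likelihood-ratio (G) test of independence between genotype cells and
phenotype — the natural test companion of an MI fitness, since G = 2n·MI in
nats.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .data_model import Dataset

__all__ = [
    "ContingencyTable",
    "FitnessValue",
    "contingency",
    "entropy",
    "mutual_information",
    "association_pvalue",
]

_LN2 = np.log(2.0)


@dataclass(frozen=True)
class ContingencyTable:
    """Joint counts of a K-SNP genotype combination and the phenotype.

    ``counts`` has shape (3^K, 2): rows are genotype tuples in lexicographic
    order (last SNP fastest), columns are phenotype 0 (control) and 1 (case).
    """

    counts: np.ndarray
    k: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", c)
        if c.shape != (3**self.k, 2):
            raise ValueError(f"expected shape ({3 ** self.k}, 2), got {c.shape}")
        if (c < 0).any():
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FitnessValue:
    """Mutual information of a SNP combination with the phenotype, in bits."""

    mi_bits: float

    def __float__(self) -> float:
        return self.mi_bits


def _check_indices(snp_indices: Sequence[int], m: int) -> np.ndarray:
    idx = np.asarray(list(snp_indices), dtype=np.int64)
    if idx.size == 0:
        raise ValueError("need at least one SNP index")
    if len(set(idx.tolist())) != idx.size:
        raise ValueError(f"duplicate SNP index in {idx.tolist()}")
    if (idx < 1).any() or (idx > m).any():
        raise ValueError(f"SNP index out of range [1, {m}]: {idx.tolist()}")
    return idx


def contingency(dataset: Dataset, snp_indices: Sequence[int]) -> ContingencyTable:
    """Tally the (genotype tuple, phenotype) joint counts for a SNP set.

    ``snp_indices`` are 1-based. Cell (g1,...,gK, y) holds the number of
    individuals carrying that joint genotype with phenotype y; genotype rows
    are ordered lexicographically by the tuple.
    """
    idx = _check_indices(snp_indices, dataset.n_snps)
    k = idx.size
    # Mixed-radix cell code: genotype tuple in base 3, phenotype last bit.
    cell = np.zeros(dataset.n_individuals, dtype=np.int64)
    for i in idx:
        cell = cell * 3 + dataset.genotypes[:, i - 1]
    code = cell * 2 + dataset.phenotype
    counts = np.bincount(code, minlength=2 * 3**k).reshape(3**k, 2)
    return ContingencyTable(counts, k)


def entropy(counts) -> float:
    """Plug-in Shannon entropy (bits) of an empirical count vector.

    Zero cells contribute nothing (0·log 0 := 0). Raises on an all-zero
    vector, for which the empirical distribution is undefined.
    """
    c = np.asarray(counts, dtype=np.float64).ravel()
    n = c.sum()
    if n <= 0:
        raise ValueError("entropy of an all-zero count vector is undefined")
    p = c[c > 0] / n
    return float(-(p * np.log2(p)).sum())


def _mi_bits(table: ContingencyTable) -> float:
    joint = table.counts
    h_x = entropy(joint.sum(axis=1))
    h_y = entropy(joint.sum(axis=0))
    h_xy = entropy(joint)
    # Clip the tiny negative round-off the three-term form can produce.
    return max(h_x + h_y - h_xy, 0.0)


def mutual_information(dataset: Dataset, snp_indices: Sequence[int]) -> FitnessValue:
    """MI(X;Y) in bits between a K-SNP genotype combination and the phenotype.

    Invariant to the order of ``snp_indices`` — the indices are canonically
    sorted before tallying, so the invariance is exact, not just up to
    round-off. Always >= 0 and <= H(Y) (<= 1 bit for a binary phenotype).
    """
    idx = sorted(int(i) for i in snp_indices)
    if len(set(idx)) != len(idx):
        raise ValueError(f"duplicate SNP index in {list(snp_indices)}")
    return FitnessValue(_mi_bits(contingency(dataset, idx)))


def association_pvalue(table: ContingencyTable) -> float:
    """G-test p-value of independence between genotype cells and phenotype.

    G = 2n·MI (in nats); df = (number of genotype rows with a nonzero
    margin - 1) x (2 - 1). A degenerate table whose individuals all share one
    genotype cell, or a one-class phenotype, carries no evidence: p = 1.
    """
    n = table.n
    if n <= 0:
        raise ValueError("empty contingency table")
    nonzero_rows = int((table.counts.sum(axis=1) > 0).sum())
    nonzero_cols = int((table.counts.sum(axis=0) > 0).sum())
    df = (nonzero_rows - 1) * (nonzero_cols - 1)
    if df <= 0:
        return 1.0
    g = 2.0 * n * _mi_bits(table) * _LN2
    return float(chi2.sf(g, df))
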