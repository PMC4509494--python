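"""Case-control genotype datasets and ground-truth annotations.

A dataset is an individuals x SNPs matrix of additive genotype codes
{0,1,2} (homozygous common / heterozygous / homozygous minor) together with a
binary phenotype (0=control, 1=case). The native on-disk format is a
tab-separated table with one header row of SNP identifiers plus a final
``phenotype`` column, one row per individual; PLINK ``.raw`` additive-coded
exports are readable as well. SNP indices are 1-based in every user-facing
report, matching the search domain {1, ..., M} of the optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Dataset", "TruthSet", "load_dataset", "write_dataset"]

PHENOTYPE_COLUMN = "phenotype"

# Non-genotype leading columns of a PLINK .raw export.
_PLINK_META = ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")


class DatasetError(ValueError):
    """Raised when a genotype file or matrix violates the data contract."""


@dataclass(frozen=True)
class Dataset:
    """Validated case-control genotype matrix.

    Parameters
    ----------
    genotypes
        ``(n_individuals, M)`` integer array with values in {0, 1, 2}.
    phenotype
        Length ``n_individuals`` integer vector, 0=control / 1=case.
    snp_ids
        ``M`` unique SNP identifiers, column order matching ``genotypes``.
    """

    genotypes: np.ndarray
    phenotype: np.ndarray
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        g = np.ascontiguousarray(np.asarray(self.genotypes, dtype=np.int8))
        y = np.ascontiguousarray(np.asarray(self.phenotype, dtype=np.int8))
        object.__setattr__(self, "genotypes", g)
        object.__setattr__(self, "phenotype", y)
        object.__setattr__(self, "snp_ids", tuple(str(s) for s in self.snp_ids))
        if g.ndim != 2:
            raise DatasetError("genotypes must be a 2-D individuals x SNPs matrix")
        n, m = g.shape
        if m < 2:
            raise DatasetError(f"need at least 2 SNPs, got M={m}")
        if y.shape != (n,):
            raise DatasetError(
                f"phenotype length {y.shape} does not match {n} individuals"
            )
        bad = np.argwhere((g < 0) | (g > 2))
        if bad.size:
            r, c = bad[0]
            raise DatasetError(
                f"genotype value {int(g[r, c])} at individual {r + 1}, "
                f"SNP {self.snp_ids[c]!r} (column {c + 1}) is not in {{0,1,2}}"
            )
        bad_y = np.argwhere((y != 0) & (y != 1))
        if bad_y.size:
            r = int(bad_y[0][0])
            raise DatasetError(f"phenotype value {int(y[r])} at row {r + 1} is not 0/1")
        if len(self.snp_ids) != m:
            raise DatasetError(
                f"{len(self.snp_ids)} SNP ids for {m} genotype columns"
            )
        if len(set(self.snp_ids)) != m:
            seen: set[str] = set()
            dup = next(s for s in self.snp_ids if s in seen or seen.add(s))
            raise DatasetError(f"duplicate SNP id {dup!r}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int(np.sum(self.phenotype == 1))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.phenotype == 0))

    def snp_index(self, snp_id: str) -> int:
        """1-based column index of a SNP id."""
        try:
            return self.snp_ids.index(snp_id) + 1
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def ids_at(self, indices) -> tuple[str, ...]:
        """SNP ids at the given 1-based indices."""
        return tuple(self.snp_ids[i - 1] for i in indices)


@dataclass(frozen=True)
class TruthSet:
    """Ground-truth causal SNPs planted by a simulator (1-based indices)."""

    causal_indices: frozenset[int]
    model_name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "causal_indices", frozenset(int(i) for i in self.causal_indices)
        )
        if not self.causal_indices:
            raise ValueError("truth set must contain at least one causal SNP")
        if min(self.causal_indices) < 1:
            raise ValueError("causal indices are 1-based and must be >= 1")

    def validate_against(self, dataset: Dataset) -> None:
        if max(self.causal_indices) > dataset.n_snps:
            raise ValueError(
                f"causal index {max(self.causal_indices)} exceeds M={dataset.n_snps}"
            )


def _truth_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".truth")


def load_dataset(path, format: str = "tabular") -> Dataset:
    """Load a case-control genotype file.

    Parameters
    ----------
    path
        File to read.
    format
        ``"tabular"`` for the native TSV layout (SNP-id header plus a final
        ``phenotype`` column) or ``"plink_raw"`` for a PLINK ``.raw``
        additive-coded export (phenotype 1/2 recoded to 0/1).
    """
    path = Path(path)
    if format == "tabular":
        return _load_tabular(path)
    if format == "plink_raw":
        return _load_plink_raw(path)
    raise ValueError(f"unknown format {format!r}; expected 'tabular' or 'plink_raw'")


def _load_tabular(path: Path) -> Dataset:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if PHENOTYPE_COLUMN not in df.columns:
        raise DatasetError(f"{path}: missing required column {PHENOTYPE_COLUMN!r}")
    snp_cols = [c for c in df.columns if c != PHENOTYPE_COLUMN]
    return _from_frame(df, snp_cols, df[PHENOTYPE_COLUMN], origin=str(path))


def _load_plink_raw(path: Path) -> Dataset:
    df = pd.read_csv(path, sep=r"\s+", dtype=str)
    missing = [c for c in _PLINK_META if c not in df.columns]
    if missing:
        raise DatasetError(f"{path}: not a PLINK .raw file (missing {missing})")
    snp_cols = [c for c in df.columns if c not in _PLINK_META]
    pheno = pd.to_numeric(df["PHENOTYPE"], errors="coerce")
    values = set(pheno.dropna().unique())
    if values <= {1, 2}:  # PLINK case/control coding: 1=control, 2=case
        pheno = pheno - 1
    elif not values <= {0, 1}:
        raise DatasetError(
            f"{path}: PHENOTYPE values {sorted(values)} are not 0/1 or 1/2 coded"
        )
    # Column names carry the counted allele as a suffix, e.g. rs123_A.
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    return _from_frame(df, snp_cols, pheno, origin=str(path), snp_ids=snp_ids)


def _from_frame(df, snp_cols, pheno, origin, snp_ids=None) -> Dataset:
    if not snp_cols:
        raise DatasetError(f"{origin}: no genotype columns found")
    geno = np.empty((len(df), len(snp_cols)), dtype=np.int8)
    for j, col in enumerate(snp_cols):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | ~vals.isin([0, 1, 2])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise DatasetError(
                f"{origin}: genotype {df[col].iloc[row]!r} at data row {row + 1}, "
                f"column {col!r} is not 0/1/2"
            )
        geno[:, j] = vals.to_numpy()
    pheno_num = pd.to_numeric(pheno, errors="coerce")
    if pheno_num.isna().any():
        row = int(np.argmax(pheno_num.isna().to_numpy()))
        raise DatasetError(f"{origin}: unparseable phenotype at data row {row + 1}")
    try:
        return Dataset(geno, pheno_num.to_numpy(), snp_ids or snp_cols)
    except DatasetError as exc:
        raise DatasetError(f"{origin}: {exc}") from None


def load_truth(path, dataset: Dataset, model_name: str = "") -> TruthSet:
    """Read a truth sidecar (one SNP id per line) against a dataset."""
    ids = [line.strip() for line in Path(path).read_text().splitlines() if line.strip()]
    return TruthSet(frozenset(dataset.snp_index(s) for s in ids), model_name)


def write_dataset(dataset: Dataset, path, truth: TruthSet | None = None) -> None:
    """Write the native tabular layout; add a ``.truth`` sidecar when given.

    ``load_dataset(path)`` reproduces the dataset exactly (genotypes,
    phenotype, SNP ids). The sidecar lists the ground-truth SNP ids, one per
    line, in ascending index order.
    """
    path = Path(path)
    df = pd.DataFrame(dataset.genotypes, columns=list(dataset.snp_ids))
    df[PHENOTYPE_COLUMN] = dataset.phenotype
    df.to_csv(path, sep="\t", index=False)
    if truth is not None:
        truth.validate_against(dataset)
        ids = dataset.ids_at(sorted(truth.causal_indices))
        _truth_path(path).write_text("".join(s + "\n" for s in ids))
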