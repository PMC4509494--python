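"""Shared fixtures: handcrafted datasets, random-dataset factory, oracles."""

from __future__ import annotations

import math
from collections import Counter
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from episwarm import Dataset, PenetranceModel

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    # stateless factory fixtures are safe to reuse across examples
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")

FIXTURE_DIR = Path(__file__).parent / "fixtures"


def mi_oracle_bits(genotypes, phenotype, snp_indices) -> float:
    """Independent plug-in MI: direct double sum over all (x, y) cells.

    Brute-force tally with a Counter, then
    sum_xy p(x,y) * log2(p(x,y) / (p(x) p(y))). Shares no code with the
    package's entropy-difference implementation.
    """
    rows = [tuple(genotypes[i, j - 1] for j in snp_indices) for i in range(len(phenotype))]
    joint = Counter(zip(rows, (int(y) for y in phenotype)))
    px = Counter(rows)
    py = Counter(int(y) for y in phenotype)
    n = len(rows)
    total = 0.0
    for (x, y), c in joint.items():
        pxy = c / n
        total += pxy * math.log2(pxy / ((px[x] / n) * (py[y] / n)))
    return total


@pytest.fixture
def tiny_dataset() -> Dataset:
    """4 individuals x 3 SNPs, hand-checkable."""
    geno = np.array(
        [
            [0, 1, 2],
            [1, 0, 2],
            [2, 2, 0],
            [0, 1, 1],
        ]
    )
    return Dataset(geno, np.array([0, 0, 1, 1]), ("rs1", "rs2", "rs3"))


@pytest.fixture
def random_dataset():
    """Factory for null datasets (every SNP independent of phenotype)."""

    def make(n=60, m=10, seed=0, maf_range=(0.1, 0.5)) -> Dataset:
        rng = np.random.default_rng(seed)
        mafs = rng.uniform(*maf_range, size=m)
        probs = np.stack([(1 - mafs) ** 2, 2 * mafs * (1 - mafs), mafs**2], axis=1)
        geno = np.empty((n, m), dtype=np.int8)
        for j in range(m):
            geno[:, j] = rng.choice(3, size=n, p=probs[j])
        pheno = rng.integers(0, 2, size=n)
        return Dataset(geno, pheno, tuple(f"SNP{j + 1}" for j in range(m)))

    return make


@pytest.fixture(scope="session")
def strong_model() -> PenetranceModel:
    """Committed calibrated both-minor-threshold model (synthetic fixture)."""
    return PenetranceModel.from_json(FIXTURE_DIR / "strong_effect_model.json")
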