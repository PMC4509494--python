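"""Penetrance-model case-control simulator with planted SNP interactions.

A disease model is a table of penetrances f(g) — the probability of disease
given the joint genotype g of the K causal SNPs — together with their minor
allele frequencies and the population prevalence. Genotype frequencies follow
Hardy-Weinberg equilibrium (HWE) and the causal loci are in linkage
equilibrium, so P(g) is a product of per-SNP HWE probabilities.

Sampling is retrospective (case-control): causal genotype tuples are drawn
from P(g | case) ∝ f(g)·P(g) for cases and P(g | control) ∝ (1-f(g))·P(g)
for controls, which matches a fixed cases/controls design. The remaining
"null" SNPs are drawn i.i.d. under HWE with per-SNP MAF ~ Uniform[0.05, 0.5],
identically in both classes. Default study dimensions are 2000 cases, 2000
controls and 100 SNPs per dataset.

Archetype shapes cover the classic two-locus benchmark models: a
both-minor-allele threshold model and an inverse-marginal model (both with
marginal effects), and heterozygosity-parity models (xor and its complement
zz) whose single-SNP marginal penetrances are exactly constant at MAF 0.5 —
pure interactions with no main effect. Models published only as numeric 3x3
tables are supported via user-supplied tables.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_model import Dataset, TruthSet

__all__ = [
    "PenetranceModel",
    "hwe_genotype_probs",
    "calibrate",
    "model_shape",
    "simulate",
    "ARCHETYPES",
]

MAF_RANGE = (0.05, 0.5)  # null-SNP minor allele frequencies
DEFAULT_N_CASES = 2000
DEFAULT_N_CONTROLS = 2000
DEFAULT_N_SNPS = 100

ARCHETYPES = (
    "threshold_both_minor",
    "inverse_marginal",
    "ref39_m3",
    "ref39_m4",
    "zz",
    "xor",
)


def hwe_genotype_probs(maf: float) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities ((1-q)^2, 2q(1-q), q^2)."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"MAF must be in [0, 0.5], got {maf}")
    q = float(maf)
    return np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])


@dataclass(frozen=True)
class PenetranceModel:
    """Calibrated disease model for K causal SNPs.

    ``table`` has shape (3,)*K, entry f(g1,...,gK) in [0,1]; ``mafs`` are the
    causal minor allele frequencies; ``prevalence`` is the population disease
    probability sum_g f(g)·P_HWE(g) implied by the table.
    """

    table: np.ndarray
    mafs: tuple[float, ...]
    prevalence: float
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.table, dtype=np.float64)
        object.__setattr__(self, "table", t)
        object.__setattr__(self, "mafs", tuple(float(q) for q in self.mafs))
        k = len(self.mafs)
        if t.shape != (3,) * k:
            raise ValueError(f"table shape {t.shape} does not match K={k} SNPs")
        if (t < 0).any() or (t > 1).any():
            raise ValueError("penetrances must lie in [0, 1]")
        for q in self.mafs:
            if not 0.0 < q <= 0.5:
                raise ValueError(f"causal MAF must be in (0, 0.5], got {q}")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        if abs(self.genotype_probs() @ t.ravel() - self.prevalence) > 1e-9:
            raise ValueError("table, MAFs and prevalence are inconsistent")

    @property
    def k(self) -> int:
        return len(self.mafs)

    def genotype_probs(self) -> np.ndarray:
        """P_HWE(g) over the 3^K genotype tuples, lexicographic order."""
        p = hwe_genotype_probs(self.mafs[0])
        for q in self.mafs[1:]:
            p = np.multiply.outer(p, hwe_genotype_probs(q))
        return p.ravel()

    def class_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """(P(g|case), P(g|control)) over genotype tuples.

        P(g|case) = f(g)·P(g)/prevalence and
        P(g|control) = (1-f(g))·P(g)/(1-prevalence); their prevalence-weighted
        mixture recovers P_HWE(g) exactly.
        """
        p = self.genotype_probs()
        f = self.table.ravel()
        return f * p / self.prevalence, (1 - f) * p / (1 - self.prevalence)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "table": self.table.tolist(),
            "mafs": list(self.mafs),
            "prevalence": self.prevalence,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenetranceModel":
        return cls(
            np.asarray(d["table"]), tuple(d["mafs"]), float(d["prevalence"]),
            d.get("name", ""),
        )

    @classmethod
    def from_json(cls, path) -> "PenetranceModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def calibrate(shape, mafs, prevalence: float, name: str = "") -> PenetranceModel:
    """Scale a non-negative shape table to hit a target prevalence.

    The penetrance table is c·shape with c solving
    sum_g c·shape(g)·P_HWE(g) = prevalence; shape ratios are preserved. Fails
    if the required scaling would push any penetrance above 1.
    """
    shape = np.asarray(shape, dtype=np.float64)
    if (shape < 0).any():
        raise ValueError("shape entries must be non-negative")
    mafs = tuple(float(q) for q in mafs)
    p = hwe_genotype_probs(mafs[0])
    for q in mafs[1:]:
        p = np.multiply.outer(p, hwe_genotype_probs(q))
    mean_shape = float(p.ravel() @ shape.ravel())
    if mean_shape <= 0:
        raise ValueError("shape has zero mass under HWE; cannot calibrate")
    c = prevalence / mean_shape
    table = c * shape
    if (table > 1 + 1e-12).any():
        raise ValueError(
            f"prevalence {prevalence} infeasible: max penetrance would be "
            f"{table.max():.4g} > 1"
        )
    return PenetranceModel(np.clip(table, 0, 1), mafs, prevalence, name)


def model_shape(name: str, params: dict | None = None) -> np.ndarray:
    """Qualitative 3x3 penetrance shape of a named two-locus archetype.

    Parameters ``alpha`` (baseline) and ``theta`` (effect size) default to
    0.0 and 1.0. Archetypes:

    - ``threshold_both_minor``: risk raised iff both SNPs carry at least one
      minor allele (marginal + interactive effects).
    - ``inverse_marginal``: SNP1's minor allele raises risk, but the effect
      flips to a reduction when SNP2 also carries a minor allele (requires
      alpha >= theta so penetrances stay non-negative).
    - ``xor``: risk raised iff exactly one SNP is heterozygous (genotype sum
      odd) — zero marginal effect at MAF 0.5.
    - ``zz``: risk raised iff both SNPs agree in heterozygosity — the
      complementary zero-marginal pattern at MAF 0.5.
    - ``ref39_m3`` / ``ref39_m4``: published numeric tables, supplied by the
      caller as ``params["table"]``.
    """
    params = dict(params or {})
    alpha = float(params.get("alpha", 0.0))
    theta = float(params.get("theta", 1.0))
    g = np.arange(3)
    g1 = g[:, None]
    g2 = g[None, :]
    if name == "threshold_both_minor":
        return alpha + theta * ((g1 >= 1) & (g2 >= 1))
    if name == "inverse_marginal":
        if alpha < theta:
            raise ValueError("inverse_marginal needs alpha >= theta (non-negative shape)")
        shape = alpha + theta * ((g1 >= 1) & (g2 == 0)) - theta * ((g1 >= 1) & (g2 >= 1))
        return shape.astype(np.float64)
    if name == "xor":
        return alpha + theta * ((g1 + g2) % 2 == 1)
    if name == "zz":
        return alpha + theta * ((g1 + g2) % 2 == 0)
    if name in ("ref39_m3", "ref39_m4"):
        if "table" not in params:
            raise ValueError(f"{name} requires an explicit 3x3 params['table']")
        table = np.asarray(params["table"], dtype=np.float64)
        if table.shape != (3, 3):
            raise ValueError("user table must be 3x3")
        return table
    raise ValueError(f"unknown model archetype {name!r}; choose from {ARCHETYPES}")


def simulate(
    model: PenetranceModel,
    n_cases: int = DEFAULT_N_CASES,
    n_controls: int = DEFAULT_N_CONTROLS,
    n_snps: int = DEFAULT_N_SNPS,
    seed: int | np.random.Generator | None = None,
) -> tuple[Dataset, TruthSet]:
    """Generate one case-control dataset with the model's SNPs planted.

    The K causal columns, placed at random distinct positions (recorded in
    the returned truth set), carry genotype tuples drawn from P(g|case) /
    P(g|control); all other columns are i.i.d. HWE noise with per-SNP MAF
    drawn uniformly from [0.05, 0.5], identically distributed in both
    classes. Rows are cases first, then controls.
    """
    k = model.k
    if n_snps <= k:
        raise ValueError(f"need n_snps > K={k}, got {n_snps}")
    if n_cases < 1 or n_controls < 1:
        raise ValueError("need at least one case and one control")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_cases + n_controls

    p_case, p_control = model.class_probs()
    tuples = np.array(list(itertools.product(range(3), repeat=k)), dtype=np.int8)
    case_cells = rng.choice(3**k, size=n_cases, p=p_case)
    control_cells = rng.choice(3**k, size=n_controls, p=p_control)
    causal = np.vstack([tuples[case_cells], tuples[control_cells]])

    geno = np.empty((n, n_snps), dtype=np.int8)
    causal_cols = np.sort(rng.choice(n_snps, size=k, replace=False))
    null_cols = np.setdiff1d(np.arange(n_snps), causal_cols)
    mafs = rng.uniform(*MAF_RANGE, size=null_cols.size)
    for j, (col, q) in enumerate(zip(null_cols, mafs)):
        geno[:, col] = rng.choice(3, size=n, p=hwe_genotype_probs(q))
    geno[:, causal_cols] = causal

    phenotype = np.concatenate(
        [np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)]
    )
    snp_ids = tuple(f"SNP{i + 1}" for i in range(n_snps))
    dataset = Dataset(geno, phenotype, snp_ids)
    truth = TruthSet(frozenset(int(c) + 1 for c in causal_cols), model.name)
    return dataset, truth
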