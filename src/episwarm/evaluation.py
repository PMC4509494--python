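"""Detection-power scoring and the batch benchmarking harness.

Two powers are reported over a batch of N simulated datasets with known
planted interactions:

- Power 1: the fraction of datasets in which the reported SNP set equals the
  ground truth exactly — all causal SNPs found, no false positives.
- Power 2: the average fraction of causal SNPs present in the reported
  K-SNP set, sum(y_i) / (K·N) with y_i the per-dataset hit count. A fully
  correct answer contributes K hits, so Power 2 >= Power 1 always.

"Reported SNP set" means the method's final answer (for the
opposition-based variant, the post-processed global best).

The experiment harness simulates N datasets per disease model and runs each
configured method/particle/iteration combination on the *same* datasets, so
method comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, TruthSet
from .simulator import PenetranceModel, simulate
from .swarm import DetectionResult, SwarmConfig, run

__all__ = ["PowerReport", "power1", "power2", "run_experiment", "reports_to_frame"]


def _tags_and_counts(
    results: Sequence[DetectionResult], truths: Sequence[TruthSet]
) -> tuple[list[int], list[int], int]:
    if len(results) != len(truths):
        raise ValueError(
            f"{len(results)} results vs {len(truths)} truth sets"
        )
    if not results:
        raise ValueError("need at least one dataset")
    k = len(results[0].snp_indices)
    tags, counts = [], []
    for res, truth in zip(results, truths):
        found = set(res.snp_indices)
        if len(found) != k:
            raise ValueError("all results must report the same interaction order K")
        hits = len(found & truth.causal_indices)
        counts.append(hits)
        tags.append(int(found == truth.causal_indices))
    return tags, counts, k


def power1(results: Sequence[DetectionResult], truths: Sequence[TruthSet]) -> float:
    """Fraction of datasets whose answer matches the truth exactly."""
    tags, _, _ = _tags_and_counts(results, truths)
    return sum(tags) / len(tags)


def power2(results: Sequence[DetectionResult], truths: Sequence[TruthSet]) -> float:
    """Average fraction of ground-truth SNPs in the reported K-SNP set."""
    _, counts, k = _tags_and_counts(results, truths)
    return sum(counts) / (k * len(counts))


@dataclass(frozen=True)
class PowerReport:
    """Power 1 / Power 2 of one method configuration on one model's batch."""

    model: str
    variant: str
    p: int
    t: int
    power1: float
    power2: float
    tags: tuple[int, ...]
    counts: tuple[int, ...]
    k: int

    @property
    def n_datasets(self) -> int:
        return len(self.tags)

    @classmethod
    def from_results(
        cls,
        results: Sequence[DetectionResult],
        truths: Sequence[TruthSet],
        model: str,
        variant: str,
        p: int,
        t: int,
    ) -> "PowerReport":
        tags, counts, k = _tags_and_counts(results, truths)
        return cls(
            model=model,
            variant=variant,
            p=p,
            t=t,
            power1=sum(tags) / len(tags),
            power2=sum(counts) / (k * len(counts)),
            tags=tuple(tags),
            counts=tuple(counts),
            k=k,
        )


def _as_model(entry) -> PenetranceModel:
    if isinstance(entry, PenetranceModel):
        return entry
    return PenetranceModel.from_dict(entry)


def run_experiment(spec: dict) -> list[PowerReport]:
    """Run a full power study from an experiment specification.

    ``spec`` keys (defaults in parentheses):

    - ``models``: list of penetrance models (objects or dicts with
      name/table/mafs/prevalence) — required.
    - ``n_datasets`` (50), ``n_cases`` (2000), ``n_controls`` (2000),
      ``n_snps`` (100): batch dimensions per model.
    - ``variants`` (["ioblpso", "pso"]): methods to compare.
    - ``grid`` ([[100, 100]]): (P, T) particle/iteration settings.
    - ``swarm`` ({}): extra SwarmConfig fields (k, c1, c2, top_n, ...).
    - ``seed``: master seed; datasets are drawn once per model and shared by
      every method/grid cell, each optimizer run on its own child stream.

    Returns one PowerReport per (model, variant, P, T) cell.
    """
    models = [_as_model(m) for m in spec["models"]]
    n_datasets = int(spec.get("n_datasets", 50))
    n_cases = int(spec.get("n_cases", 2000))
    n_controls = int(spec.get("n_controls", 2000))
    n_snps = int(spec.get("n_snps", 100))
    variants = list(spec.get("variants", ["ioblpso", "pso"]))
    grid = [tuple(int(v) for v in cell) for cell in spec.get("grid", [[100, 100]])]
    swarm_kwargs = dict(spec.get("swarm", {}))
    master = np.random.SeedSequence(spec.get("seed"))

    reports = []
    for model, model_ss in zip(models, master.spawn(len(models))):
        data_ss, run_ss = model_ss.spawn(2)
        batch = [
            simulate(model, n_cases, n_controls, n_snps, np.random.default_rng(s))
            for s in data_ss.spawn(n_datasets)
        ]
        datasets = [d for d, _ in batch]
        truths = [t for _, t in batch]
        cells = [(v, p, t) for v in variants for p, t in grid]
        for (variant, p, t), cell_ss in zip(cells, run_ss.spawn(len(cells))):
            config = SwarmConfig(p=p, t=t, variant=variant, **swarm_kwargs)
            results = [
                run(ds, config, np.random.default_rng(s))
                for ds, s in zip(datasets, cell_ss.spawn(n_datasets))
            ]
            reports.append(
                PowerReport.from_results(results, truths, model.name, variant, p, t)
            )
    return reports


def reports_to_frame(reports: Sequence[PowerReport]) -> pd.DataFrame:
    """Tabular power summary, one row per (model, variant, P, T)."""
    return pd.DataFrame(
        [
            {
                "model": r.model,
                "variant": r.variant,
                "p": r.p,
                "t": r.t,
                "n_datasets": r.n_datasets,
                "power1": r.power1,
                "power2": r.power2,
            }
            for r in reports
        ]
    )
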