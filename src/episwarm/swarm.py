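"""Discrete particle-swarm search for K-way SNP-SNP interactions.

Two variants share one loop:

``ioblpso``
    Opposition-based-learning PSO. Each particle is a K-tuple of SNP indices
    in {1, ..., M}; every iteration it also evaluates its *opposite* position
    (1 + M - index per dimension), its per-dimension inertia weight is driven
    by how often the pbest SNP has appeared across all personal bests
    (rarely-seen SNPs get high inertia and keep exploring, suspected SNPs get
    low inertia and exploit), and after the last iteration an exhaustive
    post-procedure re-scans all K-subsets of the most frequently selected
    SNPs.

``pso``
    The plain baseline at matched settings: fixed inertia weight, personal
    best compares only the current position against the previous one, no
    opposition step and no post-procedure.

Fitness is the plug-in mutual information of the genotype combination with
the binary phenotype (see :mod:`episwarm.fitness`).

A single seeded NumPy generator drives every random draw of a run, in a fixed
call order: initial positions then velocities particle by particle, then per
iteration and particle and dimension the two acceleration draws r1, r2, a
velocity-range resample when triggered, a position-range resample when
triggered, and finally duplicate-index resolution draws. Runs are therefore
bit-reproducible from the seed alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset
from .fitness import FitnessValue, association_pvalue, contingency, mutual_information

__all__ = [
    "SwarmConfig",
    "Particle",
    "SwarmState",
    "DetectionResult",
    "initialize",
    "dynamic_inertia",
    "update_velocity",
    "update_position",
    "opposite_position",
    "update_pbest",
    "update_gbest",
    "postprocess",
    "run",
    "multi_run",
]

VARIANTS = ("ioblpso", "pso")


@dataclass(frozen=True)
class SwarmConfig:
    """Optimizer settings.

    Defaults follow the standard benchmarking setup for this search problem:
    P = T = 100, acceleration factors C1 = C2 = 2, static inertia weight
    0.65 (used throughout by the plain-PSO baseline and as the fallback when
    the dynamic weight is degenerate), pairwise interactions (K = 2), and a
    post-procedure candidate set of the 10 most frequently selected SNPs.
    """

    p: int = 100
    t: int = 100
    k: int = 2
    c1: float = 2.0
    c2: float = 2.0
    static_inertia: float = 0.65
    top_n: int = 10
    seed: int | None = None
    variant: str = "ioblpso"

    def __post_init__(self) -> None:
        if self.p < 1 or self.t < 1:
            raise ValueError("particle count P and iteration count T must be >= 1")
        if self.k < 1:
            raise ValueError("interaction order K must be >= 1")
        if self.top_n < self.k:
            raise ValueError("top_n must be at least K")
        if self.c1 < 0 or self.c2 < 0:
            raise ValueError("acceleration factors must be non-negative")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")

    @classmethod
    def from_dict(cls, d: dict) -> "SwarmConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class Particle:
    """One candidate solution: a K-subset of SNP indices plus its velocity."""

    position: np.ndarray  # (K,) distinct ints in [1, M]
    velocity: np.ndarray  # (K,) floats in [1-M, M-1]
    pbest: np.ndarray  # (K,) distinct ints in [1, M]
    pbest_fitness: float


@dataclass
class SwarmState:
    """Full optimizer state after ``iteration`` counter increments.

    ``count[m-1]`` accumulates, over all counter increments so far
    (initialization counts as the first), how many times SNP m appeared in
    any particle's personal best; it drives both the dynamic inertia weight
    and the post-procedure candidate ranking.
    """

    particles: list[Particle]
    gbest: np.ndarray
    gbest_fitness: float
    count: np.ndarray  # (M,) int64
    iteration: int
    m: int


@dataclass(frozen=True)
class DetectionResult:
    """One run's answer: the reported SNP set and its evidence."""

    snp_indices: tuple[int, ...]  # sorted, 1-based
    snp_ids: tuple[str, ...]
    mi_interaction: FitnessValue
    mi_individual: tuple[FitnessValue, ...]
    pvalue: float
    counters: np.ndarray
    trace: tuple[float, ...]  # gbest fitness after each counter increment
    variant: str

    def summary(self) -> str:
        lines = [
            f"variant        : {self.variant}",
            f"SNP set        : {', '.join(self.snp_ids)} "
            f"(indices {', '.join(str(i) for i in self.snp_indices)})",
            f"MI interaction : {self.mi_interaction.mi_bits:.4f} bits",
        ]
        for sid, fv in zip(self.snp_ids, self.mi_individual):
            lines.append(f"MI {sid:<12}: {fv.mi_bits:.4f} bits")
        lines.append(f"G-test p-value : {self.pvalue:.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "snp_indices": list(self.snp_indices),
            "snp_ids": list(self.snp_ids),
            "mi_interaction": self.mi_interaction.mi_bits,
            "mi_individual": [f.mi_bits for f in self.mi_individual],
            "pvalue": self.pvalue,
            "counters": self.counters.tolist(),
            "trace": list(self.trace),
        }


class _Evaluator:
    """Memoized MI fitness over index subsets of one dataset."""

    def __init__(self, dataset: Dataset):
        self.dataset = dataset
        self._cache: dict[tuple[int, ...], float] = {}

    def __call__(self, indices: Sequence[int]) -> float:
        key = tuple(sorted(int(i) for i in indices))
        val = self._cache.get(key)
        if val is None:
            val = mutual_information(self.dataset, key).mi_bits
            self._cache[key] = val
        return val


def _random_position(m: int, k: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(m, size=k, replace=False).astype(np.int64) + 1


def initialize(
    dataset: Dataset, config: SwarmConfig, rng: np.random.Generator | None = None
) -> SwarmState:
    """Draw the initial swarm uniformly over its domains.

    Positions are uniform K-subsets of {1, ..., M}; velocities are uniform in
    [1-M, M-1]; each personal best starts at the initial position with its
    evaluated fitness; the global best is the best personal best; the counter
    vector tallies the initial personal bests (iteration 1).
    """
    m = dataset.n_snps
    if config.k >= m:
        raise ValueError(f"interaction order K={config.k} must be < M={m}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    evaluate = _Evaluator(dataset)
    particles = []
    for _ in range(config.p):
        pos = _random_position(m, config.k, rng)
        vel = rng.uniform(1 - m, m - 1, size=config.k)
        particles.append(Particle(pos, vel, pos.copy(), evaluate(pos)))
    best = max(range(config.p), key=lambda i: particles[i].pbest_fitness)
    count = np.zeros(m, dtype=np.int64)
    for part in particles:
        np.add.at(count, part.pbest - 1, 1)
    return SwarmState(
        particles=particles,
        gbest=particles[best].pbest.copy(),
        gbest_fitness=particles[best].pbest_fitness,
        count=count,
        iteration=1,
        m=m,
    )


def dynamic_inertia(count: np.ndarray, pbest_snp: int, static_inertia: float = 0.65) -> float:
    """Counter-driven inertia weight for one pbest SNP (1-based index).

    W = (max(count) - count[snp]) / (max(count) - min(count)): 1 for the
    least-seen SNP (keep exploring), 0 for the most-seen one (exploit). When
    all counters are equal the ratio is undefined and the static weight is
    used instead.
    """
    count = np.asarray(count)
    if not 1 <= pbest_snp <= count.size:
        raise IndexError(f"SNP index {pbest_snp} out of range [1, {count.size}]")
    hi = int(count.max())
    lo = int(count.min())
    if hi == lo:
        return float(static_inertia)
    return float((hi - count[pbest_snp - 1]) / (hi - lo))


def update_velocity(
    particle: Particle,
    weights: Sequence[float],
    gbest: np.ndarray,
    m: int,
    c1: float,
    c2: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """New velocity vector, one inertia weight per dimension.

    Per dimension k: v' = W_k v_k + C1 r1 (pbest_k - pos_k)
    + C2 r2 (gbest_k - pos_k) with fresh r1, r2 ~ U(0,1); any component
    leaving [1-M, M-1] is replaced by a uniform draw from that interval.
    """
    k = particle.position.size
    lo, hi = 1 - m, m - 1
    out = np.empty(k, dtype=np.float64)
    for d in range(k):
        r1 = rng.random()
        r2 = rng.random()
        v = (
            weights[d] * particle.velocity[d]
            + c1 * r1 * (particle.pbest[d] - particle.position[d])
            + c2 * r2 * (gbest[d] - particle.position[d])
        )
        if not lo <= v <= hi:
            v = rng.uniform(lo, hi)
        out[d] = v
    return out


def update_position(
    particle: Particle, new_velocity: np.ndarray, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Move the particle and repair out-of-range and duplicate indices.

    Per dimension: s = pos_k + v_k, truncated to int if s lands in [1, M],
    otherwise a uniform random integer in [1, M]. A SNP combination is a set,
    so any dimension duplicating an earlier one is then resampled uniformly
    from the indices not already present.
    """
    k = particle.position.size
    out = np.empty(k, dtype=np.int64)
    for d in range(k):
        s = particle.position[d] + new_velocity[d]
        if 1 <= s <= m:
            out[d] = int(s)
        else:
            out[d] = rng.integers(1, m + 1)
    seen: set[int] = set()
    for d in range(k):
        if out[d] in seen:
            free = np.array(sorted(set(range(1, m + 1)) - seen - set(out[d + 1 :].tolist())))
            out[d] = int(rng.choice(free))
        seen.add(int(out[d]))
    return out


def opposite_position(position: np.ndarray, m: int) -> np.ndarray:
    """Opposition-based-learning mirror: 1 + M - index, per dimension.

    A bijection on {1, ..., M}, hence an involution that preserves
    distinctness; for odd M the midpoint (M+1)/2 is its fixed point.
    """
    return (1 + m - np.asarray(position, dtype=np.int64)).astype(np.int64)


def update_pbest(
    particle: Particle,
    dataset: Dataset,
    variant: str = "ioblpso",
    evaluate: Callable[[Sequence[int]], float] | None = None,
) -> Particle:
    """Refresh a particle's personal best (in place; also returned).

    ``ioblpso`` compares the current position, its opposite, and the previous
    personal best; ``pso`` omits the opposite. Exact ties keep the previous
    personal best, then prefer the position over its opposite.
    """
    if evaluate is None:
        evaluate = _Evaluator(dataset)
    m = dataset.n_snps
    f_pos = evaluate(particle.position)
    candidates = [(particle.position, f_pos)]
    if variant == "ioblpso":
        opp = opposite_position(particle.position, m)
        candidates.append((opp, evaluate(opp)))
    best_pos, best_f = None, particle.pbest_fitness
    for pos, f in candidates:
        if f > best_f:
            best_pos, best_f = pos, f
    if best_pos is not None:
        particle.pbest = best_pos.copy()
        particle.pbest_fitness = best_f
    return particle


def update_gbest(state: SwarmState, dataset: Dataset) -> SwarmState:
    """Refresh the swarm's global best and advance the pbest counters.

    The global best is replaced only when the best personal best *strictly*
    exceeds it (ties keep the incumbent; among equal personal bests the
    lowest particle index wins). Every SNP occurrence in every current
    personal best then increments its counter, and the iteration counter
    advances.
    """
    best = max(
        range(len(state.particles)), key=lambda i: state.particles[i].pbest_fitness
    )
    if state.particles[best].pbest_fitness > state.gbest_fitness:
        state.gbest = state.particles[best].pbest.copy()
        state.gbest_fitness = state.particles[best].pbest_fitness
    for part in state.particles:
        np.add.at(state.count, part.pbest - 1, 1)
    state.iteration += 1
    return state


def _result_from(
    dataset: Dataset,
    indices: Sequence[int],
    mi_bits: float,
    state: SwarmState,
    trace: Sequence[float],
    variant: str,
) -> DetectionResult:
    idx = tuple(sorted(int(i) for i in indices))
    table = contingency(dataset, idx)
    return DetectionResult(
        snp_indices=idx,
        snp_ids=dataset.ids_at(idx),
        mi_interaction=FitnessValue(mi_bits),
        mi_individual=tuple(mutual_information(dataset, (i,)) for i in idx),
        pvalue=association_pvalue(table),
        counters=state.count.copy(),
        trace=tuple(trace),
        variant=variant,
    )


def postprocess(
    state: SwarmState,
    dataset: Dataset,
    config: SwarmConfig,
    trace: Sequence[float] = (),
    evaluate: Callable[[Sequence[int]], float] | None = None,
) -> DetectionResult:
    """Exhaustive deep search within the most suspected SNPs.

    SNPs are ranked by their pbest counters (descending; ties by ascending
    index), the ``top_n`` head is taken, and every K-subset of it is
    evaluated. The final answer is the global best unless some subset has
    strictly higher fitness, in which case the best such subset. The reported
    fitness can therefore never drop below the global best's.
    """
    if config.top_n < config.k:
        raise ValueError("top_n must be at least K")
    if evaluate is None:
        evaluate = _Evaluator(dataset)
    order = sorted(range(1, state.m + 1), key=lambda i: (-state.count[i - 1], i))
    top = order[: config.top_n]
    best_idx = tuple(state.gbest.tolist())
    best_f = state.gbest_fitness
    for subset in combinations(sorted(top), config.k):
        f = evaluate(subset)
        if f > best_f:
            best_idx, best_f = subset, f
    trace = list(trace) + [best_f]
    return _result_from(dataset, best_idx, best_f, state, trace, config.variant)


def run(
    dataset: Dataset, config: SwarmConfig, rng: np.random.Generator | None = None
) -> DetectionResult:
    """Execute one full optimization run.

    Initialization, then T iterations of inertia-weight update (dynamic for
    ``ioblpso``, static for ``pso``), velocity and position updates, personal
    best refresh (with the opposition step for ``ioblpso``), and global-best
    refresh; ``ioblpso`` finishes with the exhaustive post-procedure. The
    gbest fitness trace is non-decreasing by construction.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    evaluate = _Evaluator(dataset)
    state = initialize(dataset, config, rng)
    # reuse the memoized evaluator for everything after init
    evaluate._cache.update(
        {tuple(sorted(p.pbest.tolist())): p.pbest_fitness for p in state.particles}
    )
    trace = [state.gbest_fitness]
    for _ in range(config.t):
        for part in state.particles:
            if config.variant == "ioblpso":
                weights = [
                    dynamic_inertia(state.count, int(s), config.static_inertia)
                    for s in part.pbest
                ]
            else:
                weights = [config.static_inertia] * config.k
            vel = update_velocity(
                part, weights, state.gbest, state.m, config.c1, config.c2, rng
            )
            part.position = update_position(part, vel, state.m, rng)
            part.velocity = vel
        for part in state.particles:
            update_pbest(part, dataset, config.variant, evaluate)
        update_gbest(state, dataset)
        trace.append(state.gbest_fitness)
    if config.variant == "ioblpso":
        return postprocess(state, dataset, config, trace, evaluate)
    return _result_from(
        dataset, state.gbest.tolist(), state.gbest_fitness, state, trace, config.variant
    )


def multi_run(dataset: Dataset, config: SwarmConfig, runs: int) -> pd.DataFrame:
    """Repeat the search and aggregate identical answers, Table-style.

    Each run gets an independent child stream of ``config.seed``. Rows group
    runs that reported the same SNP set and carry: SNP ids/indices, how many
    runs found it (``times``), per-SNP and interaction MI, the G-test
    p-value, and its Bonferroni correction for the C(M, K) tests implied by
    an exhaustive scan. Sorted by interaction MI descending.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    children = np.random.SeedSequence(config.seed).spawn(runs)
    results = [run(dataset, config, np.random.default_rng(s)) for s in children]
    n_tests = math.comb(dataset.n_snps, config.k)
    groups: dict[tuple[int, ...], list[DetectionResult]] = {}
    for res in results:
        groups.setdefault(res.snp_indices, []).append(res)
    rows = []
    for idx, members in groups.items():
        r = members[0]
        rows.append(
            {
                "snp_ids": ",".join(r.snp_ids),
                "snp_indices": ",".join(str(i) for i in idx),
                "times": len(members),
                "mi_individual": ",".join(f"{f.mi_bits:.6f}" for f in r.mi_individual),
                "mi_interaction": r.mi_interaction.mi_bits,
                "pvalue": r.pvalue,
                "pvalue_bonferroni": min(1.0, r.pvalue * n_tests),
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        ["mi_interaction", "snp_indices"], ascending=[False, True]
    )
    return frame.reset_index(drop=True)
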