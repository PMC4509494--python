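"""Swarm optimizer: stage operations, full runs, and the plain-PSO baseline."""

from itertools import combinations

import numpy as np
import pytest

import episwarm.swarm as swarm_mod
from episwarm import (
    SwarmConfig,
    mutual_information,
    multi_run,
    run,
    simulate,
)
from episwarm.swarm import (
    Particle,
    dynamic_inertia,
    initialize,
    opposite_position,
    postprocess,
    update_gbest,
    update_pbest,
    update_position,
    update_velocity,
)


class ConstantRng:
    """Stub generator returning fixed uniform draws (for worked examples)."""

    def __init__(self, value=0.5):
        self.value = value

    def random(self):
        return self.value

    def uniform(self, lo, hi):
        return lo + self.value * (hi - lo)

    def integers(self, lo, hi):
        return lo

    def choice(self, arr):
        return np.asarray(arr)[0]


def make_particle(position, velocity=None, pbest=None, fitness=0.0):
    pos = np.asarray(position, dtype=np.int64)
    vel = np.zeros(len(pos)) if velocity is None else np.asarray(velocity, float)
    pb = pos.copy() if pbest is None else np.asarray(pbest, dtype=np.int64)
    return Particle(pos, vel, pb, fitness)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"p": 0},
            {"t": 0},
            {"k": 0},
            {"top_n": 1, "k": 2},
            {"c1": -1},
            {"variant": "genetic"},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SwarmConfig(**kwargs)

    def test_from_dict_rejects_unknown_keys(self):
        with pytest.raises(ValueError, match="unknown config keys"):
            SwarmConfig.from_dict({"particles": 5})


class TestInitialize:
    def test_invariants_and_counter_total(self, random_dataset):
        ds = random_dataset(n=40, m=10, seed=3)
        config = SwarmConfig(p=5, t=2, k=2, seed=11)
        state = initialize(ds, config)
        for part in state.particles:
            assert len(set(part.position.tolist())) == 2
            assert all(1 <= i <= 10 for i in part.position)
            assert all(-9 <= v <= 9 for v in part.velocity)
            assert part.pbest_fitness == mutual_information(ds, part.pbest).mi_bits
        assert state.gbest_fitness == max(p.pbest_fitness for p in state.particles)
        assert state.count.sum() == config.p * config.k
        assert state.iteration == 1

    def test_same_seed_same_state(self, random_dataset):
        ds = random_dataset(n=40, m=10, seed=3)
        config = SwarmConfig(p=5, t=2, seed=11)
        a, b = initialize(ds, config), initialize(ds, config)
        for pa, pb in zip(a.particles, b.particles):
            np.testing.assert_array_equal(pa.position, pb.position)
            np.testing.assert_array_equal(pa.velocity, pb.velocity)
        np.testing.assert_array_equal(a.gbest, b.gbest)

    def test_order_must_be_below_m(self, random_dataset):
        ds = random_dataset(n=20, m=4, seed=0)
        with pytest.raises(ValueError, match="K=4 must be < M=4"):
            initialize(ds, SwarmConfig(p=2, t=1, k=4, top_n=4))


class TestDynamicInertia:
    def test_endpoints_and_fallback(self):
        count = np.array([7, 2, 5])
        assert dynamic_inertia(count, 1) == 0.0  # max-counter SNP exploits
        assert dynamic_inertia(count, 2) == 1.0  # min-counter SNP explores
        assert dynamic_inertia(count, 3) == pytest.approx(2 / 5)
        assert dynamic_inertia(np.array([4, 4, 4]), 2) == 0.65
        assert dynamic_inertia(np.array([4, 4]), 1, static_inertia=0.3) == 0.3

    def test_out_of_range_index(self):
        with pytest.raises(IndexError):
            dynamic_inertia(np.array([1, 2]), 3)


class TestUpdateVelocity:
    def test_no_attraction_no_inertia_is_zero(self):
        part = make_particle([3, 7], velocity=[4.0, -2.0], pbest=[5, 9])
        out = update_velocity(part, [0.0, 0.0], np.array([8, 1]), 10, 0, 0, ConstantRng())
        np.testing.assert_array_equal(out, [0.0, 0.0])

    def test_worked_value(self):
        # W=0.65, v=2, C1=C2=2, r1=r2=0.5, pbest-pos=5, gbest-pos=15 -> 21.3
        part = make_particle([10], velocity=[2.0], pbest=[15])
        out = update_velocity(part, [0.65], np.array([25]), 100, 2, 2, ConstantRng(0.5))
        assert out[0] == pytest.approx(21.3, abs=1e-12)

    def test_out_of_range_replaced_by_uniform_draw(self):
        part = make_particle([1], velocity=[8.0], pbest=[10])
        out = update_velocity(part, [1.0], np.array([10]), 10, 2, 2, ConstantRng(0.999))
        assert -9 <= out[0] <= 9


class TestUpdatePosition:
    def test_truncates_in_range_sum(self):
        part = make_particle([10, 2])
        out = update_position(part, np.array([21.3, 0.4]), 100, ConstantRng())
        np.testing.assert_array_equal(out, [31, 2])

    def test_out_of_range_resampled_within_domain(self):
        part = make_particle([95, 2])
        rng = np.random.default_rng(0)
        out = update_position(part, np.array([21.3, 0.0]), 100, rng)
        assert 1 <= out[0] <= 100
        assert out[1] == 2

    def test_duplicates_resolved_to_distinct(self):
        part = make_particle([7, 6])
        rng = np.random.default_rng(0)
        out = update_position(part, np.array([0.0, 1.0]), 10, rng)
        assert len(set(out.tolist())) == 2
        assert 7 in out.tolist()  # first occurrence kept


class TestOpposite:
    def test_known_values(self):
        np.testing.assert_array_equal(opposite_position(np.array([3, 97]), 100), [98, 4])
        assert opposite_position(np.array([51]), 101)[0] == 51  # midpoint fixed

    @pytest.mark.parametrize("m", [5, 10, 101])
    def test_involution(self, m):
        pos = np.arange(1, m + 1)
        np.testing.assert_array_equal(opposite_position(opposite_position(pos, m), m), pos)


class TestUpdatePbest:
    def make_evaluator(self, scores):
        return lambda idx: scores[tuple(sorted(int(i) for i in idx))]

    def test_opposite_adopted_when_strictly_best(self, random_dataset):
        ds = random_dataset(n=20, m=10, seed=1)
        part = make_particle([2, 3], pbest=[4, 5], fitness=0.1)
        scores = {(2, 3): 0.2, (8, 9): 0.5, (4, 5): 0.1}  # opposite of (2,3) is (9,8)
        update_pbest(part, ds, "ioblpso", self.make_evaluator(scores))
        assert sorted(part.pbest.tolist()) == [8, 9]
        assert part.pbest_fitness == 0.5

    def test_all_ties_keep_previous(self, random_dataset):
        ds = random_dataset(n=20, m=10, seed=1)
        part = make_particle([2, 3], pbest=[4, 5], fitness=0.2)
        scores = {(2, 3): 0.2, (8, 9): 0.2, (4, 5): 0.2}
        update_pbest(part, ds, "ioblpso", self.make_evaluator(scores))
        assert part.pbest.tolist() == [4, 5]

    def test_position_preferred_over_equal_opposite(self, random_dataset):
        ds = random_dataset(n=20, m=10, seed=1)
        part = make_particle([2, 3], pbest=[4, 5], fitness=0.1)
        scores = {(2, 3): 0.4, (8, 9): 0.4, (4, 5): 0.1}
        update_pbest(part, ds, "ioblpso", self.make_evaluator(scores))
        assert part.pbest.tolist() == [2, 3]

    def test_pso_variant_ignores_opposite(self, random_dataset):
        ds = random_dataset(n=20, m=10, seed=1)
        part = make_particle([2, 3], pbest=[4, 5], fitness=0.1)
        scores = {(2, 3): 0.2, (4, 5): 0.1}  # opposite never queried
        update_pbest(part, ds, "pso", self.make_evaluator(scores))
        assert part.pbest.tolist() == [2, 3]


class TestUpdateGbest:
    def test_tie_keeps_incumbent_and_counters_advance(self, random_dataset):
        ds = random_dataset(n=30, m=8, seed=2)
        state = initialize(ds, SwarmConfig(p=4, t=1, seed=5))
        before = state.count.sum()
        gbest_before = state.gbest.copy()
        update_gbest(state, ds)  # no pbest changed, so best pbest ties gbest
        np.testing.assert_array_equal(state.gbest, gbest_before)
        assert state.count.sum() == before + 4 * 2
        assert state.iteration == 2

    def test_strictly_better_pbest_replaces(self, random_dataset):
        ds = random_dataset(n=30, m=8, seed=2)
        state = initialize(ds, SwarmConfig(p=4, t=1, seed=5))
        state.particles[2].pbest = np.array([1, 2])
        state.particles[2].pbest_fitness = state.gbest_fitness + 1.0
        update_gbest(state, ds)
        np.testing.assert_array_equal(state.gbest, [1, 2])


class TestPostprocess:
    def test_recovers_better_pair_in_top_n(self, strong_model):
        ds, truth = simulate(strong_model, 300, 300, 12, seed=4)
        config = SwarmConfig(p=3, t=1, k=2, top_n=12, seed=9)
        state = initialize(ds, config)
        state.gbest = np.array([1, 2] if truth.causal_indices != {1, 2} else [3, 4])
        state.gbest_fitness = mutual_information(ds, state.gbest).mi_bits
        result = postprocess(state, ds, config)
        best = max(
            (mutual_information(ds, c).mi_bits, c) for c in combinations(range(1, 13), 2)
        )
        assert result.snp_indices == best[1]
        assert result.mi_interaction.mi_bits == best[0]

    def test_never_lowers_gbest(self, random_dataset):
        ds = random_dataset(n=50, m=10, seed=6)
        config = SwarmConfig(p=5, t=1, k=2, top_n=3, seed=1)
        state = initialize(ds, config)
        result = postprocess(state, ds, config)
        assert result.mi_interaction.mi_bits >= state.gbest_fitness


class TestRun:
    def test_trace_non_decreasing_and_result_consistent(self, random_dataset):
        ds = random_dataset(n=50, m=15, seed=8)
        result = run(ds, SwarmConfig(p=8, t=12, seed=3))
        trace = np.array(result.trace)
        assert (np.diff(trace) >= 0).all()
        assert result.mi_interaction.mi_bits >= trace[-2]  # postprocess only improves
        assert result.mi_interaction.mi_bits >= max(f.mi_bits for f in result.mi_individual) - 1e-12
        assert result.counters.sum() == (12 + 1) * 8 * 2

    def test_reproducible_under_seed(self, random_dataset):
        ds = random_dataset(n=50, m=15, seed=8)
        config = SwarmConfig(p=6, t=8, seed=42)
        a, b = run(ds, config), run(ds, config)
        assert a.snp_indices == b.snp_indices
        assert a.trace == b.trace

    def test_pso_variant_skips_improvement_machinery(self, random_dataset, monkeypatch):
        ds = random_dataset(n=40, m=10, seed=9)

        def forbidden(*a, **k):  # pragma: no cover
            raise AssertionError("baseline PSO must not call this")

        monkeypatch.setattr(swarm_mod, "dynamic_inertia", forbidden)
        monkeypatch.setattr(swarm_mod, "opposite_position", forbidden)
        monkeypatch.setattr(swarm_mod, "postprocess", forbidden)
        result = run(ds, SwarmConfig(p=5, t=5, seed=1, variant="pso"))
        assert result.variant == "pso"
        assert len(result.snp_indices) == 2

    def test_stationary_without_attraction_or_inertia(self, random_dataset):
        ds = random_dataset(n=30, m=9, seed=4)
        config = SwarmConfig(p=4, t=6, c1=0, c2=0, static_inertia=0.0, seed=7, variant="pso")
        rng = np.random.default_rng(config.seed)
        state = initialize(ds, config, rng)
        starts = [p.position.copy() for p in state.particles]
        result = run(ds, config)
        # zero inertia and zero attraction: velocities collapse to 0, nobody moves
        assert set(result.snp_indices) <= {
            i for pos in starts for i in pos.tolist()
        }

    def test_planted_pair_recovered_in_most_seeded_runs(self, strong_model):
        ds, truth = simulate(strong_model, 1000, 1000, 50, seed=123)
        # confirm the planted pair dominates every other pair exhaustively
        best = max(
            (mutual_information(ds, c).mi_bits, c)
            for c in combinations(range(1, 51), 2)
        )
        assert set(best[1]) == truth.causal_indices
        hits = 0
        for seed in range(20):
            result = run(ds, SwarmConfig(p=50, t=50, seed=seed))
            hits += set(result.snp_indices) == truth.causal_indices
        assert hits >= 18


class TestMultiRun:
    def test_aggregates_and_sorts(self, strong_model):
        ds, truth = simulate(strong_model, 400, 400, 15, seed=5)
        table = multi_run(ds, SwarmConfig(p=20, t=15, seed=77), runs=4)
        assert table["times"].sum() == 4
        assert (table["mi_interaction"].diff().dropna() <= 0).all()
        assert {"pvalue", "pvalue_bonferroni", "snp_ids"} <= set(table.columns)
        top = {int(i) for i in table.loc[0, "snp_indices"].split(",")}
        assert top == truth.causal_indices  # easy instance: every run agrees

    def test_deterministic_given_seed(self, random_dataset):
        ds = random_dataset(n=40, m=12, seed=2)
        config = SwarmConfig(p=5, t=5, seed=9)
        a = multi_run(ds, config, runs=3)
        b = multi_run(ds, config, runs=3)
        assert a.equals(b)
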