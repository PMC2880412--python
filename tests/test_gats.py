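import math
from collections import deque

import numpy as np
import pytest
from scipy import stats

from abfold import (
    ABSequence,
    Conformation,
    EnergyModel,
    GATSConfig,
    Individual,
    Population,
    TabuState,
    gats_run,
)
from abfold.gats import (
    adjust_population_size,
    disturb,
    handle_total_tabu,
    initialize_population,
    is_tabu,
    ranking_select,
    select_crossover_pairs,
    tsm_step,
    tsr_accept,
    tsr_crossover,
    _rank_weights,
)

SEQ13 = ABSequence("ABBABBABABBAB")


def small_config(**kw):
    kw.setdefault("rng_seed", 11)
    kw.setdefault("max_generations", 20)
    kw.setdefault("tsm_iterations", 2)
    kw.setdefault("stagnation_limit", 50)
    return GATSConfig(**kw)


def make_individual(model, vector):
    conf = Conformation.from_vector(np.asarray(vector, dtype=float), model.n)
    return Individual(conf, model(conf))


class TestConfig:
    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="neighborhood_size"):
            GATSConfig(neighborhood_size=10)

    def test_out_of_range_override_warns(self):
        with pytest.warns(UserWarning, match="outside the benchmark range"):
            GATSConfig(neighborhood_size=10, allow_out_of_range=True)

    def test_defaults_within_printed_ranges(self):
        cfg = GATSConfig()
        assert 100 <= cfg.pop_min <= cfg.pop_max <= 500
        assert cfg.crossover_rate == 0.88
        assert 0.012 <= cfg.mutation_rate <= 0.025
        assert 7 <= cfg.tabu_min <= cfg.tabu_max <= 14
        assert 30 <= cfg.neighborhood_size <= 50
        assert 5 <= cfg.candidate_size <= 6


class TestInitializePopulation:
    def test_deterministic_under_seed(self):
        cfg = small_config()
        p1 = initialize_population(SEQ13, cfg, np.random.default_rng(3))
        p2 = initialize_population(SEQ13, cfg, np.random.default_rng(3))
        assert [m.energy for m in p1.members] == [m.energy for m in p2.members]

    def test_sorted_and_sized(self):
        pop = initialize_population(SEQ13, small_config(), np.random.default_rng(0))
        energies = [m.energy for m in pop.members]
        assert energies == sorted(energies)
        assert len(pop) == 100

    def test_angle_counts_for_n13(self):
        pop = initialize_population(SEQ13, small_config(), np.random.default_rng(0))
        assert len(pop[0].conf.theta) == 11
        assert len(pop[0].conf.beta) == 10


class TestRankingSelect:
    def test_best_selected_more_often_than_worst(self, model13):
        members = [make_individual(model13, np.full(21, 0.1)), make_individual(model13, np.full(21, 2.0))]
        members.sort(key=lambda m: m.energy)
        rng = np.random.default_rng(5)
        hits = sum(ranking_select(members, 1, rng)[0] is members[0] for _ in range(10_000))
        assert hits > 5_500

    def test_full_draw_returns_whole_population(self, model13, rng):
        members = [make_individual(model13, rng.uniform(-1, 1, 21)) for _ in range(6)]
        selected = ranking_select(members, 6, rng)
        assert sorted(id(m) for m in selected) == sorted(id(m) for m in members)

    def test_count_bounds(self, model13, rng):
        members = [make_individual(model13, rng.uniform(-1, 1, 21)) for _ in range(3)]
        with pytest.raises(ValueError):
            ranking_select(members, 4, rng)

    def test_frequencies_match_linear_rank_weights(self, model13, rng):
        """Single-draw frequencies agree with the exact multinomial within 3 sigma."""
        members = [make_individual(model13, rng.uniform(-1, 1, 21)) for _ in range(5)]
        members.sort(key=lambda m: m.energy)
        draws = 20_000
        counts = np.zeros(5)
        for _ in range(draws):
            chosen = ranking_select(members, 1, rng)[0]
            counts[members.index(chosen)] += 1
        p = _rank_weights(5, 1.8)
        sigma = np.sqrt(draws * p * (1 - p))
        assert np.all(np.abs(counts - draws * p) <= 3 * sigma)


class TestAdjustPopulationSize:
    def test_identical_energies_trigger_growth(self, model13):
        ind = make_individual(model13, np.full(21, 0.3))
        pop = Population([ind] * 100, 100, 500)
        grown = adjust_population_size(pop, small_config(), np.random.default_rng(0), model13)
        assert len(grown) == 110

    def test_growth_clamped_at_pop_max(self, model13):
        ind = make_individual(model13, np.full(21, 0.3))
        pop = Population([ind] * 500, 100, 500)
        grown = adjust_population_size(pop, small_config(), np.random.default_rng(0), model13)
        assert len(grown) == 500

    def test_no_shrink_below_pop_min(self, model13, rng):
        members = [make_individual(model13, rng.uniform(-np.pi, np.pi, 21)) for _ in range(100)]
        pop = Population(members, 100, 500)
        shrunk = adjust_population_size(pop, small_config(), rng, model13)
        assert len(shrunk) >= 100


class TestDisturb:
    def test_alpha_one_is_identity(self, random_conf, rng):
        conf = random_conf(8)
        out = disturb(conf, 3, 1.0, math.pi, rng)
        assert np.array_equal(out.vector, conf.vector)

    def test_exactly_one_parameter_changes(self, random_conf, rng):
        conf = random_conf(8)
        out = disturb(conf, 4, 0.3, math.pi, rng)
        diff = out.vector != conf.vector
        assert diff.sum() == 1 and diff[4]

    def test_alpha_zero_magnitude_is_uniform(self, rng):
        """At alpha = 0 the shift is lambda * (1 - r), i.e. U(0, lambda)."""
        conf = Conformation(np.zeros(3), np.zeros(2))
        lam = 1.0  # < pi so wrapping cannot fold the distribution
        mags = np.array([
            abs(disturb(conf, 0, 0.0, lam, rng).vector[0]) for _ in range(100_000)
        ])
        assert stats.kstest(mags, "uniform", args=(0, lam)).pvalue > 0.01

    def test_index_out_of_range(self, random_conf, rng):
        with pytest.raises(IndexError):
            disturb(random_conf(8), 11, 0.5, math.pi, rng)


class TestTabu:
    def test_fifo_eviction_and_alignment(self):
        tabu = TabuState(7, 14)
        for k in range(20):
            tabu.add(np.full(4, float(k)), float(k))
        assert len(tabu.solutions) == len(tabu.energies) <= tabu.bound
        # oldest entries evicted first
        assert tabu.energies[0] == 20 - len(tabu.energies)
        assert list(tabu.energies) == sorted(tabu.energies)

    def test_bound_adapts_within_limits(self):
        tabu = TabuState(7, 14)
        for _ in range(10):
            tabu.on_total_tabu()
        assert tabu.bound == 14
        for _ in range(50 * 8):
            tabu.add(np.zeros(2), 0.0)
        assert tabu.bound == 7

    def test_identical_entry_is_tabu(self, model13, rng):
        ind = make_individual(model13, rng.uniform(-1, 1, 21))
        tabu = TabuState()
        tabu.add(ind.vector, ind.energy)
        assert is_tabu(ind, tabu, psi=0.0, eta=0.0)

    def test_empty_list_never_tabu(self, model13, rng):
        ind = make_individual(model13, rng.uniform(-1, 1, 21))
        assert not is_tabu(ind, TabuState(), psi=10.0, eta=10.0)

    def test_criterion_is_a_conjunction(self, model13):
        a = make_individual(model13, np.zeros(21))
        far = make_individual(model13, np.full(21, 2.0))
        tabu = TabuState()
        tabu.add(a.vector, a.energy)
        # energy arbitrarily close but angle distance large -> not tabu
        assert not is_tabu(
            Individual(far.conf, a.energy), tabu, psi=1.0, eta=1.0
        )

    def test_wrapped_distance_used(self, model13):
        a = make_individual(model13, np.full(21, np.pi - 0.01))
        b = make_individual(model13, np.full(21, -np.pi + 0.01))
        tabu = TabuState()
        tabu.add(a.vector, a.energy)
        # across the seam the wrapped distance is tiny
        assert is_tabu(Individual(b.conf, a.energy), tabu, psi=1.0, eta=0.5)


class TestTSM:
    def test_empty_tabu_accepts_best_neighbor(self, model13, rng):
        current = make_individual(model13, rng.uniform(-1, 1, 21))
        out, _ = tsm_step(current, TabuState(), current, 0.5, small_config(), rng, model13)
        assert out is not current

    def test_aspiration_overrides_tabu(self, model13, rng):
        """A candidate below the global best is accepted even when everything is tabu."""
        current = make_individual(model13, rng.uniform(-1, 1, 21))
        weak_best = Individual(current.conf, 1e9)  # any neighbor beats this
        tabu = TabuState()
        cfg = small_config(psi=1e12, eta=1e12)  # everything is tabu
        out, tabu = tsm_step(current, tabu, weak_best, 0.5, cfg, rng, model13)
        assert out.energy < 1e9
        assert tabu.total_tabu_events == 0  # aspiration, not total-tabu escape

    def test_inferior_moves_are_accepted(self, model13, rng):
        """Chained TSM steps go uphill at least once: the hill-climbing contract."""
        pop = initialize_population(SEQ13, small_config(), rng, model13)
        current = pop.best
        tabu = TabuState()
        uphill = 0
        for _ in range(200):
            nxt, tabu = tsm_step(current, tabu, pop.best, 0.9, small_config(), rng, model13)
            if nxt.energy > current.energy:
                uphill += 1
            current = nxt
        assert uphill > 0

    def test_total_tabu_escapes_from_global_best(self, model13, rng):
        current = make_individual(model13, rng.uniform(-1, 1, 21))
        best = make_individual(model13, np.full(21, 0.5))
        tabu = TabuState()
        cfg = small_config(psi=1e12, eta=1e12)
        out = handle_total_tabu(tabu, best, 0.3, cfg, rng, model13)
        # parent is the global best: exactly two parameters moved off best's vector
        assert np.sum(out.vector != best.vector) <= 2
        assert np.any(out.vector != best.vector)
        assert tabu.total_tabu_events == 1

    def test_total_tabu_inside_step(self, model13, rng):
        current = make_individual(model13, rng.uniform(-1, 1, 21))
        strong_best = Individual(current.conf, -1e9)  # aspiration unreachable
        tabu = TabuState()
        tabu.add(current.vector, current.energy)  # non-empty memory
        cfg = small_config(psi=1e12, eta=1e12)  # so every candidate matches it
        _, tabu = tsm_step(current, tabu, strong_best, 0.5, cfg, rng, model13)
        assert tabu.total_tabu_events == 1


class TestTSR:
    def test_fixed_point(self, model13):
        a = make_individual(model13, np.full(21, 0.7))
        child = tsr_crossover(a, a, a, np.random.default_rng(0))
        assert np.allclose(child.vector, a.vector)

    def test_offspring_in_interval_hull(self, model13, rng):
        for _ in range(50):
            a = make_individual(model13, rng.uniform(-3, 3, 21))
            b = make_individual(model13, rng.uniform(-3, 3, 21))
            best = make_individual(model13, rng.uniform(-3, 3, 21))
            child = tsr_crossover(a, b, best, rng)
            lo = np.minimum.reduce([a.vector, b.vector, best.vector]) - 1e-12
            hi = np.maximum.reduce([a.vector, b.vector, best.vector]) + 1e-12
            assert np.all((child.vector >= lo) & (child.vector <= hi))

    def test_length_mismatch_rejected(self, model13, rng):
        m9 = EnergyModel(ABSequence("ABBABBABA"))
        a = make_individual(model13, rng.uniform(-1, 1, 21))
        b = make_individual(m9, rng.uniform(-1, 1, 13))
        with pytest.raises(ValueError, match="equal-length"):
            tsr_crossover(a, b, a, rng)

    def test_accept_below_mean(self, model13, rng):
        child = make_individual(model13, rng.uniform(-1, 1, 21))
        parents = (child, child)
        fifo = deque(maxlen=14)
        fifo.append(child.energy)  # even a tabu-matching child passes below the mean
        out = tsr_accept(child, parents, pop_mean_energy=child.energy + 1, fitness_tabu=fifo, psi=1.0)
        assert out is child

    def test_accept_above_mean_when_not_tabu(self, model13, rng):
        child = make_individual(model13, rng.uniform(-1, 1, 21))
        out = tsr_accept(child, (child, child), child.energy - 1, deque(maxlen=14), psi=0.1)
        assert out is child

    def test_tabu_above_mean_returns_better_parent(self, model13, rng):
        child = make_individual(model13, rng.uniform(-1, 1, 21))
        good = Individual(child.conf, child.energy - 5)
        bad = Individual(child.conf, child.energy + 5)
        fifo = deque([child.energy], maxlen=14)
        out = tsr_accept(child, (bad, good), child.energy - 1, fifo, psi=0.1)
        assert out is good


class TestSelectCrossoverPairs:
    def make_pop(self, model13, rng, size):
        members = [make_individual(model13, rng.uniform(-np.pi, np.pi, 21)) for _ in range(size)]
        return Population(members, 100, 500)

    def test_default_mode_pairs_with_best(self, model13, rng):
        pop = self.make_pop(model13, rng, 100)
        pairs = select_crossover_pairs(pop, 0.88, rng, return_indices=True)
        assert len(pairs) == 88
        assert all(j == 0 for _, j in pairs)
        assert all(i >= 10 for i, _ in pairs)  # top decile untouched

    def test_small_population_excludes_top(self, model13, rng):
        pop = self.make_pop(model13, rng, 10)
        pairs = select_crossover_pairs(pop, 0.5, rng, return_indices=True)
        assert all(i >= 1 for i, _ in pairs)

    def test_free_pairing_maximizes_distance_greedily(self, model13, rng):
        pop = self.make_pop(model13, rng, 100)
        pairs = select_crossover_pairs(pop, 0.88, rng, cross_with_best=False, return_indices=True)
        assert len(pairs) == 44
        assert all(i != j for i, j in pairs)

    def test_invalid_rate(self, model13, rng):
        pop = self.make_pop(model13, rng, 100)
        with pytest.raises(ValueError, match="rate"):
            select_crossover_pairs(pop, 0.0, rng)


class TestGatsRun:
    def run(self, **kw):
        kw.setdefault("rng_seed", 4)
        kw.setdefault("max_evaluations", 8000)
        kw.setdefault("max_generations", 10**6)
        return gats_run(SEQ13, GATSConfig(**kw))

    def test_trajectory_best_is_non_increasing(self):
        res = self.run()
        assert np.all(np.diff(res.best_series) <= 1e-12)

    def test_best_energy_equals_trajectory_minimum(self):
        res = self.run()
        assert res.best_energy <= res.best_series.min() + 1e-12

    def test_deterministic_under_seed(self):
        r1, r2 = self.run(), self.run()
        assert r1.best_energy == r2.best_energy
        assert np.array_equal(r1.best_conf.vector, r2.best_conf.vector)
        assert r1.trajectory == r2.trajectory

    def test_budget_overshoot_is_bounded(self):
        # the budget is checked between operator applications, so a run may
        # exceed it by at most one neighborhood batch, one population
        # initialization, or one growth step
        res = self.run()
        cfg = GATSConfig()
        slack = cfg.neighborhood_size + cfg.pop_min + cfg.pop_max // 10
        assert res.evaluations <= 8000 + slack

    def test_evaluation_count_matches_energy_calls(self, monkeypatch):
        """RunResult.evaluations equals the number of energy-functional calls."""
        import abfold.gats as gats_mod

        calls = {"n": 0}
        orig = EnergyModel.energy_of_arrays

        def counting(self, theta, beta):
            calls["n"] += 1
            return orig(self, theta, beta)

        monkeypatch.setattr(EnergyModel, "energy_of_arrays", counting)
        res = gats_run(SEQ13, GATSConfig(rng_seed=4, max_evaluations=3000, max_generations=10**6))
        assert res.evaluations == calls["n"]

    def test_cached_energy_is_coherent(self, model13):
        res = self.run()
        assert model13(res.best_conf) == pytest.approx(res.best_energy, abs=1e-9)

    def test_result_reports_seed_and_sequence(self):
        res = self.run()
        assert res.seed == 4
        assert res.sequence == str(SEQ13)
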