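"""The weekly Monte Carlo update loop: division, clones, competition."""

from dataclasses import replace

import numpy as np
import pytest

import hscsoma as h
from hscsoma.engine import COMPETITION_WEIGHT_FLOOR, _snapshot

from conftest import desk_scale


def make_config(**over):
    cfg = h.get_preset("mutations_only")
    return replace(cfg, **over)


def flat_schedules(n0, cap, rate):
    return h.Schedules(
        initial_size=n0,
        adult_size=cap,
        early_division_rate=rate,
        adult_division_rate=rate,
    )


def neutral_config(n0=300, cap=2000, rate=0.025, **over):
    return make_config(
        dfe=h.DFESpec(sigma=0.0, tier3_rate_per_division=0.0),
        schedules=flat_schedules(n0, cap, rate),
        initial_cells=n0,
        **over,
    )


class TestInitializePool:
    def test_default_pool_is_300_cells_at_fitness_one(self):
        pool = h.initialize_pool(make_config())
        assert pool.n_cells == 300
        assert np.all(pool.fitness == 1.0)
        assert np.all(pool.tier3 == 0)
        assert pool.week == 0

    def test_configured_initial_count(self):
        pool = h.initialize_pool(make_config(initial_cells=10))
        assert pool.n_cells == 10

    def test_per_cell_and_single_ancestral_clone_modes(self):
        per_cell = h.initialize_pool(make_config(initial_cells=10))
        assert per_cell.n_clones == 10
        single = h.initialize_pool(
            make_config(initial_cells=10, initial_clones="single")
        )
        assert single.n_clones == 1
        assert np.all(single.clone_id == 0)

    def test_same_seed_gives_identical_pools(self):
        a = h.initialize_pool(make_config(seed=3))
        b = h.initialize_pool(make_config(seed=3))
        np.testing.assert_array_equal(a.fitness, b.fitness)
        assert a.rng.division.random() == b.rng.division.random()


class TestDivideCells:
    def test_zero_division_probability_leaves_the_pool_unchanged(self):
        cfg = neutral_config(rate=0.0)
        pool = h.initialize_pool(cfg)
        h.divide_cells(pool, cfg)
        assert pool.n_cells == 300

    @pytest.mark.parametrize("symmetric", [False, True])
    def test_certain_division_doubles_the_pool(self, symmetric):
        cfg = neutral_config(n0=100, cap=10_000, rate=1.0,
                             symmetric_division=symmetric)
        pool = h.initialize_pool(cfg)
        h.divide_cells(pool, cfg)
        assert pool.n_cells == 200
        assert np.all(pool.fitness == 1.0)
        assert np.all(pool.tier3 == 0)

    def test_dividing_fraction_matches_the_weekly_probability(self):
        n = 10_000
        cfg = neutral_config(n0=n, cap=10 * n, rate=0.5)
        pool = h.initialize_pool(cfg)
        h.divide_cells(pool, cfg)
        frac = (pool.n_cells - n) / n
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)

    def test_mother_state_is_retained_under_the_default_update(self):
        cfg = make_config(
            dfe=h.DFESpec(sigma=0.2, positive_tail_fraction=0.0,
                          tier3_rate_per_division=0.5),
            schedules=flat_schedules(100, 10_000, 1.0),
            initial_cells=100,
        )
        pool = h.initialize_pool(cfg)
        h.divide_cells(pool, cfg)
        # first 100 slots are the self-renewing daughters, unchanged
        assert np.all(pool.fitness[:100] == 1.0)
        assert np.all(pool.tier3[:100] == 0)
        assert np.any(pool.fitness[100:] != 1.0)


class TestAssignClones:
    def test_small_deviation_keeps_the_clone_label(self):
        pool = h.initialize_pool(make_config(initial_cells=4))
        ids = h.assign_clones(pool, np.array([1.0, 1.01]),
                              np.array([0, 1]), threshold=0.05)
        np.testing.assert_array_equal(ids, [0, 1])

    def test_threshold_crossing_founds_a_new_clone(self):
        pool = h.initialize_pool(make_config(initial_cells=4))
        ids = h.assign_clones(pool, np.array([1.1]), np.array([2]), threshold=0.05)
        assert ids[0] == 4  # fresh label
        assert pool.founder_fitness[4] == pytest.approx(1.1)

    def test_steady_drift_founds_a_clone_every_second_division(self):
        # Daughters drifting +0.6*theta per division from the current founder
        # cross the threshold on every second step.
        theta = 0.05
        pool = h.initialize_pool(make_config(initial_cells=1))
        clone = np.array([0])
        fitness = 1.0
        new_clone_steps = []
        for step in range(1, 9):
            fitness += 0.6 * theta
            new = h.assign_clones(pool, np.array([fitness]), clone, theta)
            if new[0] != clone[0]:
                new_clone_steps.append(step)
            clone = new
        assert new_clone_steps == [2, 4, 6, 8]

    def test_non_positive_threshold_rejected(self):
        pool = h.initialize_pool(make_config(initial_cells=1))
        with pytest.raises(h.ConfigError):
            h.assign_clones(pool, np.array([1.0]), np.array([0]), threshold=0.0)


class TestCompetition:
    def test_pool_within_capacity_is_untouched(self):
        cfg = neutral_config(n0=300, cap=2000)
        pool = h.initialize_pool(cfg)
        assert h.apply_competition(pool, cfg) == 0
        assert pool.n_cells == 300

    def test_equal_fitness_overflow_is_a_fair_lottery(self):
        # 200 equal cells against capacity 100: each survives about half
        # the time across replicate lotteries.
        cfg = neutral_config(n0=200, cap=200)
        cfg = replace(cfg, schedules=flat_schedules(100, 200, 0.025))
        survival = np.zeros(200)
        reps = 300
        for seed in range(reps):
            pool = h.initialize_pool(replace(cfg, initial_cells=200, seed=seed))
            removed = h.apply_competition(pool, cfg)
            assert removed == 100 and pool.n_cells == 100
            survival[np.unique(pool.clone_id)] += 1
        freq = survival / reps
        assert abs(freq.mean() - 0.5) < 1e-9  # exactly half survive each round
        assert np.all(np.abs(freq - 0.5) < 3 * np.sqrt(0.25 / reps) + 0.02)

    def test_high_fitness_cell_wins_an_overflow_by_one(self):
        # fitness (1.0, eps): the fit cell survives with odds 1/(1+eps).
        cfg = neutral_config(n0=2, cap=2)
        cfg = replace(cfg, schedules=flat_schedules(1, 2, 0.025))
        wins = 0
        for seed in range(200):
            pool = h.initialize_pool(replace(cfg, initial_cells=2, seed=seed))
            pool.fitness = np.array([1.0, COMPETITION_WEIGHT_FLOOR])
            h.apply_competition(pool, cfg)
            wins += int(pool.clone_id[0] == 0)
        assert wins == 200


class TestStepWeek:
    def test_neutral_step_changes_only_demography(self):
        cfg = neutral_config()
        pool = h.initialize_pool(cfg)
        for _ in range(20):
            h.step_week(pool, cfg)
        assert np.all(pool.fitness == 1.0)
        assert np.all(pool.tier3 == 0)
        assert pool.week == 20

    def test_uniform_environmental_drop_in_a_single_step(self):
        # With divisions off, sigma=0 and a symmetric environment, one step
        # lowers mean fitness by the analytic weekly drop.
        cfg = neutral_config(rate=0.0, lifespan_weeks=1,
                             env=h.EnvSpec(enabled=True))
        pool = h.initialize_pool(cfg)
        h.step_week(pool, cfg)
        expected = 1.0 - h.weekly_fitness_drop(0.0)
        assert pool.fitness.mean() == pytest.approx(expected, abs=1e-7)

    def test_pool_never_exceeds_capacity(self, small_config):
        traj = h.run_simulation(small_config)
        caps = np.array([small_config.schedules.capacity(int(w)) for w in traj.weeks])
        assert np.all(traj.pool_size <= caps)


class TestRunSimulation:
    def test_zero_lifespan_records_only_the_initial_state(self):
        traj = h.run_simulation(make_config(lifespan_weeks=0))
        assert len(traj.weeks) == 1 and traj.weeks[0] == 0
        assert traj.pool_size[0] == 300

    def test_weekly_updates_and_recording_cadence(self, small_config):
        traj = h.run_simulation(small_config)
        assert traj.weeks[-1] == 200
        assert len(traj.weeks) == 201  # cadence 1: every week plus week 0

    def test_same_seed_reproduces_the_trajectory(self, small_config):
        a = h.run_simulation(small_config)
        b = h.run_simulation(small_config)
        for name in ("pool_size", "mean_fitness", "mean_tier3",
                     "top_clone_share", "n_clones"):
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_disabled_environment_is_bit_for_bit_mutations_only(self, small_config):
        # Environment draws come from a dedicated stream, so a disabled
        # environment block (whatever its parameters) changes nothing.
        base = h.run_simulation(small_config)
        other = h.run_simulation(
            replace(small_config,
                    env=h.EnvSpec(enabled=False, f_min=0.5, positive_tail_fraction=0.0))
        )
        np.testing.assert_array_equal(base.mean_fitness, other.mean_fitness)
        np.testing.assert_array_equal(base.mean_tier3, other.mean_tier3)

    def test_neutral_accrual_matches_the_analytic_expectation(self):
        # With sigma=0 and the environment off, the pool-mean Tier-3 count at
        # age T is mu0 * sum_t m(t) d(t)/(1+d(t)) under the default update.
        cfg = make_config(
            dfe=h.DFESpec(sigma=0.0),
            lifespan_weeks=600,
            schedules=replace(h.schedules_from_preset("stable"), adult_size=500),
            record_cadence=100,
        )
        sched = cfg.schedules
        mu0 = cfg.dfe.tier3_rate_per_division
        d = np.array([sched.division_probability(t) for t in range(600)])
        expected = mu0 * np.sum(d / (1.0 + d))
        finals = [
            h.run_simulation(replace(cfg, seed=s)).mean_tier3[-1] for s in range(8)
        ]
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - expected) < 3 * se

    def test_purifying_selection_slows_tier3_accumulation(self):
        # A wide all-deleterious DFE purges mutation-laden cells: end-of-life
        # mean Tier-3 burden is lower than under a near-neutral DFE.
        def end_burden(sigma):
            vals = []
            for seed in (1, 2, 3):
                cfg = desk_scale(
                    "mutations_only", seed=seed,
                    schedules=replace(h.schedules_from_preset("stable"),
                                      adult_size=1000),
                )
                cfg = replace(cfg, dfe=replace(cfg.dfe, sigma=sigma,
                                               positive_tail_fraction=0.0))
                vals.append(h.run_simulation(cfg).mean_tier3[-1])
            return np.mean(vals)

        assert end_burden(5e-1) < end_burden(5e-6)
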