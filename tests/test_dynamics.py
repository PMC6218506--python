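"""Update rules, elementary events and the Monte Carlo scheduler."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from coevogame import (
    SimulationParams,
    elementary_update,
    fermi_copy_probability,
    run_simulation,
    strategy_copy_probability,
    update_perception,
)
from coevogame.dynamics import _apply_update, _new_perception
from conftest import make_world


class TestFermiCopyProbability:
    def test_equal_distances_give_half(self):
        terms = fermi_copy_probability(0.3, 0.7, 0.5)
        assert terms.p == pytest.approx(0.5)
        assert terms.delta_x == pytest.approx(0.2)
        assert terms.delta_y == pytest.approx(0.2)

    @pytest.mark.parametrize("theta_th, tt", [(0.7, 0.7), (0.3, 0.7), (0.5, 0.5)])
    def test_noise_is_max_distance_to_threshold(self, theta_th, tt):
        terms = fermi_copy_probability(theta_th - 0.01, theta_th + 0.01, theta_th)
        assert terms.tt == pytest.approx(tt)

    def test_fully_entrenched_focal_value(self):
        # dx = 0.7, dy = 0 at theta_th = 0.7: p = 1 / (1 + e)
        terms = fermi_copy_probability(0.0, 0.7, 0.7)
        assert terms.p == pytest.approx(1.0 / (1.0 + math.e), abs=1e-12)

    def test_same_side_pair_rejected(self):
        with pytest.raises(ValueError):
            fermi_copy_probability(0.1, 0.2, 0.5)

    @given(
        theta_th=st.floats(0.05, 0.95),
        a=st.floats(0.0, 1.0),
        b=st.floats(0.0, 1.0),
    )
    def test_probability_ordering(self, theta_th, a, b):
        theta_x = a * theta_th * 0.999  # strictly safe side
        theta_y = theta_th + b * (1 - theta_th)  # dangerous side
        terms = fermi_copy_probability(theta_x, theta_y, theta_th)
        assert 0.0 < terms.p < 1.0
        if terms.delta_x > terms.delta_y:
            assert terms.p < 0.5
        elif terms.delta_x < terms.delta_y:
            assert terms.p > 0.5


class TestPerceptionUpdate:
    @pytest.mark.parametrize(
        "tx, ty, expected",
        [
            (0.3, 0.4, 0.299),      # both safe: reinforce toward 0
            (0.8, 0.9, 0.801),      # both dangerous: reinforce toward 1
            (0.0005, 0.2, 0.0),     # clamped at the lower boundary
        ],
    )
    def test_reinforcement_branch(self, tx, ty, expected):
        world = make_world(np.ones((2, 2)), np.full((2, 2), 0.5))
        world.perception[0, 0] = tx
        world.perception[0, 1] = ty
        params = SimulationParams(b0=1.2, theta_th=0.5, L=2, delta=0.001, sweeps=1,
                                  stationary_window=1)
        new = update_perception(world, (0, 0), (0, 1), params, np.random.default_rng(0))
        assert new == pytest.approx(expected)
        assert world.perception[0, 0] == pytest.approx(expected)

    def test_upper_clamp(self):
        assert _new_perception(0.9997, 0.9, 0.5, 0.001, u=0.0) == 1.0

    def test_cross_side_copy_frequency(self):
        # Fermi branch: copy frequency over repeated draws matches the closed form
        tx, ty, theta_th = 0.3, 0.7, 0.5
        p = fermi_copy_probability(tx, ty, theta_th).p
        rng = np.random.default_rng(11)
        n = 20_000
        hits = sum(_new_perception(tx, ty, theta_th, 0.001, rng.random()) == ty for _ in range(n))
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 3 * se


class TestStrategyCopyProbability:
    def test_maximal_gap_saturates(self):
        assert strategy_copy_probability(0.0, 9.6, b0=1.2, degree=8) == pytest.approx(1.0)

    def test_half_gap(self):
        assert strategy_copy_probability(0.0, 4.8, b0=1.2, degree=8) == pytest.approx(0.5)

    def test_vanishing_gap(self):
        assert strategy_copy_probability(1.0, 1.0 + 1e-9, b0=1.2, degree=8) < 1e-9

    @pytest.mark.parametrize("ux, uy", [(1.0, 1.0), (2.0, 1.0)])
    def test_gate_violation_rejected(self, ux, uy):
        with pytest.raises(ValueError):
            strategy_copy_probability(ux, uy, b0=1.2, degree=8)


class TestElementaryUpdate:
    def test_uniform_cooperator_world_is_frozen(self):
        # identical utilities everywhere: the strict gate never fires
        world = make_world(np.ones((4, 4)), np.full((4, 4), 0.3))
        params = SimulationParams(b0=1.2, theta_th=0.5, L=4, sweeps=1, stationary_window=1)
        rng = np.random.default_rng(5)
        before_s, before_p = world.strategy.copy(), world.perception.copy()
        for _ in range(200):
            rec = elementary_update(world, params, rng)
            assert not rec.perception_changed and not rec.strategy_changed
        assert np.array_equal(world.strategy, before_s)
        assert np.array_equal(world.perception, before_p)

    def test_changes_imply_utility_gate(self):
        params = SimulationParams(b0=1.3, theta_th=0.6, L=6, delta=0.05, sweeps=1,
                                  stationary_window=1)
        rng = np.random.default_rng(2)
        from coevogame import build_lattice

        world = build_lattice(params, rng)
        fired = 0
        for _ in range(2000):
            rec = elementary_update(world, params, rng)
            if rec.perception_changed or rec.strategy_changed:
                assert rec.u_y > rec.u_x
                fired += 1
            assert 0.0 <= world.perception.min() and world.perception.max() <= 1.0
        assert fired > 0

    def test_gated_copy_frequency_matches_linear_rule(self):
        # 3x3 toy world: central defector (HG, U = 7.2) against a cooperator
        # neighbour (U = 7); empirical copy rate over 1e5 gated trials should
        # match (U_y - U_x) / (8 b0) within 3 binomial standard errors.
        strat = np.ones((3, 3), dtype=np.int8)
        strat[1, 1] = 0
        world = make_world(strat, np.full((3, 3), 0.9))
        params = SimulationParams(b0=1.2, theta_th=0.5, L=3, sweeps=1, stationary_window=1)
        focal_flat = 0 * 3 + 1  # site (0, 1), a cooperator; its 'down' neighbour is (1, 1)
        choice = world.neighbor_table()[focal_flat].tolist().index(1 * 3 + 1)
        p_expected = strategy_copy_probability(7.0, 7.2, b0=1.2, degree=8)
        rng = np.random.default_rng(123)
        n, hits = 100_000, 0
        for _ in range(n):
            rec = _apply_update(world, params, focal_flat, choice, rng.random(), rng.random())
            assert rec.u_x == pytest.approx(7.0) and rec.u_y == pytest.approx(7.2)
            hits += rec.strategy_changed
            world.strategy[0, 1] = 1  # reset the focal agent for the next trial
            world.perception[0, 1] = 0.9
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(hits / n - p_expected) < 3 * se


class TestRunSimulation:
    def small(self, **kw):
        base = dict(b0=1.2, theta_th=0.5, L=4, sweeps=10, record_every=1,
                    stationary_window=5, seed=7)
        base.update(kw)
        return SimulationParams(**base)

    def test_zero_sweeps_keeps_initial_record_only(self):
        result = run_simulation(self.small(sweeps=0, stationary_window=1))
        assert len(result.series) == 1
        assert result.series.c.iloc[0] == 0.5

    def test_numba_and_python_engines_agree_exactly(self):
        a = run_simulation(self.small(), engine="numba")
        b = run_simulation(self.small(), engine="python")
        assert a.series.equals(b.series)
        assert np.array_equal(a.world.strategy, b.world.strategy)
        assert np.array_equal(a.world.perception, b.world.perception)

    def test_bit_identical_rerun_and_seed_sensitivity(self):
        p = self.small(L=8, sweeps=30, stationary_window=10)
        a, b = run_simulation(p), run_simulation(p)
        assert a.series.equals(b.series)
        assert np.array_equal(a.world.perception, b.world.perception)
        c = run_simulation(p, seed=p.seed + 1)
        assert not np.array_equal(a.world.perception, c.world.perception)

    def test_zero_threshold_runs_harmony_game_only(self):
        # theta_th = 0: the safe set is empty for the entire run
        result = run_simulation(self.small(theta_th=0.0, L=10, sweeps=50, stationary_window=10))
        assert (result.series.s == 0.0).all()
        assert result.series.c.iloc[-1] >= result.series.c.iloc[0]

    def test_perception_clamped_under_aggressive_learning_rate(self):
        result = run_simulation(self.small(L=10, delta=0.3, sweeps=50, stationary_window=10))
        assert result.world.perception.min() >= 0.0
        assert result.world.perception.max() <= 1.0

    def test_capture_snapshots(self):
        result = run_simulation(self.small(sweeps=6), capture_sweeps=[0, 3, 6])
        assert sorted(result.captures) == [0, 3, 6]
        assert result.captures[0].strategy.mean() == 0.5
        with pytest.raises(ValueError):
            run_simulation(self.small(sweeps=6), capture_sweeps=[7])

    def test_record_cadence(self):
        result = run_simulation(self.small(sweeps=10, record_every=3))
        assert result.series.sweep.tolist() == [0, 3, 6, 9]
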