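"""Marine Predators Algorithm: worked-example arithmetic and invariants."""

import numpy as np
import pytest

from mpadbn import (MPAConfig, SearchSpace, StepContext, benchmark_objective,
                    compute_cf, decode_candidate, error_rate, fads_effect,
                    hyperparameter_space, init_population, levy_vector,
                    optimize, phase1_update, phase2_update, phase3_update)
from mpadbn.mpa import _first_half, _phase_of


def make_ctx(n, d, *, RB=0.0, RL=0.0, R=0.0, CF=1.0, r=1.0, U=0.0,
             R_fads=0.0, r1=None, r2=None):
    full = lambda v: np.full((n, d), float(v))
    idx = np.arange(n)
    return StepContext(RB=full(RB), RL=full(RL), R=full(R), CF=CF,
                       r=np.full(n, float(r)), U=full(U), R_fads=full(R_fads),
                       r1=idx if r1 is None else np.asarray(r1),
                       r2=idx if r2 is None else np.asarray(r2))


SPACE1 = SearchSpace(lb=[-10.0], ub=[10.0])
CFG = MPAConfig(n=1, Imax=9, seed=0)


class TestInit:
    def test_within_bounds_for_many_draws(self):
        space = SearchSpace(lb=[-3.0, 0.0, 5.0], ub=[-1.0, 2.0, 50.0])
        pop = init_population(space, MPAConfig(n=10_000, seed=3))
        assert np.all(pop >= space.lb) and np.all(pop <= space.ub)

    def test_degenerate_bounds_collapse_to_lb(self):
        eps = 1e-12
        space = SearchSpace(lb=[1.0], ub=[1.0 + eps])
        pop = init_population(space, MPAConfig(n=50, seed=0))
        np.testing.assert_allclose(pop, 1.0, atol=1e-11)

    def test_same_seed_identical(self):
        space = SearchSpace(lb=[-1.0] * 4, ub=[1.0] * 4)
        cfg = MPAConfig(n=7, seed=42)
        np.testing.assert_array_equal(init_population(space, cfg),
                                      init_population(space, cfg))


class TestAdaptiveFactor:
    def test_endpoint_and_midpoint_values(self):
        assert compute_cf(0, 100) == 1.0
        assert compute_cf(100, 100) == 0.0
        assert compute_cf(50, 100) == pytest.approx(0.5)

    def test_monotone_nonincreasing_over_schedule(self):
        vals = [compute_cf(i, 200) for i in range(201)]
        assert np.all(np.diff(vals) <= 0)

    def test_iteration_past_end_rejected(self):
        with pytest.raises(ValueError):
            compute_cf(101, 100)


class TestLevy:
    def test_shape_and_reproducibility(self):
        a = levy_vector((3, 4), 1.5, np.random.default_rng(5))
        b = levy_vector((3, 4), 1.5, np.random.default_rng(5))
        assert a.shape == (3, 4)
        np.testing.assert_array_equal(a, b)

    def test_tail_exponent_matches_alpha(self):
        """Hill estimator on the top 1% of 1e5 draws recovers alpha."""
        alpha = 1.5
        draws = np.abs(levy_vector(100_000, alpha, np.random.default_rng(11)))
        top = np.sort(draws)[-1000:]
        hill = 1.0 / np.mean(np.log(top[1:] / top[0]))
        assert abs(hill - alpha) < 0.3

    def test_alpha_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            levy_vector(3, 2.5, np.random.default_rng(0))


class TestPhaseUpdates:
    def test_phase1_zero_brownian_is_fixed_point(self):
        prey = np.array([[1.0], [2.0]])
        out = phase1_update(prey, np.array([5.0]), make_ctx(2, 1, RB=0.0, R=1.0),
                            MPAConfig(n=2))
        np.testing.assert_array_equal(out, prey)

    def test_phase1_unit_brownian_at_elite_is_fixed_point(self):
        prey = np.full((3, 2), 4.0)
        out = phase1_update(prey, np.full(2, 4.0),
                            make_ctx(3, 2, RB=1.0, R=1.0), MPAConfig(n=3))
        np.testing.assert_array_equal(out, prey)

    def test_phase1_scalar_worked_example(self):
        """Elite=2, Prey=1, RB=0.5, R=1, P=0.5: step=0.5*(2-0.5)=0.75 ->1.375."""
        out = phase1_update(np.array([[1.0]]), np.array([2.0]),
                            make_ctx(1, 1, RB=0.5, R=1.0), MPAConfig(n=1))
        np.testing.assert_allclose(out, [[1.375]])

    def test_phase2_halves_follow_their_rules(self):
        """n=2, d=1, all draws pinned at 0.5, CF=0.25, elite=2."""
        prey = np.array([[1.0], [3.0]])
        elite = np.array([2.0])
        cfg = MPAConfig(n=2)
        ctx = make_ctx(2, 1, RB=0.5, RL=0.5, R=0.5, CF=0.25)
        out = phase2_update(prey, elite, ctx, cfg)
        # first half (Levy prey): step = 0.5*(2 - 0.5*1) = 0.75
        #   new = 1 + 0.5*0.5*0.75 = 1.1875
        # second half (Brownian predator): step = 0.5*(2 - 3) = -0.5
        #   new = 2 + 0.5*0.25*(-0.5) = 1.9375
        np.testing.assert_allclose(out, [[1.1875], [1.9375]])

    def test_phase2_zero_levy_keeps_first_half(self):
        prey = np.array([[1.0], [2.0], [3.0]])
        ctx = make_ctx(3, 1, RL=0.0, RB=0.0, R=1.0, CF=0.5)
        out = phase2_update(prey, np.array([9.0]), ctx, MPAConfig(n=3))
        np.testing.assert_array_equal(out[: _first_half(3)],
                                      prey[: _first_half(3)])

    def test_phase2_cf_zero_collapses_second_half_to_elite(self):
        prey = np.array([[1.0], [2.0], [3.0], [4.0]])
        ctx = make_ctx(4, 1, RB=0.7, CF=0.0)
        out = phase2_update(prey, np.array([-5.0]), ctx, MPAConfig(n=4))
        np.testing.assert_array_equal(out[2:], [[-5.0], [-5.0]])

    def test_phase3_cf_zero_collapses_population_to_elite(self):
        prey = np.arange(6.0).reshape(3, 2)
        ctx = make_ctx(3, 2, RL=0.9, CF=0.0)
        out = phase3_update(prey, np.array([1.0, -1.0]), ctx, MPAConfig(n=3))
        np.testing.assert_array_equal(out, np.tile([1.0, -1.0], (3, 1)))

    def test_phase3_worked_example_default_and_literal(self):
        prey = np.array([[1.0]])
        elite = np.array([2.0])
        ctx = make_ctx(1, 1, RL=0.5, CF=0.5)
        # default: step = 0.5*(0.5*2 - 1) = 0; new = elite
        out = phase3_update(prey, elite, ctx, MPAConfig(n=1))
        np.testing.assert_allclose(out, [[2.0]])
        # literal printed form: step = 0.5*(2-1) = 0.5; new = 2 + 0.5*0.5*0.5
        out_lit = phase3_update(prey, elite, ctx,
                                MPAConfig(n=1, eq11_literal=True))
        np.testing.assert_allclose(out_lit, [[2.125]])


class TestFads:
    def test_no_trigger_same_partner_is_identity(self):
        prey = np.array([[1.0], [2.0]])
        ctx = make_ctx(2, 1, r=0.9, r1=[0, 1], r2=[0, 1])
        out = fads_effect(prey, SPACE1, ctx, MPAConfig(n=2))
        np.testing.assert_array_equal(out, prey)

    def test_trigger_with_zero_mask_is_identity(self):
        prey = np.array([[1.0], [2.0]])
        ctx = make_ctx(2, 1, r=0.0, U=0.0, R_fads=0.5)
        out = fads_effect(prey, SPACE1, ctx, MPAConfig(n=2))
        np.testing.assert_array_equal(out, prey)

    def test_positions_stay_in_bounds_after_clamp(self):
        space = SearchSpace(lb=[-2.0, 0.0], ub=[2.0, 1.0])
        rng = np.random.default_rng(8)
        cfg = MPAConfig(n=100, Imax=10)
        prey = init_population(space, cfg, rng)
        for _ in range(100):
            ctx = StepContext.draw(100, 2, 0.5, cfg, rng)
            moved = space.clamp(fads_effect(prey, space, ctx, cfg))
            assert np.all(moved >= space.lb) and np.all(moved <= space.ub)
            prey = moved


class TestOptimize:
    def test_phase_schedule_partitions_iterations(self):
        for imax in [1, 2, 3, 4, 5, 9, 10, 300]:
            phases = [_phase_of(i, imax) for i in range(imax)]
            assert len(phases) == imax
            assert all(p in (1, 2, 3) for p in phases)
            assert phases == sorted(phases)  # phases only move forward
            assert phases[: imax // 3] == [1] * (imax // 3)
            assert phases[(2 * imax) // 3:] == [3] * (imax - (2 * imax) // 3)

    def test_imax_zero_returns_best_initial_member(self):
        space = SearchSpace(lb=[-4.0] * 3, ub=[4.0] * 3)
        cfg = MPAConfig(n=12, Imax=0, seed=2)
        sphere = lambda x: float(np.sum(x * x))
        res = optimize(sphere, space, cfg)
        pop = init_population(space, cfg)
        assert res.best_f == pytest.approx(min(sphere(x) for x in pop))
        assert res.evals == 12 and len(res.history) == 1

    def test_history_nonincreasing_and_bounds_respected(self):
        space = SearchSpace(lb=[-5.0] * 4, ub=[5.0] * 4)
        seen = []
        def f(x):
            seen.append(x.copy())
            return float(np.sum(np.abs(x)))
        res = optimize(f, space, MPAConfig(n=8, Imax=40, seed=1))
        assert np.all(np.diff(res.history) <= 0)
        assert res.best_f == res.history[-1]
        seen = np.array(seen)
        assert np.all(seen >= space.lb - 1e-12)
        assert np.all(seen <= space.ub + 1e-12)
        assert res.evals == len(seen) == 8 * 41

    def test_reproducible_per_seed(self):
        space = SearchSpace(lb=[-5.0] * 3, ub=[5.0] * 3)
        f = lambda x: float(np.sum(x * x))
        a = optimize(f, space, MPAConfig(n=6, Imax=30, seed=9))
        b = optimize(f, space, MPAConfig(n=6, Imax=30, seed=9))
        np.testing.assert_array_equal(a.best_x, b.best_x)
        np.testing.assert_array_equal(a.history, b.history)

    def test_degenerate_single_agent_single_dim(self):
        res = optimize(lambda x: float(x[0] ** 2), SPACE1,
                       MPAConfig(n=1, Imax=12, seed=4))
        assert np.all(np.diff(res.history) <= 0)
        assert -10.0 <= res.best_x[0] <= 10.0

    def test_nonfinite_fitness_raises_naming_candidate(self):
        with pytest.raises(ValueError, match="non-finite"):
            optimize(lambda x: float("nan"), SPACE1, MPAConfig(n=2, Imax=1))

    def test_beats_objective_floor_on_sphere(self):
        bench = benchmark_objective("sphere", 6)
        space = SearchSpace(lb=bench.lb, ub=bench.ub)
        res = optimize(bench.fn, space, MPAConfig(n=20, Imax=150, seed=0))
        assert res.best_f < 1e-3


class TestFitness:
    def test_error_rate_percent_arithmetic(self):
        y = np.arange(100) % 5
        pred = y.copy()
        pred[:3] = (pred[:3] + 1) % 5
        assert error_rate(y, pred) == pytest.approx(3.0)
        assert error_rate(y, y) == 0.0
        ten = np.zeros(10, dtype=int)
        assert error_rate(ten, ten + 1) == pytest.approx(100.0)

    def test_decoding_contract_never_degenerate(self):
        space = hyperparameter_space()
        for x in (space.lb, space.ub, (space.lb + space.ub) / 2):
            hp = decode_candidate(x)
            assert hp["hidden"][0] >= 8 and hp["hidden"][1] >= 8
            assert 1 <= hp["cd_k"] <= 5
            assert 1e-4 <= hp["rbm_lr"] <= 1e-1
            assert hp["finetune_epochs"] >= 5
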