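"""Unit and property tests for the SO / PSO / PSSO optimizer core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snakeswarm.swarm import (
    ALGORITHMS,
    BoundsSpec,
    OptimizerConfig,
    behavior_coefficient,
    environment,
    init_population,
    optimize,
    pso_update,
    so_move,
)


class TestBounds:
    def test_rejects_inverted_bounds(self):
        with pytest.raises(ValueError):
            BoundsSpec(np.array([1.0]), np.array([1.0]))

    def test_cube_shape(self):
        b = BoundsSpec.cube(1, 100, 5)
        assert b.dim == 5 and np.all(b.span == 99.0)


class TestEnvironment:
    def test_closed_forms_at_endpoints(self, small_config):
        cfg = small_config
        q0, temp0 = environment(0, 50, cfg)
        qT, tempT = environment(50, 50, cfg)
        assert temp0 == pytest.approx(1.0, abs=1e-12)
        assert qT == pytest.approx(cfg.k1, abs=1e-12)
        # independent high-precision evaluation of the closed forms
        assert q0 == pytest.approx(0.5 * np.exp(-1.0), abs=1e-12)
        assert tempT == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_monotone_in_iteration(self, small_config):
        qs, temps = zip(*(environment(c, 50, small_config) for c in range(51)))
        assert np.all(np.diff(qs) > 0)
        assert np.all(np.diff(temps) < 0)

    def test_zero_total_iterations_rejected(self, small_config):
        with pytest.raises(ValueError):
            environment(0, 0, small_config)


class TestBehaviorCoefficient:
    @pytest.mark.parametrize(
        "f_ref,f_self,expected",
        [(0.0, 1.0, 1.0), (1.0, 1.0, np.exp(-1)), (2.0, 1.0, np.exp(-2))],
    )
    def test_known_values(self, small_config, f_ref, f_self, expected):
        for kind in ("forage", "fight", "mate"):
            assert behavior_coefficient(kind, f_ref, f_self, small_config) == pytest.approx(
                expected, rel=1e-12
            )

    def test_nonfinite_rejected(self, small_config):
        with pytest.raises(ValueError):
            behavior_coefficient("fight", np.nan, 1.0, small_config)

    def test_unknown_kind_rejected(self, small_config):
        with pytest.raises(ValueError):
            behavior_coefficient("dance", 1.0, 1.0, small_config)


class TestInitPopulation:
    def test_roles_and_containment(self, sphere):
        bounds = BoundsSpec.cube(1, 100, 3)
        state = init_population(bounds, OptimizerConfig(n_pop=10, seed=1), sphere)
        assert len(state.males()) == 5 and len(state.females()) == 5
        for c in state.candidates:
            assert np.all(c.position >= 1) and np.all(c.position <= 100)

    def test_odd_population_floor_rule(self, sphere):
        state = init_population(
            BoundsSpec.cube(1, 100, 2), OptimizerConfig(n_pop=11, seed=0), sphere
        )
        assert len(state.males()) == 5 and len(state.females()) == 6

    def test_constant_objective_all_tied(self):
        state = init_population(
            BoundsSpec.cube(0, 1, 2), OptimizerConfig(n_pop=6, seed=0), lambda x: 7.0
        )
        assert state.food_fitness == 7.0
        assert all(c.fitness == 7.0 for c in state.candidates)

    def test_nonfinite_objective_signalled(self):
        with pytest.raises(ValueError, match="invalid-objective"):
            init_population(
                BoundsSpec.cube(0, 1, 2), OptimizerConfig(n_pop=4, seed=0), lambda x: np.nan
            )


class TestHandWorkedMoves:
    def test_food_following_step(self):
        # hot mode: new = L_food + sign*K3*Temp*R*(L_food - x)
        l_food, x, temp, r, k3 = 50.0, 40.0, 0.8, 0.5, 2.0
        assert l_food + k3 * temp * r * (l_food - x) == pytest.approx(58.0)

    def test_exploration_step(self):
        # exploration: new = S_R + sign*K2*AB*((hi-lo)*R + lo)
        s_r, ab, r, k2 = 10.0, 1.0, 0.5, 0.05
        assert s_r + k2 * ab * ((100 - 1) * r + 1) == pytest.approx(12.525)

    def test_replacement_endpoints(self):
        lo, hi = 1.0, 100.0
        assert lo + 0.0 * (hi - lo) == lo
        assert lo + 1.0 * (hi - lo) == hi


class TestPsoUpdate:
    def test_hand_worked_velocity(self, small_config):
        # w*V + C1*r1*(P-X) + C2*r2*(G-X) with r1=r2=1 = 0.5 + 0.8 + 1.8
        v = 0.5 * 1.0 + 0.8 * 1.0 * (1.0 - 0.0) + 0.9 * 1.0 * (2.0 - 0.0)
        assert v == pytest.approx(3.1)

    def test_fixed_point(self, small_config):
        from snakeswarm.swarm import Candidate

        x = np.array([3.0])
        cand = Candidate(
            position=x.copy(), velocity=np.zeros(1), fitness=0.0,
            personal_best_position=x.copy(), personal_best_fitness=0.0, role="male",
        )
        rng = np.random.default_rng(0)
        out = pso_update(
            cand, x.copy(), BoundsSpec.cube(1, 100, 1), small_config, rng,
            lambda p: float((p[0] - 3) ** 2),
        )
        assert np.array_equal(out.position, x)
        assert np.array_equal(out.velocity, np.zeros(1))

    def test_velocity_clamp(self, small_config):
        from snakeswarm.swarm import Candidate

        bounds = BoundsSpec.cube(1, 100, 1)
        cand = Candidate(
            position=np.array([1.0]), velocity=np.array([500.0]), fitness=0.0,
            personal_best_position=np.array([100.0]), personal_best_fitness=0.0,
            role="male",
        )
        rng = np.random.default_rng(0)
        out = pso_update(cand, np.array([100.0]), bounds, small_config, rng, lambda p: 0.0)
        assert abs(out.velocity[0]) <= 0.1 * 99.0 + 1e-12


class TestOptimize:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_trace_non_increasing_and_feasible(self, sphere, box10, algorithm):
        cfg = OptimizerConfig(n_pop=10, n_iter=30, seed=5)
        res = optimize(sphere, box10, cfg, algorithm)
        assert len(res.trace) == 30
        assert np.all(np.diff(res.trace) <= 0)
        assert res.best_fitness == res.trace[-1]
        assert np.all(res.best_position >= -5) and np.all(res.best_position <= 5)

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_deterministic_given_seed(self, sphere, box10, algorithm):
        cfg = OptimizerConfig(n_pop=8, n_iter=15, seed=11)
        r1 = optimize(sphere, box10, cfg, algorithm)
        r2 = optimize(sphere, box10, cfg, algorithm)
        assert np.array_equal(r1.trace, r2.trace)
        assert np.array_equal(r1.best_position, r2.best_position)

    def test_constant_objective_flat_trace(self, box10):
        res = optimize(lambda x: 4.2, box10, OptimizerConfig(n_pop=6, n_iter=10, seed=0))
        assert res.best_fitness == 4.2
        assert np.all(np.asarray(res.trace) == 4.2)

    def test_unknown_algorithm_rejected(self, sphere, box10, small_config):
        with pytest.raises(ValueError, match="invalid-algorithm"):
            optimize(sphere, box10, small_config, "annealing")

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_quadratic_recovery_rate(self, algorithm):
        bounds = BoundsSpec.cube(1, 100, 1)
        hits = 0
        for seed in range(20):
            cfg = OptimizerConfig(n_pop=10, n_iter=50, seed=seed)
            res = optimize(lambda x: float((x[0] - 3.0) ** 2), bounds, cfg, algorithm)
            hits += abs(res.best_position[0] - 3.0) < 0.1
        assert hits >= 18

    def test_trace_export_roundtrip(self, sphere, box10, small_config):
        import json

        res = optimize(sphere, box10, small_config)
        csv = res.trace_csv()
        assert csv.splitlines()[0] == "iteration,best_fitness"
        assert len(csv.splitlines()) == small_config.n_iter + 1
        payload = json.loads(res.to_json())
        assert payload["best_fitness"] == res.best_fitness


class TestReduction:
    def test_psso_with_zero_snake_term_is_pso(self, box10):
        """With the snake displacement scaled to zero and shared named RNG
        streams, hybrid iterations are bit-identical to plain PSO."""
        rng = np.random.default_rng(99)
        for trial in range(5):
            shift = rng.normal(size=10)

            def objective(x, shift=shift):
                return float(np.sum((x - shift) ** 2))

            base = OptimizerConfig(n_pop=8, n_iter=12, seed=trial)
            r_pso = optimize(objective, box10, base, "pso")
            r_hyb = optimize(
                objective, box10,
                OptimizerConfig(n_pop=8, n_iter=12, seed=trial, so_weight=0.0),
                "psso",
            )
            assert np.array_equal(r_pso.trace, r_hyb.trace)
            assert np.array_equal(r_pso.best_position, r_hyb.best_position)


class TestSoMove:
    def test_iteration_advances_and_stays_feasible(self, sphere):
        bounds = BoundsSpec.cube(-5, 5, 4)
        cfg = OptimizerConfig(n_pop=10, n_iter=50, seed=3)
        state = init_population(bounds, cfg, sphere)
        for _ in range(10):
            before = state.food_fitness
            so_move(state, bounds, cfg, sphere)
            assert state.food_fitness <= before
            for c in state.candidates:
                assert np.all(c.position >= -5) and np.all(c.position <= 5)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_pop=st.integers(4, 16))
def test_elitism_property(seed, n_pop):
    """Best-so-far never worsens for any seed or population size."""
    obj = lambda x: float(np.sum(np.abs(x)))
    res = optimize(
        obj, BoundsSpec.cube(-3, 3, 3),
        OptimizerConfig(n_pop=n_pop, n_iter=10, seed=seed), "psso",
    )
    assert np.all(np.diff(res.trace) <= 0)
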