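"""Optimizer unit tests, including a literal dual implementation of the
producer/scrounger/scout update rules used as an independent oracle."""

import copy
import math

import numpy as np
import pytest

from mitfopt import ssa
from mitfopt.ssa import (
    SSAConfig,
    SSAEvaluationError,
    assign_roles,
    init_population,
    optimize,
    random_search,
    sphere,
    update_producers,
    update_scouts,
    update_scroungers,
)

# ---------------------------------------------------------------------------
# Independent line-by-line transcriptions of the three update rules.  They
# draw random scalars in the same documented order as the implementation
# (R2 per call; alpha or Q per producer; Q or r-vector per scrounger;
# beta or K per scout) but share no code with it.
# ---------------------------------------------------------------------------


def oracle_producers(X, ST, itermax, n1, rng):
    X = X.copy()
    d = X.shape[1]
    R2 = rng.uniform()
    for i in range(1, n1 + 1):
        if R2 < ST:
            alpha = 1.0 - rng.uniform()
            for j in range(d):
                X[i - 1, j] = X[i - 1, j] * math.exp(-i / (alpha * itermax))
        else:
            Q = rng.standard_normal()
            for j in range(d):
                X[i - 1, j] = X[i - 1, j] + Q * 1.0
    for i in range(n1):
        for j in range(d):
            X[i, j] = min(max(X[i, j], 0.0), 1.0)
    return X


def oracle_scroungers(X, Xworst, n1, rng):
    X = X.copy()
    d = X.shape[1]
    n2 = X.shape[0] - n1
    xbest = X[0]  # best producer, already updated
    for i in range(1, n2 + 1):
        row = n1 + i - 1
        if i > n2 / 2.0:
            Q = rng.standard_normal()
            for j in range(d):
                X[row, j] = Q * math.exp((Xworst[j] - X[row, j]) / i**2)
        else:
            r = rng.uniform(-1.0, 1.0, size=d)
            s = 0.0
            for j in range(d):
                s += r[j] * abs(X[row, j] - xbest[j])
            s /= d
            for j in range(d):
                X[row, j] = xbest[j] + s
    for row in range(n1, X.shape[0]):
        for j in range(d):
            X[row, j] = min(max(X[row, j], 0.0), 1.0)
    return X


def oracle_scouts(X, F, scout_idx, Xbest, Xworst, fg, fw, rng, eps=1e-10):
    X = X.copy()
    d = X.shape[1]
    for row in scout_idx:
        fi = F[row]
        if fi != fg:
            beta = rng.standard_normal()
            for j in range(d):
                X[row, j] = Xbest[j] + beta * (X[row, j] - Xbest[j])
        else:
            K = rng.uniform(-1.0, 1.0)
            for j in range(d):
                X[row, j] = X[row, j] + K * (X[row, j] - Xworst[j]) / ((fi - fw) + eps)
        for j in range(d):
            X[row, j] = min(max(X[row, j], 0.0), 1.0)
    return X


def prepared_population(seed, config=None):
    config = config or SSAConfig(seed=seed)
    rng = np.random.default_rng(seed)
    pop = init_population(config, d=4, rng=rng)
    for i in range(pop.n):
        pop.F[i] = sphere(pop.X[i])
    assign_roles(pop, config, rng)
    return pop, config


class TestDualImplementation:
    @pytest.mark.parametrize("seed", range(10))
    def test_producer_update_matches_oracle(self, seed):
        pop, config = prepared_population(seed)
        ref = oracle_producers(
            pop.X, pop.ST, config.itermax, config.n_producers, np.random.default_rng(seed + 100)
        )
        update_producers(pop, config, np.random.default_rng(seed + 100))
        np.testing.assert_allclose(pop.X, ref, atol=1e-12, rtol=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_scrounger_update_matches_oracle(self, seed):
        pop, config = prepared_population(seed)
        update_producers(pop, config, np.random.default_rng(seed + 100))
        ref = oracle_scroungers(
            pop.X, pop.Xworst, config.n_producers, np.random.default_rng(seed + 200)
        )
        update_scroungers(pop, config, np.random.default_rng(seed + 200))
        np.testing.assert_allclose(pop.X, ref, atol=1e-12, rtol=0)

    @pytest.mark.parametrize("seed", range(10))
    def test_scout_update_matches_oracle(self, seed):
        pop, config = prepared_population(seed)
        ref = oracle_scouts(
            pop.X, pop.F, pop.scout_idx, pop.Xbest, pop.Xworst, pop.fg, pop.fw,
            np.random.default_rng(seed + 300),
        )
        update_scouts(pop, config, np.random.default_rng(seed + 300))
        np.testing.assert_allclose(pop.X, ref, atol=1e-12, rtol=0)


class TestClosedForms:
    def test_producer_contraction_branch_shrinks_positions(self):
        pop, config = prepared_population(0)
        pop.ST = 1.0  # forces the R2 < ST (no-alarm) branch
        before = pop.X[: config.n_producers].copy()
        update_producers(pop, config, np.random.default_rng(0))
        assert np.all(pop.X[: config.n_producers] <= before + 1e-15)
        assert np.all(pop.X[: config.n_producers] >= 0.0)

    def test_scrounger_at_best_stays_at_best(self):
        pop, config = prepared_population(1)
        update_producers(pop, config, np.random.default_rng(1))
        xbest = pop.X[0].copy()
        pop.X[config.n_producers] = xbest  # scrounger rank 1 <= n2/2
        update_scroungers(pop, config, np.random.default_rng(1))
        np.testing.assert_allclose(pop.X[config.n_producers], xbest, atol=1e-15)

    def test_scrounger_at_worst_becomes_constant_vector(self):
        pop, config = prepared_population(2)
        update_producers(pop, config, np.random.default_rng(2))
        last = pop.n - 1  # highest scrounger rank: i > n2/2 branch
        pop.X[last] = pop.Xworst.copy()
        update_scroungers(pop, config, np.random.default_rng(2))
        # Q * exp(0) = Q on every component, then clipped
        assert np.unique(pop.X[last]).size == 1

    def test_scout_at_best_position_with_nonbest_fitness_stays(self):
        pop, config = prepared_population(3)
        row = int(pop.scout_idx[-1])
        if row == 0:
            row = int(pop.scout_idx[0])
        if row == 0:
            pytest.skip("both scouts are the best sparrow for this seed")
        pop.X[row] = pop.Xbest.copy()
        before = pop.X[row].copy()
        update_scouts(pop, config, np.random.default_rng(3))
        np.testing.assert_allclose(pop.X[row], before, atol=1e-15)

    def test_best_scout_at_worst_position_unchanged(self):
        pop, config = prepared_population(4)
        pop.scout_idx = np.array([0])  # the best sparrow (fi == fg)
        pop.Xworst = pop.X[0].copy()  # numerator (X - Xworst) vanishes
        before = pop.X[0].copy()
        update_scouts(pop, config, np.random.default_rng(4))
        np.testing.assert_allclose(pop.X[0], before, atol=1e-15)


class TestPopulation:
    def test_init_deterministic(self):
        config = SSAConfig(seed=5)
        a = init_population(config, d=4)
        b = init_population(config, d=4)
        np.testing.assert_array_equal(a.X, b.X)
        assert a.ST == b.ST

    def test_init_shape_and_box(self):
        pop = init_population(SSAConfig(n=10, seed=0), d=4)
        assert pop.X.shape == (10, 4)
        assert np.all((pop.X >= 0) & (pop.X <= 1))

    def test_init_uniform_mean(self):
        pop = init_population(SSAConfig(n=2500, seed=0), d=4)
        assert abs(pop.X.mean() - 0.5) < 0.02

    def test_role_counts_at_reference_settings(self):
        pop, config = prepared_population(0)
        assert (pop.roles == "producer").sum() == 7
        assert (pop.roles == "scrounger").sum() == 3
        assert len(pop.scout_idx) == 2

    def test_equal_fitness_ties_keep_index_order(self):
        config = SSAConfig(seed=0)
        rng = np.random.default_rng(0)
        pop = init_population(config, d=4, rng=rng)
        X0 = pop.X.copy()
        pop.F[:] = 0.5
        assign_roles(pop, config, rng)
        np.testing.assert_array_equal(pop.X, X0)  # stable sort

    def test_best_sparrow_is_producer(self):
        pop, _ = prepared_population(6)
        assert pop.roles[0] == "producer"
        assert pop.fg == pop.F.min()

    def test_roles_require_evaluated_fitness(self):
        pop = init_population(SSAConfig(seed=0), d=4)
        with pytest.raises(ValueError, match="fitness"):
            assign_roles(pop, SSAConfig(seed=0), np.random.default_rng(0))


class TestOptimize:
    def test_history_non_increasing_and_eval_count(self):
        for seed in range(5):
            res = optimize(sphere, SSAConfig(seed=seed), d=4)
            assert np.all(np.diff(res.history) <= 0)
            assert len(res.history) == 21
            assert res.n_evaluations == 10 * 21

    def test_constant_fitness_flat_history(self):
        res = optimize(lambda x: 0.25, SSAConfig(seed=0), d=4)
        assert np.all(res.history == 0.25)
        assert np.all((res.best_position >= 0) & (res.best_position <= 1))

    def test_positions_stay_in_box_throughout(self):
        seen = []

        def probe(x):
            seen.append(x.copy())
            return sphere(x)

        optimize(probe, SSAConfig(seed=3), d=4)
        seen = np.array(seen)
        assert np.all((seen >= 0.0) & (seen <= 1.0))

    def test_failure_annotated_with_context(self):
        calls = {"n": 0}

        def flaky(x):
            calls["n"] += 1
            if calls["n"] == 17:
                raise ValueError("boom")
            return sphere(x)

        with pytest.raises(SSAEvaluationError) as exc:
            optimize(flaky, SSAConfig(seed=0), d=4)
        assert exc.value.iteration == 1
        assert exc.value.index == 6

    def test_beats_random_search_on_sphere(self):
        wins = 0
        for seed in range(5):
            res = optimize(sphere, SSAConfig(seed=seed), d=4)
            base = random_search(sphere, n_evals=200, d=4, seed=seed)
            wins += res.best_fitness < base.best_fitness
        assert wins >= 4
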