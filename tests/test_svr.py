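"""ε-SVR with the Tanimoto kernel: fit contract, metrics, sweep protocol."""

import numpy as np
import pytest

from svrsar.errors import ConfigError, ValidationError
from svrsar.similarity import pairwise_matrix
from svrsar.svr import (
    SvrConfig,
    SvrModel,
    SweepResult,
    eps_insensitive_abs_error,
    fit_svr,
    make_splits,
    mean_abs_error,
    predict,
    r_squared,
    run_trials,
    select_best_c,
    sweep,
    tanimoto_kernel_matrix,
)


def _fps(rng, n, universe=64, lo=5, hi=20):
    X = np.zeros((n, universe), dtype=bool)
    for i in range(n):
        X[i, rng.choice(universe, size=rng.integers(lo, hi), replace=False)] = True
    return X


class TestFit:
    def test_constant_targets_inside_tube(self, rng):
        X = _fps(rng, 10)
        y = np.full(10, 7.3)
        m = fit_svr(X, y, C=10.0, epsilon=0.1)
        assert np.all(np.abs(predict(m, X) - 7.3) <= 0.1 + 1e-9)

    def test_disjoint_fingerprints_identity_kernel(self):
        # kernel = I: the dual solution can place both predictions on the
        # tube boundary at negligible norm cost, so with a large C both
        # training predictions land within epsilon of their targets
        X = np.zeros((2, 8), dtype=bool)
        X[0, :4] = True
        X[1, 4:] = True
        y = np.array([5.0, 9.0])
        m = fit_svr(X, y, C=1000.0, epsilon=0.1)
        assert np.all(np.abs(predict(m, X) - y) <= 0.1 + 1e-6)

    def test_dual_box_constraint(self, rng):
        X = _fps(rng, 40)
        y = rng.uniform(5, 10, size=40)
        for C in (1.0, 5.0, 50.0):
            m = fit_svr(X, y, C=C, epsilon=0.1)
            assert np.all(np.abs(m.dual_coeffs) <= C + 1e-8)

    def test_points_inside_tube_have_zero_dual(self, rng):
        X = _fps(rng, 60)
        y = rng.uniform(5, 10, size=60)
        m = fit_svr(X, y, C=5.0, epsilon=0.1)
        resid = np.abs(predict(m, X) - y)
        duals = np.zeros(60)
        duals[m.support_indices] = m.dual_coeffs
        assert np.all(np.abs(duals[resid < 0.1 - 1e-6]) <= 1e-6)

    def test_invalid_inputs_rejected(self, rng):
        X = _fps(rng, 4)
        with pytest.raises(ValidationError):
            fit_svr(X, np.ones(3), C=1.0)
        with pytest.raises(ConfigError):
            fit_svr(X, np.ones(4) * 6, C=0.0)


class TestPredict:
    def test_self_consistency_with_precomputed_path(self, cliff_dataset):
        cfg = SvrConfig(c_grid=(5.0,), n_trials=2, seed=0)
        trials = run_trials(cliff_dataset, 5.0, cfg)
        X = cliff_dataset.fingerprint_matrix()
        for t in trials:
            again = predict(t.model, X[t.train_indices])
            assert np.allclose(again, t.train_predictions, atol=1e-10)

    def test_zero_duals_constant_intercept(self, rng):
        X = _fps(rng, 5)
        m = SvrModel(
            dual_coeffs=np.array([]),
            intercept=6.5,
            support_indices=np.array([], dtype=int),
            train_fingerprints=X,
            C=1.0,
            epsilon=0.1,
        )
        assert np.allclose(predict(m, X), 6.5)

    def test_hand_built_two_support_vector_model(self):
        train = np.zeros((2, 6), dtype=bool)
        train[0, :3] = True
        train[1, 3:] = True
        m = SvrModel(
            dual_coeffs=np.array([2.0, -1.0]),
            intercept=0.5,
            support_indices=np.array([0, 1]),
            train_fingerprints=train,
            C=10.0,
            epsilon=0.1,
        )
        x = np.zeros((1, 6), dtype=bool)
        x[0, [0, 1, 3]] = True
        # Tc(x, sv0) = 2/4, Tc(x, sv1) = 1/5 -> 2*0.5 - 1*0.2 + 0.5
        assert predict(m, x)[0] == pytest.approx(1.3, abs=1e-12)

    def test_universe_mismatch_rejected(self, rng):
        X = _fps(rng, 4)
        m = fit_svr(X, np.array([5, 6, 7, 8.0]), C=1.0)
        with pytest.raises(ValidationError):
            predict(m, np.zeros((2, 32), dtype=bool))


class TestErrorMetrics:
    def test_inside_tube_costs_nothing(self):
        assert eps_insensitive_abs_error([5.0], [5.05], 0.1) == 0.0

    def test_hand_summed_value(self):
        assert eps_insensitive_abs_error([5.0, 7.0], [5.5, 6.0], 0.1) == pytest.approx(
            1.3, abs=1e-12
        )

    def test_zero_epsilon_is_l1(self, rng):
        y = rng.uniform(5, 10, size=50)
        p = y + rng.normal(0, 1, size=50)
        oracle = sum(abs(a - b) for a, b in zip(y, p))
        assert eps_insensitive_abs_error(y, p, 0.0) == pytest.approx(oracle, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            eps_insensitive_abs_error([1.0], [1.0, 2.0], 0.1)

    def test_mean_error_divides_by_n(self):
        assert mean_abs_error([5.0, 7.0], [5.5, 6.0], 0.1) == pytest.approx(0.65)
        assert mean_abs_error([5.0, 7.0], [5.0, 7.0], 0.1) == 0.0

    def test_mean_error_duplication_invariant(self, rng):
        y = rng.uniform(5, 10, size=20)
        p = y + rng.normal(0, 0.5, size=20)
        single = mean_abs_error(y, p, 0.1)
        doubled = mean_abs_error(np.tile(y, 2), np.tile(p, 2), 0.1)
        assert doubled == pytest.approx(single, abs=1e-12)


class TestRSquared:
    def test_perfect_and_constant_predictions(self):
        y = np.array([5, 6, 7, 8.0])
        assert r_squared(y, y) == 1.0
        assert r_squared(y, np.full(4, y.mean())) == pytest.approx(0.0)

    def test_hand_computed_ss_ratio(self):
        # SS_res = 4 * 0.25 = 1.0, SS_tot = 5.0 -> 0.8
        y = np.array([5, 6, 7, 8.0])
        pred = np.array([5.5, 5.5, 7.5, 7.5])
        assert r_squared(y, pred) == pytest.approx(0.8, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            r_squared([5.0, 5.0], [5.0, 5.1])


class TestTrialsAndSweep:
    def test_splits_partition_and_sizes(self, cliff_dataset):
        n = len(cliff_dataset)
        for train, test in make_splits(n, 5, 0.5, seed=3):
            assert len(train) == n // 2 and len(test) == n - n // 2
            assert np.array_equal(np.sort(np.concatenate([train, test])), np.arange(n))
            assert np.intersect1d(train, test).size == 0

    def test_trials_deterministic_under_seed(self, cliff_dataset):
        cfg = SvrConfig(c_grid=(5.0,), n_trials=3, seed=42)
        t1 = run_trials(cliff_dataset, 5.0, cfg)
        t2 = run_trials(cliff_dataset, 5.0, cfg)
        for a, b in zip(t1, t2):
            assert np.array_equal(a.train_indices, b.train_indices)
            assert np.array_equal(a.test_predictions, b.test_predictions)

    def test_sweep_bookkeeping_and_determinism(self, cliff_dataset):
        cfg = SvrConfig(c_grid=(1.0, 10.0), n_trials=3, seed=1)
        s1 = sweep(cliff_dataset, cfg)
        s2 = sweep(cliff_dataset, cfg)
        assert s1.c_values == (1.0, 10.0)
        assert s1.mean_test_errors.shape == (2,)
        assert np.array_equal(s1.mean_test_errors, s2.mean_test_errors)
        assert np.array_equal(s1.mean_train_errors, s2.mean_train_errors)

    def test_weaker_regularization_lowers_training_error(self, cliff_dataset):
        sim = pairwise_matrix(cliff_dataset)
        splits = make_splits(len(cliff_dataset), 1, 0.5, seed=2)
        cfg = SvrConfig(c_grid=(1.0,), n_trials=1, seed=2)
        errs = []
        for C in (1.0, 1000.0):
            (t,) = run_trials(cliff_dataset, C, cfg, splits=splits, sim_matrix=sim)
            errs.append(t.train_eps_error)
        assert errs[1] <= errs[0] + 1e-6

    def test_sweep_reuses_one_split_family_across_c(self, cliff_dataset):
        cfg = SvrConfig(c_grid=(1.0, 5.0), n_trials=2, seed=7)
        s = sweep(cliff_dataset, cfg, keep_trials=True)
        for a, b in zip(s.trials[1.0], s.trials[5.0]):
            assert np.array_equal(a.train_indices, b.train_indices)
            assert np.array_equal(a.test_indices, b.test_indices)


class TestBestC:
    def _sweep(self, cs, errs):
        k = len(cs)
        return SweepResult(
            c_values=tuple(cs),
            mean_train_errors=np.zeros(k),
            sd_train_errors=np.zeros(k),
            mean_test_errors=np.array(errs, dtype=float),
            sd_test_errors=np.zeros(k),
            n_trials=1,
        )

    def test_argmin_of_test_error(self):
        assert select_best_c(self._sweep([1, 2, 3], [0.5, 0.4, 0.45])) == 2

    def test_tie_breaks_toward_smallest_c(self):
        assert select_best_c(self._sweep([1, 2], [0.4, 0.4])) == 1

    def test_matches_loop_argmin(self, rng):
        cs = sorted(rng.choice(np.arange(1, 100), size=10, replace=False).tolist())
        errs = rng.uniform(0.1, 1.0, size=10)
        best, best_err = None, np.inf
        for c, e in zip(cs, errs):
            if e < best_err:
                best, best_err = c, e
        assert select_best_c(self._sweep(cs, errs)) == best

    def test_empty_sweep_rejected(self):
        with pytest.raises(ConfigError):
            SvrConfig(c_grid=())


def test_kernel_matrix_matches_pairwise(cliff_dataset):
    X = cliff_dataset.fingerprint_matrix()
    assert np.allclose(
        tanimoto_kernel_matrix(X, X), pairwise_matrix(cliff_dataset), atol=1e-12
    )
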