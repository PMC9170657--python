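"""Recursive KSVR core: one-shot load updates, incremental inverse,
importance scaling, pruning and prediction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroksvr import (KSVR, FitConfig, TriangularThetaKernel, direct_solve,
                       empirical_kernel, fit_batch)
from neuroksvr.ksvr import scaled_kernel_entry


def _random_instance(rng, kernel, p, t_max=100, channels=1, a_range=(1.0, 1.0)):
    times = np.sort(rng.choice(t_max, size=p, replace=False)).astype(float)
    targets = rng.standard_normal((p, channels))
    importances = rng.uniform(*a_range, size=p)
    return times, targets, importances


class TestInsertion:
    def test_first_sample_solves_1x1_system(self, theta_config):
        model = KSVR(theta_config)
        assert model.add_sample(3.0, 5.0)
        c = theta_config.kernel.self_value(3.0)
        assert model.store.loads[0, 0] == pytest.approx(5.0 / c)
        assert model.state.inv[0, 0] == pytest.approx(1.0 / c)

    def test_identity_gram_loads_equal_targets(self):
        kern = empirical_kernel(np.eye(3))
        model = KSVR(FitConfig(kern)).fit([0.0, 1.0], [2.0, 3.0])
        assert np.allclose(model.store.loads[:, 0], [2.0, 3.0])

    def test_non_finite_inputs_rejected(self, theta_config):
        model = KSVR(theta_config)
        with pytest.raises(ValueError):
            model.add_sample(np.nan, 1.0)
        with pytest.raises(ValueError):
            model.add_sample(0.0, np.inf)
        with pytest.raises(ValueError):
            model.add_sample(0.0, 1.0, importance=1.5)

    def test_duplicate_time_rejected_with_warning(self, theta_config, caplog):
        model = KSVR(theta_config)
        model.add_sample(0.0, 1.0)
        with caplog.at_level("WARNING", logger="neuroksvr"):
            assert not model.add_sample(0.0, 2.0)
        assert "rejected" in caplog.text
        assert model.n_samples == 1
        assert model.store.targets[0, 0] == 1.0  # no overwrite

    def test_zero_importance_sample_is_inert(self, theta_config, rng):
        times, targets, _ = _random_instance(rng, theta_config.kernel, 6)
        model = fit_batch(times, targets, config=theta_config)
        grid = np.arange(0, 100, dtype=float)
        before = model.predict(grid)
        assert not model.add_sample(55.5, 7.0, importance=0.0)
        assert np.array_equal(model.predict(grid), before)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    @pytest.mark.parametrize("p", [1, 5, 20])
    def test_recursion_matches_dense_solve(self, theta_kernel, seed, p):
        rng = np.random.default_rng(seed)
        times, targets, importances = _random_instance(
            rng, theta_kernel, p, a_range=(0.5, 1.0))
        model = fit_batch(times, targets, importances,
                          config=FitConfig(theta_kernel))
        u = direct_solve(model.scaled_kernel_matrix(), targets)
        assert np.abs(model.store.loads - u).max() < 1e-8

    def test_direct_solve_identity_and_scalar(self):
        assert np.allclose(direct_solve(np.eye(3), np.arange(3.0)), np.arange(3.0))
        assert direct_solve(np.array([[4.0]]), np.array([2.0]))[0] == pytest.approx(0.5)
        with pytest.raises(np.linalg.LinAlgError):
            direct_solve(np.zeros((2, 2)), np.ones(2))


class TestScaledKernel:
    def test_entries(self, theta_kernel, rng):
        times, targets, importances = _random_instance(
            rng, theta_kernel, 4, a_range=(0.2, 0.9))
        model = fit_batch(times, targets, importances,
                          config=FitConfig(theta_kernel))
        s, k = model.store, theta_kernel
        assert scaled_kernel_entry(s, k, 0, 1) == pytest.approx(
            k.evaluate(s.times[0], s.times[1]) * s.importances[0] * s.importances[1])
        assert scaled_kernel_entry(s, k, 1, 0) == pytest.approx(
            scaled_kernel_entry(s, k, 0, 1))


class TestPrediction:
    def test_single_sample_self_and_far_retrieval(self, theta_config):
        model = KSVR(theta_config).fit([10.0], [4.0])
        assert model.predict(10.0) == pytest.approx(4.0)
        # beyond the kernel length only the chance-overlap pedestal remains
        assert model.predict(40.0) == pytest.approx(4.0 * 100.0 / 1090.0)

    def test_empty_store_predicts_zero(self, theta_config):
        model = KSVR(theta_config)
        assert model.predict(1.0) == 0.0
        assert np.array_equal(model.predict(np.arange(3.0)), np.zeros(3))

    def test_multichannel_shares_one_inverse(self, theta_config, rng):
        times, targets, importances = _random_instance(
            rng, theta_config.kernel, 7, channels=3, a_range=(0.6, 1.0))
        joint = fit_batch(times, targets, importances, config=theta_config)
        grid = np.linspace(0, 99, 40)
        for c in range(3):
            single = fit_batch(times, targets[:, c], importances,
                               config=theta_config)
            assert np.abs(joint.predict(grid)[:, c]
                          - single.predict(grid)).max() < 1e-10


class TestExactRecoveryAndOrder:
    def test_lowpass_signal_recovered_at_all_points(self, theta_config, rng):
        from neuroksvr import lowpass_noise
        signal = lowpass_noise(100, 50, seed=7)
        times = np.arange(100, dtype=float)
        model = fit_batch(times, signal, config=theta_config)
        err = np.abs(model.predict(times) - signal).max()
        assert err < 1e-6 * np.abs(signal).max()

    def test_insertion_order_invariance(self, theta_config, rng):
        times, targets, importances = _random_instance(
            rng, theta_config.kernel, 30, a_range=(0.5, 1.0))
        ref = fit_batch(times, targets, importances, config=theta_config)
        perm = rng.permutation(30)
        other = fit_batch(times[perm], targets[perm], importances[perm],
                          config=theta_config)
        grid = np.linspace(0, 99, 200)
        scale = np.abs(ref.predict(grid)).max()
        assert np.abs(ref.predict(grid) - other.predict(grid)).max() < 1e-8 * scale

    def test_empty_fit(self, theta_config):
        model = fit_batch([], [], config=theta_config)
        assert model.n_samples == 0
        assert np.array_equal(model.predict(np.arange(4.0)), np.zeros(4))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 10_000), p=st.integers(1, 12))
    def test_property_exact_recovery_below_capacity(self, seed, p):
        """Below the cutoff, retrieval at stored times equals y/a."""
        rng = np.random.default_rng(seed)
        kern = TriangularThetaKernel(10_000, 10, 0.01)
        times = np.sort(rng.choice(200, size=p, replace=False)).astype(float)
        targets = rng.standard_normal(p)
        importances = rng.uniform(0.5, 1.0, size=p)
        model = fit_batch(times, targets, importances, config=FitConfig(kern))
        retrieved = np.atleast_1d(model.predict(times)) * importances
        assert np.abs(retrieved - targets).max() < 1e-6 * max(np.abs(targets).max(), 1.0)


class TestInverseConsistency:
    def test_residual_small_after_insertions_and_prunes(self, theta_kernel, rng):
        cfg = FitConfig(theta_kernel, cutoff_dimension=10)
        model = KSVR(cfg)
        times = rng.permutation(60)[:15].astype(float)
        for i, t in enumerate(times):
            model.add_sample(t, rng.standard_normal(),
                             importance=rng.uniform(0.3, 1.0))
            assert model.inverse_residual() < 1e-6
        assert model.n_samples == 10  # cutoff enforced


class TestPruning:
    def test_two_samples_keeps_high_importance(self, theta_config):
        model = KSVR(theta_config).fit([0.0, 30.0], [1.0, 2.0], [0.1, 0.9])
        removed = model.prune_lowest_importance()
        assert removed == 0
        fresh = KSVR(theta_config).fit([30.0], [2.0], [0.9])
        grid = np.linspace(0, 60, 50)
        assert np.allclose(model.predict(grid), fresh.predict(grid))

    def test_downdate_matches_dense_inversion(self, theta_kernel, rng):
        times, targets, importances = _random_instance(
            rng, theta_kernel, 6, a_range=(0.3, 1.0))
        model = fit_batch(times, targets, importances,
                          config=FitConfig(theta_kernel))
        model.prune_lowest_importance()
        dense = np.linalg.inv(model.scaled_kernel_matrix())
        assert np.abs(model.state.inv - dense).max() < 1e-8

    def test_equal_importances_removes_oldest(self, theta_config):
        model = KSVR(theta_config).fit([5.0, 17.0, 42.0], [1.0, 2.0, 3.0])
        model.prune_lowest_importance()
        assert 5.0 not in model.store.times
        assert model.n_samples == 2

    def test_prune_requires_two_samples(self, theta_config):
        model = KSVR(theta_config).fit([1.0], [1.0])
        with pytest.raises(ValueError):
            model.prune_lowest_importance()

    def test_cutoff_triggers_pruning_during_fit(self, theta_kernel, rng):
        cfg = FitConfig(theta_kernel, cutoff_dimension=5)
        times = np.arange(0, 40, 4, dtype=float)
        a = np.linspace(0.1, 1.0, times.size)
        model = fit_batch(times, rng.standard_normal(times.size), a, config=cfg)
        assert model.n_samples == 5
        # survivors are the highest-importance (latest) samples
        assert set(model.store.times) == set(times[-5:])


class TestSetImportance:
    def test_noop_change_preserves_predictions(self, theta_config, rng):
        times, targets, importances = _random_instance(
            rng, theta_config.kernel, 8, a_range=(0.4, 1.0))
        model = fit_batch(times, targets, importances, config=theta_config)
        grid = np.linspace(0, 99, 60)
        before = model.predict(grid)
        model.set_importance(3, importances[3])
        assert np.abs(model.predict(grid) - before).max() < 1e-10

    def test_out_of_range_rejected(self, theta_config):
        model = KSVR(theta_config).fit([0.0, 10.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            model.set_importance(0, 1.2)
        with pytest.raises(IndexError):
            model.set_importance(5, 0.5)

    def test_extinction_to_zero_removes_sample_first(self, theta_kernel, rng):
        """Setting a = 0 makes the sample the first one dropped from the fit."""
        cfg = FitConfig(theta_kernel, cutoff_dimension=300)
        times, targets, _ = _random_instance(rng, theta_kernel, 6)
        model = fit_batch(times, targets, config=cfg)
        victim = model.store.times[2]
        model.set_importance(2, 0.0)
        assert victim not in model.store.times
        assert model.n_samples == 5

    def test_consolidation_reduces_retrieval_error(self, theta_kernel):
        """Raising the importance of a pruned-away sample above the current
        minimum and refitting brings its retrieval back."""
        cfg = FitConfig(theta_kernel, cutoff_dimension=4)
        rng = np.random.default_rng(3)
        times = np.arange(0, 60, 10, dtype=float)  # 6 samples, cutoff 4
        targets = rng.standard_normal(6)
        a = np.array([0.2, 0.9, 0.85, 0.95, 0.8, 0.9])
        model = fit_batch(times, targets, a, config=cfg)
        assert times[0] not in model.store.times  # pruned
        err_before = abs(model.predict(times[0]) - targets[0])
        a2 = a.copy()
        a2[0] = 1.0  # consolidate
        model2 = fit_batch(times, targets, a2, config=cfg)
        err_after = abs(model2.predict(times[0]) * a2[0] - targets[0])
        assert times[0] in model2.store.times
        assert err_after < err_before


class TestSerialization:
    def test_csv_round_trip(self, theta_config, rng, tmp_path):
        times, targets, importances = _random_instance(
            rng, theta_config.kernel, 5, channels=2, a_range=(0.5, 1.0))
        model = fit_batch(times, targets, importances, config=theta_config)
        path = tmp_path / "model.csv"
        model.save_csv(path)
        loaded = KSVR.load_csv(path, theta_config)
        grid = np.linspace(0, 99, 30)
        assert np.abs(loaded.predict(grid) - model.predict(grid)).max() < 1e-10
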