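import numpy as np
import pytest
from scipy.optimize import differential_evolution as scipy_de

from targetclp.de_integration import (
    DEConfig,
    DEWeightIntegrator,
    cv_mcc_fitness,
    de_optimize,
    weighted_concat,
)
from targetclp.io_formats import FeatureTable
from targetclp.synthetic_data import SynthSpec, gen_multiview_dataset


def quadratic(w):
    return -np.sum((w - 0.5) ** 2)


class TestWeightedConcat:
    def test_identity_weights_are_serial_concatenation(self, rng):
        blocks = [rng.normal(size=(5, 3)), rng.normal(size=(5, 2))]
        out = weighted_concat(blocks, [1.0, 1.0])
        np.testing.assert_array_equal(out, np.concatenate(blocks, axis=1))

    def test_zero_weight_zeroes_block_but_keeps_width(self, rng):
        blocks = [rng.normal(size=(4, 3)), rng.normal(size=(4, 2))]
        out = weighted_concat(blocks, [0.0, 1.0])
        assert out.shape == (4, 5)
        assert (out[:, :3] == 0).all()

    def test_default_view_widths_total_1899(self, rng):
        blocks = [rng.normal(size=(2, d)) for d in (1280, 236, 147, 236)]
        assert weighted_concat(blocks, [1, 1, 1, 1]).shape == (2, 1899)

    def test_weight_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="weights"):
            weighted_concat([rng.normal(size=(2, 2))], [1.0, 2.0])


class TestDEOptimize:
    def test_recovers_separable_quadratic_optimum(self):
        res = de_optimize(quadratic, DEConfig(seed=42))
        assert np.abs(res.w_best - 0.5).max() < 0.01

    def test_agrees_with_scipy_on_quadratic(self):
        res = de_optimize(quadratic, DEConfig(seed=42))
        ref = scipy_de(lambda w: -quadratic(w), [(-2, 2)] * 4, seed=1, tol=1e-10)
        assert np.abs(res.w_best - ref.x).max() < 0.02

    @pytest.mark.parametrize("seed", range(10))
    def test_trace_non_decreasing(self, seed):
        res = de_optimize(quadratic, DEConfig(n_pop=12, max_gen=15, seed=seed))
        assert (np.diff(res.trace) >= 0).all()

    def test_all_candidates_within_bounds(self):
        seen = []

        def recording(w):
            seen.append(w.copy())
            return quadratic(w)

        de_optimize(recording, DEConfig(n_pop=10, max_gen=10, seed=5))
        seen = np.array(seen)
        assert (seen >= -2).all() and (seen <= 2).all()

    def test_degenerate_operators_change_single_coordinates(self):
        # F=0, CR=0: the mutant equals another member; the trial can differ
        # from its target only at the forced coordinate k_rand.
        seen = []

        def recording(w):
            seen.append(w.copy())
            return quadratic(w)

        cfg = DEConfig(n_pop=6, max_gen=4, cr=0.0, f=1e-12, seed=2)
        de_optimize(recording, cfg)
        for i in range(cfg.n_pop, len(seen)):
            prev = np.array(seen[:i])
            diffs = np.sum(~np.isclose(prev, seen[i], atol=1e-9), axis=1)
            assert diffs.min() <= 1

    def test_seed_reproducible(self):
        a = de_optimize(quadratic, DEConfig(n_pop=10, max_gen=10, seed=9))
        b = de_optimize(quadratic, DEConfig(n_pop=10, max_gen=10, seed=9))
        np.testing.assert_array_equal(a.w_best, b.w_best)
        np.testing.assert_array_equal(a.trace, b.trace)

    def test_population_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            DEConfig(n_pop=3)

    def test_non_finite_fitness_named(self):
        with pytest.raises(ValueError, match="non-finite"):
            de_optimize(lambda w: np.nan, DEConfig(n_pop=5, max_gen=1, seed=0))


def _two_view_table(shift, seed, n=40):
    spec = SynthSpec(
        n_sequences=n, block_names=("sig", "noise"), block_dims=(4, 6),
        informative={"sig": [0, 1, 2, 3]}, shift=shift, seed=seed,
    )
    return gen_multiview_dataset(spec)


class TestCvMccFitness:
    def test_separable_data_reaches_perfect_mcc(self):
        table = _two_view_table(shift=6.0, seed=1)
        assert cv_mcc_fitness(table, [1.0, 1.0], k=5, seed=0) == pytest.approx(1.0)

    def test_shuffled_labels_near_zero(self):
        vals = []
        for rep in range(5):
            table = _two_view_table(shift=6.0, seed=rep, n=60)
            rng = np.random.default_rng(rep)
            shuffled = FeatureTable(
                table.ids, list(table.block_names), list(table.block_dims),
                table.matrix, rng.permutation(table.labels),
            )
            vals.append(cv_mcc_fitness(shuffled, [1.0, 1.0], k=5, seed=0))
        assert abs(np.mean(vals)) < 0.15

    def test_deterministic(self):
        table = _two_view_table(shift=2.0, seed=3)
        a = cv_mcc_fitness(table, [0.7, -0.3], k=4, seed=5)
        b = cv_mcc_fitness(table, [0.7, -0.3], k=4, seed=5)
        assert a == b

    def test_unlabelled_table_rejected(self, rng):
        table = FeatureTable(["a", "b"], ["x"], [2], rng.normal(size=(2, 2)))
        with pytest.raises(ValueError, match="labels"):
            cv_mcc_fitness(table, [1.0], k=2)


class TestDEWeightIntegrator:
    def test_signal_view_weight_dominates_noise_views(self):
        wins = 0
        for seed in range(10):
            table = _two_view_table(shift=2.0, seed=100 + seed, n=60)
            integ = DEWeightIntegrator(
                block_dims=[4, 6], n_pop=12, max_gen=10, seed=seed, cv=3,
            ).fit(table.matrix, table.labels)
            w = np.abs(integ.weights_)
            if w[1] <= w[0]:
                wins += 1
        assert wins >= 8

    def test_transform_scales_blocks(self, rng):
        X = rng.normal(size=(6, 5))
        integ = DEWeightIntegrator(block_dims=[2, 3])
        integ.weights_ = np.array([2.0, -1.0])
        integ.n_features_in_ = 5
        out = integ.transform(X)
        np.testing.assert_allclose(out[:, :2], 2.0 * X[:, :2])
        np.testing.assert_allclose(out[:, 2:], -X[:, 2:])

    def test_sklearn_params_roundtrip(self):
        integ = DEWeightIntegrator(n_pop=8, seed=3)
        assert DEWeightIntegrator(**integ.get_params()).get_params() == integ.get_params()
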