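import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import Ridge

from stackenc.encoding import (
    _simplex_lstsq_batch,
    fit_ridge_cv,
    fit_stacked,
    make_folds,
    partition_unique_r2,
    clip_component_r2,
    preference_index,
    score_r2,
    simplex_grid_search,
    simplex_lstsq,
    stack_models,
)


class TestMakeFolds:
    def test_even_split(self):
        folds = make_folds(10, 5)
        assert all(len(f) == 2 for f in folds)

    def test_remainder_goes_to_early_folds(self):
        sizes = [len(f) for f in make_folds(11, 5)]
        assert sizes == [3, 2, 2, 2, 2]

    @pytest.mark.parametrize("n,k", [(10, 5), (11, 5), (100, 7), (5, 5)])
    def test_partition_contract(self, n, k):
        folds = make_folds(n, k)
        all_idx = np.concatenate(folds)
        assert len(all_idx) == n
        assert len(np.unique(all_idx)) == n

    def test_rejects_k_over_n(self):
        with pytest.raises(ValueError):
            make_folds(3, 5)


class TestScoreR2:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        assert score_r2(y, y) == pytest.approx(1.0)

    def test_mean_prediction_is_zero(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert score_r2(np.full(4, y.mean()), y) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = np.array([2.0, 2.0, 3.0, 3.0])
        assert score_r2(pred, obs) == pytest.approx(0.6)

    def test_constant_observed_flagged(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(score_r2(np.array([1.0, 2.0]), np.array([3.0, 3.0])))


class TestFitRidgeCV:
    def test_noiseless_recovery(self, rng):
        x = rng.standard_normal((400, 5))
        beta = rng.standard_normal(5)
        y = x @ beta
        fit = fit_ridge_cv(x, y, penalty_grid=np.array([1e-6]))
        assert fit.r2[0] >= 0.999

    def test_null_response_has_near_zero_r2(self, rng):
        # 100 independent null responses against one design: mean held-out
        # R^2 should sit at the no-information level.
        x = rng.standard_normal((500, 4))
        y = rng.standard_normal((500, 100))
        fit = fit_ridge_cv(x, y)
        assert np.mean(fit.r2) <= 0.02

    def test_infinite_shrinkage_predicts_training_mean(self, rng):
        x = rng.standard_normal((200, 3))
        y = x @ np.array([1.0, -1.0, 0.5]) + rng.standard_normal(200)
        fit = fit_ridge_cv(x, y, penalty_grid=np.array([1e12]))
        assert fit.r2[0] <= 1e-3
        folds = fit.folds
        train_mean = np.delete(y, folds[0]).mean()
        np.testing.assert_allclose(fit.heldout_pred[folds[0]], train_mean,
                                   atol=1e-3)

    def test_heldout_covers_each_timepoint_once(self, rng):
        x = rng.standard_normal((103, 3))
        y = rng.standard_normal(103)
        fit = fit_ridge_cv(x, y)
        idx = np.sort(np.concatenate(fit.folds))
        np.testing.assert_array_equal(idx, np.arange(103))

    def test_matches_sklearn_ridge_single_fold(self, rng):
        """Coefficient path cross-check against sklearn at a fixed penalty."""
        x = rng.standard_normal((120, 4))
        y = x @ np.array([0.5, -2.0, 1.0, 0.0]) + 0.1 * rng.standard_normal(120)
        lam = 3.7
        from stackenc.encoding import _ridge_coef

        coef, icpt = _ridge_coef(x, y[:, None], np.array([lam]))
        sk = Ridge(alpha=lam).fit(x, y)
        np.testing.assert_allclose(coef[0], sk.coef_, atol=1e-8)
        assert icpt[0] == pytest.approx(sk.intercept_, abs=1e-8)

    def test_rejects_empty_penalty_grid(self, rng):
        with pytest.raises(ValueError):
            fit_ridge_cv(rng.standard_normal((50, 2)),
                         rng.standard_normal(50), penalty_grid=np.array([]))


class TestSimplexStacking:
    def test_dominant_model_takes_all_weight(self, rng):
        y = rng.standard_normal(300)
        preds = np.column_stack([y, rng.standard_normal(300)])
        alpha = simplex_lstsq(preds, y)
        assert alpha[0] >= 0.99
        assert alpha.sum() == pytest.approx(1.0)

    def test_identical_predictions_tie_break_uniform(self, rng):
        p = rng.standard_normal(100)
        alpha = simplex_lstsq(np.column_stack([p, p]), rng.standard_normal(100))
        np.testing.assert_allclose(alpha, [0.5, 0.5], atol=1e-9)

    def test_qp_matches_grid_search_oracle(self, rng):
        """Exact QP vs exhaustive simplex grid search on random instances."""
        for _ in range(5):
            preds = rng.standard_normal((200, 3))
            truth = rng.dirichlet([1.0, 1.0, 1.0])
            y = preds @ truth + 0.5 * rng.standard_normal(200)
            qp = simplex_lstsq(preds, y)
            grid = simplex_grid_search(preds, y, step=0.005)
            np.testing.assert_allclose(qp, grid, atol=0.01)

    def test_batch_solver_agrees_with_scalar(self, rng):
        preds = rng.standard_normal((80, 30, 4))
        y = rng.standard_normal((80, 30))
        batch = _simplex_lstsq_batch(preds, y)
        for gi in range(30):
            np.testing.assert_allclose(
                batch[gi], simplex_lstsq(preds[:, gi], y[:, gi]), atol=1e-8
            )

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_simplex_invariants_and_dominance(self, seed):
        """Weights stay on the simplex; the stacked residual never exceeds
        the best single space's residual on the stacking-training data."""
        r = np.random.default_rng(seed)
        k = r.integers(2, 5)
        preds = r.standard_normal((60, k))
        y = r.standard_normal(60)
        alpha = simplex_lstsq(preds, y)
        assert alpha.min() >= -1e-10
        assert abs(alpha.sum() - 1.0) <= 1e-8
        stacked_resid = np.sum((y - preds @ alpha) ** 2)
        single_resids = [np.sum((y - preds[:, j]) ** 2) for j in range(k)]
        assert stacked_resid <= min(single_resids) + 1e-10

    def test_stack_models_returns_fit_slice(self, rng):
        y = rng.standard_normal(150)
        preds = np.column_stack([y + 0.1 * rng.standard_normal(150),
                                 rng.standard_normal(150)])
        sl = stack_models(preds, y)
        assert sl.alpha[0] > 0.9
        assert sl.r2 > 0.9


class TestFitStacked:
    def test_simplex_invariant_on_every_grayordinate(self, small_study):
        designs = {k: v.values for k, v in small_study.designs.items()}
        sid = small_study.phenotype["subject_id"].iloc[0]
        fit = fit_stacked(designs, small_study.bold[sid].values.T)
        assert fit.alphas.min() >= -1e-10
        np.testing.assert_allclose(fit.alphas.sum(axis=1), 1.0, atol=1e-8)

    def test_weight_recovery_on_known_mixture(self, rng):
        """On synthetic data with known mixing weights, the stacked fit
        recovers them with small mean absolute error."""
        t = 2000
        designs = {
            "audio-low": rng.standard_normal((t, 4)),
            "visual-high": rng.standard_normal((t, 4)),
        }
        truth = np.array([0.3, 0.7])
        comps = []
        for name in designs:
            p = designs[name] @ rng.standard_normal(4)
            comps.append((p - p.mean()) / p.std())
        signal = truth[0] * comps[0] + truth[1] * comps[1]
        y = signal + signal.std() * rng.standard_normal(t)  # snr = 1
        fit = fit_stacked(designs, y[:, None])
        assert np.abs(fit.alphas[0] - truth).mean() <= 0.05

    def test_mismatched_time_axis_rejected(self, rng):
        designs = {"audio-low": rng.standard_normal((100, 2)),
                   "visual-low": rng.standard_normal((90, 2))}
        with pytest.raises(ValueError, match="time axis"):
            fit_stacked(designs, rng.standard_normal((100, 3)))


class TestVariancePartition:
    @pytest.mark.parametrize(
        "stacked,component,expected",
        [
            (0.3, -0.1, 0.3),   # negative component clipped to zero
            (0.3, 0.5, 0.0),    # component exceeding stacked: unique zero
            (0.3, 0.2, 0.1),    # plain subtraction branch
        ],
    )
    def test_clipping_branches(self, stacked, component, expected):
        assert partition_unique_r2(stacked, component) == pytest.approx(expected)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(-1.0, 1.0), st.floats(-1.0, 1.0))
    def test_partition_consistency_every_branch(self, stacked, component):
        """unique + clipped component reconstructs the stacked R^2 exactly."""
        unique = partition_unique_r2(stacked, component)
        clipped = clip_component_r2(stacked, component)
        assert unique + clipped == pytest.approx(stacked, abs=1e-12)
        assert unique >= 0 or stacked < 0


class TestPreferenceIndex:
    @pytest.mark.parametrize(
        "weights,contrast,expected",
        [
            ({"audio-high": 1.0, "audio-low": 0.0}, "high_vs_low_audio", 1.0),
            ({"visual-high": 0.5, "visual-low": 0.5}, "high_vs_low_visual", 0.0),
            ({"audio-high": 0.25, "audio-low": 0.75}, "high_vs_low_audio", -0.5),
            ({"visual": 0.9, "audio": 0.1}, "visual_vs_audio", 0.8),
        ],
    )
    def test_weight_differences(self, weights, contrast, expected):
        idx = preference_index(weights, contrast)
        assert idx.value == pytest.approx(expected)
        assert abs(idx.value) <= 1.0

    def test_missing_weight_rejected(self):
        with pytest.raises(KeyError, match="audio-low"):
            preference_index({"audio-high": 1.0}, "high_vs_low_audio")

    def test_unknown_contrast_rejected(self):
        with pytest.raises(ValueError):
            preference_index({"a": 1.0}, "bogus")
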