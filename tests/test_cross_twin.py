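import warnings

import numpy as np
import pytest
from scipy import stats

from twinconn import (
    PredictiveModel,
    adjust_cohort,
    build_model,
    fit_plsr,
    generate_cohort,
    predict_and_score,
    run_logocv_bootstrap,
    select_features_ftest,
    split_pairs,
    TwinSimParams,
)
from twinconn.cross_twin import _fit_pls, _staged_predictions, screening_f_statistics


class TestSplitPairs:
    def test_structural_invariants(self, small_cohort):
        split = split_pairs(small_cohort, "MZ", rng_seed=1)
        assert split.train_idx.size == split.test_idx.size == 12
        assert np.intersect1d(split.train_idx, split.test_idx).size == 0
        pair_ids = small_cohort.roster["pair_id"].to_numpy()
        assert sorted(pair_ids[split.train_idx]) == sorted(pair_ids[split.test_idx])

    def test_same_seed_same_assignment(self, small_cohort):
        a = split_pairs(small_cohort, "MZ", rng_seed=5)
        b = split_pairs(small_cohort, "MZ", rng_seed=5)
        assert np.array_equal(a.train_idx, b.train_idx)

    def test_members_split_fairly_over_many_draws(self, small_cohort):
        n_draws = 600
        first_member_in_train = np.zeros(12)
        for s in range(n_draws):
            split = split_pairs(small_cohort, "MZ", rng_seed=s)
            pairs = small_cohort.subset("MZ").pair_indices()
            first_member_in_train += np.isin(pairs[:, 0], split.train_idx)
        # binomial oracle: each member trains ~n/2 times, 4 sigma band
        sd = np.sqrt(n_draws * 0.25)
        assert np.all(np.abs(first_member_in_train - n_draws / 2) < 4 * sd)

    def test_single_pair_rejected(self, pair_cohort_factory):
        with pytest.raises(ValueError, match="2 pairs"):
            split_pairs(pair_cohort_factory([(1.0, 2.0)]), "MZ")


class TestFeatureScreening:
    def test_matches_single_predictor_regression_oracle(self, rng):
        n, m = 8, 20
        X = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        fvals = screening_f_statistics(X, y)
        for j in range(m):
            # explicit simple-regression F oracle
            r = stats.pearsonr(X[:, j], y)[0]
            f_oracle = r**2 * (n - 2) / (1 - r**2)
            assert fvals[j] == pytest.approx(f_oracle, abs=1e-8)

    def test_edge_equal_to_response_always_selected(self, rng):
        X = rng.standard_normal((20, 10))
        y = X[:, 3].copy()
        sel = select_features_ftest(X, y, alpha=1e-6)
        assert 3 in sel

    def test_null_selection_rate_near_alpha(self, rng):
        n, m, alpha = 50, 400, 0.05
        X = rng.standard_normal((n, m))
        y = rng.standard_normal(n)
        sel = select_features_ftest(X, y, alpha)
        sd = np.sqrt(m * alpha * (1 - alpha))
        assert abs(sel.size - alpha * m) < 4 * sd

    def test_constant_edge_never_selected(self, rng):
        X = rng.standard_normal((15, 4))
        X[:, 2] = 7.0
        sel = select_features_ftest(X, X[:, 0], alpha=0.999)
        assert 2 not in sel

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 4"):
            select_features_ftest(rng.standard_normal((3, 5)), np.arange(3.0))


class TestPlsr:
    def test_truncated_predictions_equal_separate_fits(self, rng):
        X = rng.standard_normal((30, 9))
        y = X @ rng.standard_normal(9) + 0.5 * rng.standard_normal(30)
        full = _fit_pls(X, y, 5)
        staged = _staged_predictions(full, X, y, X)
        for c in range(1, 6):
            direct = _fit_pls(X, y, c).predict(X).ravel()
            assert np.allclose(staged[:, c - 1], direct, atol=1e-10)

    def test_first_component_follows_covariance_weights(self, rng):
        X = rng.standard_normal((200, 6))
        true_w = np.array([3.0, -2.0, 1.0, 0.0, 0.0, 0.5])
        y = X @ true_w
        pls = _fit_pls(X, y, 1)
        w = pls.x_weights_[:, 0]
        cov = np.array([stats.pearsonr(X[:, j], y)[0] for j in range(6)])
        cos = abs(w @ cov) / (np.linalg.norm(w) * np.linalg.norm(cov))
        assert cos > 0.9999

    def test_exact_recovery_of_two_feature_linear_response(self, rng):
        X = rng.standard_normal((40, 2))
        X[:, 1] -= (X[:, 1] @ X[:, 0]) / (X[:, 0] @ X[:, 0]) * X[:, 0]
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pls, ncomp = fit_plsr(X, y, component_grid_max=10, inner_folds=4)
        assert ncomp <= 2
        preds = pls.predict(X).ravel()
        assert stats.pearsonr(preds, y)[0] == pytest.approx(1.0, abs=1e-6)

    def test_grid_clipped_with_warning(self, rng):
        X = rng.standard_normal((12, 3))
        y = rng.standard_normal(12)
        with pytest.warns(UserWarning, match="clipped"):
            _, ncomp = fit_plsr(X, y, component_grid_max=100, inner_folds=3)
        assert ncomp <= 3


class TestPredictAndScore:
    def _model(self, preds):
        class Fixed:
            def predict(self, X):
                return preds

        return PredictiveModel(np.arange(3), 1, Fixed(), 5, 0.0)

    def test_perfect_and_inverted_predictions(self, rng):
        y = rng.standard_normal(5)
        X = rng.standard_normal((5, 3))
        assert predict_and_score(self._model(y), X, y) == pytest.approx(1.0)
        assert predict_and_score(self._model(-y), X, y) == pytest.approx(-1.0)

    def test_matches_covariance_formula_on_five_points(self, rng):
        y = np.array([1.0, 2.0, 0.5, 3.0, 2.5])
        p = np.array([0.8, 1.5, 1.0, 2.4, 2.9])
        X = rng.standard_normal((5, 3))
        num = np.sum((p - p.mean()) * (y - y.mean()))
        den = np.sqrt(np.sum((p - p.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
        assert predict_and_score(self._model(p), X, y) == pytest.approx(num / den)

    def test_constant_predictions_score_zero_with_warning(self, rng):
        y = rng.standard_normal(5)
        X = rng.standard_normal((5, 3))
        with pytest.warns(UserWarning, match="zero-variance"):
            assert predict_and_score(self._model(np.ones(5)), X, y) == 0.0


@pytest.fixture(scope="module")
def signal_cohort():
    syn = generate_cohort(
        TwinSimParams(n_pairs=40, node_count=20, rho=0.8, seed=31,
                      causal_edge_count=20)
    )
    return adjust_cohort(syn.cohort)


class TestLogocvBootstrap:
    def test_single_iteration_is_deterministic(self, signal_cohort):
        kwargs = dict(B=1, perms_per_model=3, component_grid_max=8,
                      inner_folds=3, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = run_logocv_bootstrap(signal_cohort, "MZ", **kwargs)
            b = run_logocv_bootstrap(signal_cohort, "MZ", **kwargs)
        assert np.array_equal(a.per_iteration_r, b.per_iteration_r)
        assert np.array_equal(a.null_draws, b.null_draws)
        for (s1, s2), (t1, t2) in zip(a.selections, b.selections):
            assert np.array_equal(s1, t1) and np.array_equal(s2, t2)

    def test_result_structure_and_null_centering(self, signal_cohort):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_logocv_bootstrap(
                signal_cohort, "MZ", B=6, perms_per_model=10,
                component_grid_max=8, inner_folds=3, seed=2,
            )
        assert res.per_iteration_r.shape == (6,)
        assert res.null_draws.shape == (60,)
        assert len(res.selections) == 6
        assert np.isfinite(res.per_iteration_r).all()
        se = res.null_draws.std() / np.sqrt(res.null_draws.size)
        assert abs(res.null_draws.mean()) < 5 * se + 0.02
        assert res.mean_r == pytest.approx(res.per_iteration_r.mean())

    def test_high_similarity_condition_outpredicts_low(self):
        rs = {}
        for rho in (0.8, 0.2):
            syn = generate_cohort(
                TwinSimParams(n_pairs=60, node_count=20, rho=rho, seed=33,
                              causal_edge_count=20)
            )
            cohort = adjust_cohort(syn.cohort)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_logocv_bootstrap(
                    cohort, "MZ", B=8, perms_per_model=0 or 1,
                    component_grid_max=8, inner_folds=3, seed=34,
                )
            rs[rho] = res.mean_r
        assert rs[0.8] > rs[0.2]

    def test_perfect_twins_transfer_equals_within_group_prediction(self):
        # rho = 1, no G noise: the co-twin group is a copy of the training group,
        # so cross-twin r must equal the model's within-group (training) r
        syn = generate_cohort(
            TwinSimParams(n_pairs=30, node_count=15, rho=1.0, sigma=0.0,
                          shared_env=0.0, causal_edge_count=10, seed=35)
        )
        cohort = adjust_cohort(syn.cohort)
        X, y = cohort.edges, cohort.g_adjusted
        pairs = cohort.pair_indices()
        tr, te = pairs[:, 0], pairs[:, 1]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = build_model(X[tr], y[tr], 0.05, 8, 3)
            r_cotwin = predict_and_score(model, X[te], y[te])
            r_within = predict_and_score(model, X[tr], y[tr])
        assert r_cotwin == pytest.approx(r_within, abs=1e-10)
        assert r_cotwin > 0.5
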