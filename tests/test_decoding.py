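import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirsload.decoding import (CVScheme, DEFAULT_K_GRID, apply_pca_truncation,
                               decode_peripheral, fit_lasso,
                               fit_pca_truncation, lambda_max,
                               make_lambda_grid, nested_cv_decode, pearson_r)
from nirsload.preprocessing import LabeledSampleSet
from nirsload.synthetic import generate_behavior, generate_design


def make_samples(X, y, trials_of=None):
    n = len(y)
    trial = np.asarray(trials_of) if trials_of is not None else np.arange(n)
    return LabeledSampleSet(np.asarray(X, float), np.asarray(y, float),
                            trial, np.arange(n, dtype=float),
                            list(range(1, X.shape[1] + 1)))


class TestPearson:
    def test_identity_and_sign_flip(self):
        a = np.array([1.0, 2.0, 5.0, 3.0])
        assert pearson_r(a, a) == pytest.approx(1.0)
        assert pearson_r(a, -a) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson_r([1, 2, 3], [2, 4, 7]) == pytest.approx(0.9934, abs=5e-5)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestPCA:
    rng = np.random.default_rng(0)

    def test_full_basis_is_identity(self):
        X = self.rng.normal(0, 1, (40, 6))
        m = fit_pca_truncation(X, 6)
        assert np.allclose(apply_pca_truncation(m, X), X, atol=1e-10)

    def test_rank_one_data_exact_with_k1(self):
        u = self.rng.normal(0, 1, (30, 1))
        v = self.rng.normal(0, 1, (1, 8))
        X = u @ v
        m = fit_pca_truncation(X, 1)
        assert np.max(np.abs(apply_pca_truncation(m, X) - X)) <= 1e-9

    def test_explained_variance_matches_sklearn_and_decreases(self):
        from sklearn.decomposition import PCA

        X = self.rng.normal(0, 1, (5, 20)) @ self.rng.normal(0, 1, (20, 20))
        X = self.rng.normal(0, 1, (25, 20))
        m = fit_pca_truncation(X, 10)
        assert np.all(np.diff(m.explained_variance) <= 1e-12)
        ref = PCA(n_components=10).fit(X)
        assert np.allclose(m.explained_variance, ref.explained_variance_,
                           rtol=1e-8)
        # components agree up to sign
        dots = np.abs(np.sum(m.component_basis * ref.components_, axis=1))
        assert np.allclose(dots, 1.0, atol=1e-8)

    def test_idempotent_projection(self):
        X = self.rng.normal(0, 1, (50, 7))
        m = fit_pca_truncation(X, 3)
        once = apply_pca_truncation(m, X)
        assert np.allclose(apply_pca_truncation(m, once), once, atol=1e-10)

    def test_truncation_denoises_top_component_signal(self):
        t = np.linspace(0, 6 * np.pi, 400)
        signal = np.sin(t)[:, None] * self.rng.normal(0, 1, (1, 12)) * 3
        noise = self.rng.normal(0, 1, (400, 12))
        X = signal + noise
        m = fit_pca_truncation(X, 1)
        den = apply_pca_truncation(m, X)
        snr_in = signal.var() / noise.var()
        snr_out = signal.var() / (den - signal - X.mean(0)).var()
        assert snr_out > snr_in

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k must"):
            fit_pca_truncation(self.rng.normal(0, 1, (10, 4)), 5)


class TestLasso:
    rng = np.random.default_rng(1)

    def test_above_lambda_max_full_shrinkage(self):
        X = self.rng.normal(0, 1, (60, 5))
        y = self.rng.normal(0, 1, 60)
        xs = (X - X.mean(0)) / X.std(0)
        lmax = lambda_max(xs, y)
        m = fit_lasso(X, y, lmax * 1.001)
        assert np.allclose(m.weights, 0)
        assert m.intercept == pytest.approx(y.mean())

    def test_lambda_zero_equals_normal_equations(self):
        X = self.rng.normal(0, 1, (50, 4))
        beta = np.array([1.0, -2.0, 0.5, 0.0])
        y = X @ beta + self.rng.normal(0, 0.1, 50)
        m = fit_lasso(X, y, 0.0)
        xs = (X - m.feature_mean) / m.feature_scale
        a = np.column_stack([np.ones(50), xs])
        ref = np.linalg.solve(a.T @ a, a.T @ y)
        assert np.allclose(m.weights, ref[1:], atol=1e-8)
        assert m.intercept == pytest.approx(ref[0])

    @given(st.floats(min_value=0.001, max_value=2.0))
    def test_univariate_soft_threshold_closed_form(self, lam):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 200)[:, None]
        y = 1.5 * x[:, 0] + rng.normal(0, 0.5, 200)
        m = fit_lasso(x, y, lam)
        xs = (x[:, 0] - x.mean()) / x.std()
        rho = xs @ (y - y.mean()) / len(y)       # var(xs) = 1
        expected = np.sign(rho) * max(abs(rho) - lam, 0.0)
        assert m.weights[0] == pytest.approx(expected, abs=1e-6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso(np.array([[1.0], [np.nan]]), np.array([1.0, 2.0]), 0.1)


class TestNestedCV:
    def _linear_samples(self, n_trials=40, n_ch=6, noise=0.05, seed=0,
                        samples_per_trial=5):
        rng = np.random.default_rng(seed)
        levels = rng.integers(0, 5, n_trials)
        w = rng.normal(0, 1, n_ch)
        rows, ys, trials = [], [], []
        for tid, lv in enumerate(levels):
            for _ in range(samples_per_trial):
                rows.append(w * lv + rng.normal(0, noise, n_ch))
                ys.append(lv)
                trials.append(tid)
        return make_samples(np.array(rows), np.array(ys, float), trials)

    def test_high_snr_recovers_labels(self):
        ss = self._linear_samples()
        res = nested_cv_decode(ss, CVScheme(5, 3, seed=0),
                               k_grid=(1, 3, None), n_lambdas=10)
        assert res.r_mvr > 0.95

    def test_reproducible_for_fixed_seed(self):
        ss = self._linear_samples()
        kw = dict(k_grid=(1, 3, None), n_lambdas=8)
        a = nested_cv_decode(ss, CVScheme(5, 3, seed=3), **kw)
        b = nested_cv_decode(ss, CVScheme(5, 3, seed=3), **kw)
        assert np.array_equal(a.predicted, b.predicted)
        assert a.chosen_k == b.chosen_k and a.chosen_lambda == b.chosen_lambda

    def test_folds_partition_trials(self):
        ss = self._linear_samples()
        res = nested_cv_decode(ss, CVScheme(5, 3, seed=1),
                               k_grid=(3,), n_lambdas=5)
        seen = {}
        for tid, fold in zip(ss.trial_id, res.fold_of_sample):
            assert seen.setdefault(tid, fold) == fold   # one fold per trial
        all_test = np.concatenate([m.test_trials for m in res.fold_models])
        assert sorted(all_test) == sorted(np.unique(ss.trial_id))

    def test_every_sample_predicted_exactly_once(self):
        ss = self._linear_samples(n_trials=23)
        res = nested_cv_decode(ss, CVScheme(5, 3, seed=2),
                               k_grid=(2,), n_lambdas=5)
        assert np.all(np.isfinite(res.predicted))
        assert res.fold_of_sample.min() >= 0

    def test_no_leakage_of_test_labels(self):
        """Replacing held-out-fold labels with noise leaves that fold's
        fitted model bitwise identical."""
        ss = self._linear_samples(seed=5)
        kw = dict(scheme=CVScheme(5, 3, seed=7), k_grid=(1, 3), n_lambdas=6)
        base = nested_cv_decode(ss, **kw)
        fold0_trials = base.fold_models[0].test_trials
        y2 = ss.labels.copy()
        mask = np.isin(ss.trial_id, fold0_trials)
        y2[mask] = np.random.default_rng(99).normal(2, 1, mask.sum())
        ss2 = LabeledSampleSet(ss.features, y2, ss.trial_id, ss.sample_time,
                               ss.channel_ids)
        mod = nested_cv_decode(ss2, **kw)
        m0, m1 = base.fold_models[0], mod.fold_models[0]
        assert np.array_equal(m0.test_trials, m1.test_trials)
        assert (m0.k, m0.lam) == (m1.k, m1.lam)
        assert np.array_equal(m0.lasso.weights, m1.lasso.weights)
        assert np.array_equal(m0.pca.component_basis, m1.pca.component_basis)
        assert np.array_equal(base.predicted[mask], mod.predicted[mask])

    def test_fewer_trials_than_folds_rejected(self):
        ss = self._linear_samples(n_trials=5)
        with pytest.raises(ValueError, match="fewer trials"):
            nested_cv_decode(ss, CVScheme(10, 3, seed=0))

    def test_channel_subset_restricts_features(self):
        ss = self._linear_samples()
        res = nested_cv_decode(ss, CVScheme(5, 3, seed=0), k_grid=(2,),
                               n_lambdas=5, channel_subset=[1, 2],
                               subset_label="frontal")
        assert res.channel_subset_label == "frontal"
        assert all(m.lasso.weights.shape == (2,) for m in res.fold_models)


class TestPeripheral:
    def test_label_as_feature_is_perfect(self):
        design = generate_design(seed=0)
        tbl = generate_behavior(design, n_participants=1, seed=0)
        tbl["heart_rate"] = tbl["nback_level"].astype(float)
        tbl["rmssd"] = 1.0 + 0 * tbl["rmssd"]
        res = decode_peripheral(tbl, CVScheme(5, 3, seed=0), n_lambdas=20)
        assert res.r_mvr > 0.999

    def test_uninformative_features_near_zero(self):
        design = generate_design(seed=1)
        tbl = generate_behavior(design, n_participants=1, seed=1)
        rng = np.random.default_rng(2)
        tbl["heart_rate"] = rng.normal(70, 5, len(tbl))
        tbl["rmssd"] = rng.normal(40, 10, len(tbl))
        res = decode_peripheral(tbl, CVScheme(5, 3, seed=0), n_lambdas=20)
        assert abs(res.r_mvr) < 0.3

    def test_missing_feature_rejected(self):
        design = generate_design(seed=0)
        tbl = generate_behavior(design, n_participants=1, seed=0)
        with pytest.raises(ValueError, match="missing features"):
            decode_peripheral(tbl.drop(columns=["rmssd"]), CVScheme(5, 3, 0))
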