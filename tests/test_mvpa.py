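"""Balanced LOOCV SVM decoding, permutation nulls and the Haufe transform."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from alphadyn import _svmcore
from alphadyn.features import FeatureTable
from alphadyn.mvpa import (
    DecodingConfig,
    auc_from_decisions,
    balanced_loocv_auc,
    bonferroni_adjust,
    decode_all_features,
    permutation_test,
    _training_draws,
)


def make_table(X, n_high=None, name="sd_alpha_cf", tag="pre"):
    n = X.shape[0]
    n_high = n_high if n_high is not None else n // 2
    sids = [f"s{i}" for i in range(n)]
    labels = pd.Series(["high"] * n_high + ["low"] * (n - n_high), index=sids)
    df = pd.DataFrame(X, index=sids, columns=[f"ch{j}" for j in range(X.shape[1])])
    return FeatureTable(df, name, tag, labels)


class TestAUC:
    def test_perfect_separation(self):
        d = np.r_[np.ones(10), -np.ones(10)]
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        assert auc_from_decisions(d, y) == 1.0

    def test_label_flip_maps_auc_to_complement(self):
        rng = np.random.default_rng(0)
        d = rng.standard_normal(40)
        y = rng.integers(0, 2, 40)
        y[0], y[1] = 0, 1  # both classes present
        assert auc_from_decisions(d, y) == pytest.approx(1 - auc_from_decisions(d, 1 - y))

    def test_midrank_tie_handling(self):
        d = np.zeros(10)
        y = np.r_[np.ones(5, int), np.zeros(5, int)]
        assert auc_from_decisions(d, y) == 0.5


class TestSVMSolver:
    @pytest.mark.filterwarnings("ignore::UserWarning")
    @pytest.mark.filterwarnings("ignore:Liblinear failed to converge")
    def test_matches_sklearn_linear_svc(self):
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 6))
        y01 = np.r_[np.ones(15, int), np.zeros(15, int)]
        X[y01 == 1] += 0.8
        Xa = np.hstack([X, np.ones((30, 1))])
        w = _svmcore.svm_dual_cd(Xa, np.where(y01 == 1, 1.0, -1.0), 1.0, 5000, 1e-12)
        ref = sklearn_svm.LinearSVC(
            C=1.0, loss="hinge", max_iter=200_000, tol=1e-10, random_state=0
        ).fit(X, y01)
        np.testing.assert_allclose(w[:-1], ref.coef_[0], atol=5e-3)
        np.testing.assert_allclose(w[-1], ref.intercept_[0], atol=5e-3)


class TestBalancedLOOCV:
    def test_separable_feature_gives_auc_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 4)) * 0.01
        X[:20, 0] += 10.0
        auc, reps, _ = balanced_loocv_auc(make_table(X), DecodingConfig(n_repetitions=2))
        assert auc == 1.0

    def test_null_features_near_chance(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((40, 8))
        auc, _, _ = balanced_loocv_auc(make_table(X), DecodingConfig(n_repetitions=5))
        assert 0.35 <= auc <= 0.65

    def test_gaussian_dprime_closed_form_oracle(self):
        """Two spherical Gaussian classes at d'=1: the optimal linear rule has
        AUC = Phi(d'/sqrt(2)) ~ 0.760; the fitted SVM approaches it."""
        rng = np.random.default_rng(5)
        n = 200
        X = rng.standard_normal((2 * n, 2))
        X[:n] += np.array([1.0, 0.0])
        cfg = DecodingConfig(n_per_class_train=150, n_repetitions=1)
        auc, _, _ = balanced_loocv_auc(make_table(X, n_high=n), cfg)
        assert abs(auc - norm.cdf(1 / np.sqrt(2))) < 0.05

    def test_class_exhaustion_raises(self):
        X = np.random.default_rng(0).standard_normal((10, 3))
        with pytest.raises(ValueError):
            balanced_loocv_auc(make_table(X), DecodingConfig(n_per_class_train=5))

    def test_constant_column_handled(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((40, 3))
        X[:, 1] = 7.0  # zero-variance channel must not produce NaNs
        auc, _, pattern = balanced_loocv_auc(make_table(X), DecodingConfig(n_repetitions=2))
        assert np.isfinite(auc) and np.all(np.isfinite(pattern))


class TestPermutationTest:
    CFG = DecodingConfig(n_repetitions=3, n_permutations=100, perm_repetitions=1)

    def test_p_floor_with_strong_effect(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 4)) * 0.01
        X[:20, 0] += 10.0
        res = permutation_test(make_table(X), self.CFG)
        assert res.p_value == pytest.approx(1 / 101)
        assert res.significant_raw

    def test_null_distribution_mean_near_half(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((40, 6))
        res = permutation_test(make_table(X), self.CFG)
        assert abs(res.null_aucs.mean() - 0.5) < 0.03

    def test_null_feature_rarely_rejected(self):
        """Exchangeable labels: raw rejections stay near the nominal 5% rate."""
        rejections = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((30, 4))
            cfg = DecodingConfig(
                n_repetitions=2, n_permutations=60, perm_repetitions=1,
                n_per_class_train=10, seed=seed,
            )
            res = permutation_test(make_table(X), cfg)
            rejections += res.significant_raw
        assert rejections <= 3  # Binomial(10, 0.05): P(>3) < 0.002


class TestBonferroni:
    def test_threshold_arithmetic(self):
        flags = bonferroni_adjust([0.009, 0.02], n_tests=5)
        assert flags.tolist() == [True, False]

    def test_single_test_is_identity(self):
        assert bonferroni_adjust([0.04], n_tests=1).tolist() == [True]

    def test_rejects_undersized_family(self):
        with pytest.raises(ValueError):
            bonferroni_adjust([0.01, 0.02, 0.03], n_tests=2)


class TestHaufe:
    def test_whitened_features_pattern_proportional_to_weights(self):
        """With whitened features the covariance is ~identity, so the averaged
        activation pattern aligns with the averaged weight vector."""
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 5))
        X[:20] += np.array([0.8, 0.4, 0.0, -0.4, 0.2])
        X = (X - X.mean(0)) @ np.linalg.inv(np.linalg.cholesky(np.cov(X.T)).T)
        y = np.r_[np.ones(20, np.int64), np.zeros(20, np.int64)]
        cfg = DecodingConfig(n_repetitions=10, standardize=False)
        draws = _training_draws(y, cfg.n_per_class_train, cfg.n_repetitions,
                                np.random.default_rng(0))
        _, haufe, wsum, count = _svmcore.loocv_decisions(
            X, y, draws, 1.0, False
        )
        pattern, weights = haufe / count, wsum[:5] / count
        cos = pattern @ weights / (np.linalg.norm(pattern) * np.linalg.norm(weights))
        assert cos > 0.98

    def test_informative_channel_has_peak_pattern(self):
        """One channel carries the class difference on top of channel-correlated
        noise; the averaged Haufe pattern peaks at that channel."""
        rng = np.random.default_rng(6)
        n, d, signal_ch = 40, 6, 2
        shared = rng.standard_normal((n, 1))
        X = 0.8 * shared + 0.6 * rng.standard_normal((n, d))
        X[:20, signal_ch] += 1.5
        _, _, pattern = balanced_loocv_auc(make_table(X), DecodingConfig(n_repetitions=5))
        assert int(np.argmax(np.abs(pattern))) == signal_ch


class TestDecodeAll:
    def test_main_family_has_ten_results(self):
        rng = np.random.default_rng(9)
        tables = {}
        for feat in ("sd_alpha_cf", "sd_alpha_amplitude", "sd_alpha_width",
                     "sd_offset", "sd_exponent"):
            for tag in ("pre", "delta"):
                tables[(feat, tag)] = make_table(
                    rng.standard_normal((12, 3)), name=feat, tag=tag
                )
        cfg = DecodingConfig(
            n_repetitions=1, n_permutations=20, perm_repetitions=1, n_per_class_train=4
        )
        results, summary = decode_all_features(tables, cfg)
        assert len(results) == 10
        assert len(summary) == 10
        assert set(summary.columns) >= {"feature", "contrast", "auc", "p_value"}
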