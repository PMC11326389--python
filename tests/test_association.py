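"""Classifier importances, scaling, ensemble FCA, and Otsu binarization."""

import numpy as np
import pandas as pd
import pytest

import scired as sr


def _planted_scores(seed=0, n=300, k=5, target=2):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=(n, k))
    labels = (scores[:, target] > np.median(scores[:, target])).astype(int)
    return scores, labels


class TestImportances:
    def test_logistic_argmax_at_planted_factor(self):
        scores, labels = _planted_scores()
        imp = sr.importance_logistic(scores, labels)
        assert int(np.argmax(imp)) == 2

    def test_logistic_single_class_error(self):
        scores, _ = _planted_scores()
        with pytest.raises(ValueError):
            sr.importance_logistic(scores, np.zeros(len(scores), dtype=int))

    def test_logistic_duplicated_factor_keeps_argmax_in_pair(self):
        scores, labels = _planted_scores()
        dup = np.column_stack([scores, scores[:, 2]])
        imp = sr.importance_logistic(dup, labels)
        assert int(np.argmax(imp)) in (2, 5)

    @pytest.mark.parametrize("model", ["decision_tree", "xgb"])
    def test_tree_importances_contract(self, model):
        scores, labels = _planted_scores(seed=1)
        imp = sr.importance_tree(scores, labels, model, seed=0)
        assert np.all(imp >= 0)
        assert imp.sum() <= 1 + 1e-9
        assert int(np.argmax(imp)) == 2

    def test_auc_perfect_separation(self):
        scores = np.array([[1.0], [2.0], [3.0], [4.0]])
        labels = np.array([0, 0, 1, 1])
        assert sr.importance_auc(scores, labels)[0] == pytest.approx(1.0)

    def test_auc_identical_distributions_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(2000, 1))
        labels = np.r_[np.zeros(1000, int), np.ones(1000, int)]
        auc = sr.importance_auc(scores, labels)[0]
        assert 0.5 <= auc < 0.55  # rectified, so >= 0.5 by construction

    def test_auc_matches_roc_integration_oracle(self):
        """AUC from the U statistic equals explicit ROC curve integration."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n0, n1 = rng.integers(5, 40, 2)
            x = np.r_[rng.normal(0, 1, n0), rng.normal(rng.uniform(0, 2), 1, n1)]
            labels = np.r_[np.zeros(n0, int), np.ones(n1, int)]
            auc_u = sr.importance_auc(x[:, None], labels)[0]
            # trapezoid ROC integration over all thresholds
            thr = np.r_[-np.inf, np.sort(np.unique(x)), np.inf]
            tpr = [(x[labels == 1] > t).mean() for t in thr]
            fpr = [(x[labels == 0] > t).mean() for t in thr]
            auc_roc = -np.trapezoid(tpr, fpr)
            assert auc_u == pytest.approx(max(auc_roc, 1 - auc_roc), abs=1e-10)


class TestScaling:
    def test_minmax_example(self):
        assert np.allclose(
            sr.scale_importances(np.array([1.0, 2.0, 3.0]), "minmax"), [0, 0.5, 1]
        )

    def test_rank_example(self):
        assert np.allclose(
            sr.scale_importances(np.array([10.0, 30.0, 20.0]), "rank"),
            [1 / 3, 1.0, 2 / 3],
        )

    def test_standardize_zero_mean_unit_sd(self):
        z = sr.scale_importances(np.array([4.0, 7.0, 1.0, 2.0]), "standardize")
        assert abs(z.mean()) < 1e-12 and abs(z.std() - 1) < 1e-12

    def test_zero_variance_standardize_is_zeros(self):
        assert np.allclose(sr.scale_importances(np.ones(4), "standardize"), 0)

    def test_geometric_mean_refused_with_standardize(self):
        scores, labels = _planted_scores()
        cov = pd.DataFrame({"lab": np.where(labels == 1, "a", "b")})
        with pytest.raises(ValueError, match="geometric"):
            sr.ensemble_fca(scores, cov, scaling="standardize", mean="geometric")


class TestOtsu:
    def test_bimodal_threshold_between_modes(self):
        assert 0 < sr.otsu_threshold([0, 0, 0, 10, 10]) < 10
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 1, 200), rng.normal(8, 1, 200)]
        assert 2 < sr.otsu_threshold(x) < 6

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            sr.otsu_threshold(np.ones(10))

    def test_matches_bruteforce_scan_oracle(self):
        """The chosen cut maximizes between-class variance over every
        possible partition of the sorted values."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(size=rng.integers(5, 60))
            thr = sr.otsu_threshold(x)

            def between(t):
                lo, hi = x[x <= t], x[x > t]
                if len(lo) == 0 or len(hi) == 0:
                    return -np.inf
                return (
                    len(lo) / len(x) * len(hi) / len(x) * (lo.mean() - hi.mean()) ** 2
                )

            best = max(between(t) for t in x)
            assert between(thr) == pytest.approx(best, rel=1e-12)

    def test_agrees_with_skimage_partition(self):
        import skimage.filters

        rng = np.random.default_rng(1)
        x = np.r_[rng.normal(0, 1, 300), rng.normal(6, 1, 300)]
        t_pkg = sr.otsu_threshold(x)
        t_ski = skimage.filters.threshold_otsu(x, nbins=4096)
        # histogram binning can move the cut by a point or two where the
        # between-class variance is flat; partitions must agree otherwise
        assert int(np.sum((x <= t_pkg) != (x <= t_ski))) <= 2


class TestEnsembleFCA:
    def test_complementary_levels_pick_same_factor(self):
        scores, labels = _planted_scores(seed=3)
        cov = pd.DataFrame({"grp": np.where(labels == 1, "a", "b")})
        fca = sr.ensemble_fca(scores, cov, seed=0)
        assert fca.values.loc["grp:a"].idxmax() == fca.values.loc["grp:b"].idxmax()

    def test_column_order_invariance(self):
        scores, labels = _planted_scores(seed=4)
        cov = pd.DataFrame({"grp": np.where(labels == 1, "a", "b")})
        perm = np.array([3, 0, 4, 1, 2])
        a = sr.ensemble_fca(scores, cov, seed=0).values.to_numpy()
        b = sr.ensemble_fca(scores[:, perm], cov, seed=0).values.to_numpy()
        assert np.allclose(a[:, perm], b, atol=1e-8)

    def test_shuffled_labels_lower_max_score(self, factor_model, fixture_data):
        _, cov = fixture_data
        obs = sr.ensemble_fca(factor_model, cov, ["line"], seed=0)
        obs_max = obs.values.to_numpy().max()
        rng = np.random.default_rng(0)
        wins = 0
        for _ in range(20):
            shuffled = cov.table.copy()
            lab = shuffled["line"].to_numpy()
            shuffled["line"] = lab[rng.permutation(len(lab))]
            perm = sr.ensemble_fca(
                factor_model, sr.CovariateTable(shuffled), ["line"], seed=0
            )
            if perm.values.to_numpy().max() < obs_max:
                wins += 1
        assert wins == 20

    def test_no_categorical_covariate_error(self):
        scores, _ = _planted_scores()
        cov = pd.DataFrame({"depth": np.linspace(0, 1, len(scores))})
        with pytest.raises(ValueError):
            sr.ensemble_fca(scores, cov)


class TestCalls:
    def test_binarization_consistent_with_threshold(self, fca_table):
        calls = sr.call_associations(fca_table)
        expect = fca_table.values > calls.threshold
        assert (calls.significant.astype(bool) == expect).all().all()

    def test_high_contrast_one_hot_rows(self):
        vals = pd.DataFrame(
            np.eye(3) * 10.0,
            index=["c:a", "c:b", "c:c"],
            columns=["F1", "F2", "F3"],
        )
        calls = sr.call_associations(sr.FCATable(vals))
        assert all(len(v) == 1 for v in calls.matched_factors.values())
        assert calls.unannotated_factors == []

    def test_unannotated_factors_listed(self, fca_table):
        calls = sr.call_associations(fca_table)
        sig_factors = {f for v in calls.matched_factors.values() for f in v}
        assert set(calls.unannotated_factors) == set(fca_table.values.columns) - sig_factors
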