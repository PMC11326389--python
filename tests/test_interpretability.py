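"""Separability, effect size, specificity and homogeneity metrics."""

import numpy as np
import pandas as pd
import pytest

import scired as sr
from scired.interpretability import dip_statistic


def _two_clusters(gap=6.0, n=100, sd=0.5, seed=0):
    rng = np.random.default_rng(seed)
    x = np.r_[rng.normal(0, sd, n // 2), rng.normal(gap, sd, n - n // 2)]
    labels = np.r_[np.zeros(n // 2, int), np.ones(n - n // 2, int)]
    return x, labels


class TestKmeansPartition:
    def test_recovers_separated_groups(self):
        x = np.r_[np.zeros(50), np.full(50, 10.0)]
        labels = sr.kmeans2_partition(x, seed=0)
        assert len(np.unique(labels[:50])) == 1
        assert len(np.unique(labels[50:])) == 1
        assert labels[0] != labels[-1]

    def test_constant_scores_error(self):
        with pytest.raises(ValueError):
            sr.kmeans2_partition(np.ones(20), seed=0)

    def test_label_swap_leaves_metrics_unchanged(self):
        x, labels = _two_clusters()
        for fn in (sr.vrs, sr.wvrs, sr.silhouette_sep, sr.davies_bouldin_scaled):
            assert fn(x, labels) == pytest.approx(fn(x, 1 - labels))


class TestClusterMetrics:
    def test_vrs_large_for_tight_separated_clusters(self):
        x, labels = _two_clusters()
        assert sr.vrs(x, labels) > 20

    def test_vrs_translation_invariant_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            x = rng.normal(size=40)
            labels = (rng.random(40) > 0.4).astype(int)
            if labels.sum() in (0, 40):
                continue
            got = sr.vrs(x, labels)
            # direct SS decomposition oracle
            grand = x.mean()
            bss = sum(
                (labels == c).sum() * (x[labels == c].mean() - grand) ** 2
                for c in (0, 1)
            )
            wss = sum(((x[labels == c] - x[labels == c].mean()) ** 2).sum() for c in (0, 1))
            assert got == pytest.approx(bss / wss)
            assert sr.vrs(x + 5.0, labels) == pytest.approx(got)

    def test_wvrs_stable_under_imbalance(self):
        rng = np.random.default_rng(2)
        bal = np.r_[rng.normal(0, 1, 100), rng.normal(4, 1, 100)]
        bal_l = np.r_[np.zeros(100, int), np.ones(100, int)]
        imb = np.r_[rng.normal(0, 1, 190), rng.normal(4, 1, 10)]
        imb_l = np.r_[np.zeros(190, int), np.ones(10, int)]
        w_bal, w_imb = sr.wvrs(bal, bal_l), sr.wvrs(imb, imb_l)
        v_bal, v_imb = sr.vrs(bal, bal_l), sr.vrs(imb, imb_l)
        # wvrs moves far less than vrs when sizes become 95:5
        assert abs(np.log(w_imb / w_bal)) < abs(np.log(v_imb / v_bal))

    def test_silhouette_extremes_and_oracle(self):
        x, labels = _two_clusters(gap=50.0, sd=0.1)
        assert sr.silhouette_sep(x, labels) > 0.95
        rng = np.random.default_rng(3)
        y = rng.normal(size=50)
        lab = (rng.random(50) > 0.5).astype(int)
        # brute-force pairwise-distance silhouette
        D = np.abs(y[:, None] - y[None, :])
        s = []
        for i in range(50):
            same = lab == lab[i]
            icd = D[i][same & (np.arange(50) != i)].mean()
            ncd = D[i][~same].mean()
            s.append((ncd - icd) / max(icd, ncd))
        assert sr.silhouette_sep(y, lab) == pytest.approx(np.mean(s), abs=1e-10)

    def test_davies_bouldin_scaling(self):
        x, labels = _two_clusters(gap=100.0, sd=0.01)
        assert sr.davies_bouldin_scaled(x, labels) > 0.95
        y, lab = _two_clusters(gap=0.5, sd=1.0, seed=4)
        scaled, raw = sr.davies_bouldin_scaled(y, lab, return_raw=True)
        assert raw > 1 and scaled < 0.5
        assert scaled == pytest.approx(1 / (1 + raw))


class TestBimodalityIndex:
    def test_printed_formula_fixed_point(self):
        fit = sr.GMMFit(mu1=0.0, mu2=4.0, sigma=1.0, pi=0.5, delta=4.0)
        assert fit.pi * (1 - fit.pi) * fit.delta == pytest.approx(1.0)

    def test_separated_mixture_bi_near_one(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0, 1, 500), rng.normal(4, 1, 500)]
        bi, fit = sr.bimodality_index(x, seed=0)
        assert bi == pytest.approx(fit.pi * (1 - fit.pi) * fit.delta)
        assert 0.8 < bi < 1.2
        bi_sqrt, _ = sr.bimodality_index(x, seed=0, sqrt_proportions=True)
        assert bi_sqrt == pytest.approx(bi / np.sqrt(fit.pi * (1 - fit.pi)), rel=1e-6)

    def test_unimodal_low_bi(self):
        rng = np.random.default_rng(1)
        bi, _ = sr.bimodality_index(rng.normal(size=1000), seed=0)
        assert bi < 0.6

    def test_parameter_recovery_over_replicates(self):
        """Mean GMM estimates over 100 replicates land within 3 standard
        errors of the generating mixture parameters."""
        mu1, mu2, sigma, pi = 0.0, 3.0, 0.8, 0.5
        rng = np.random.default_rng(2)
        est = []
        for _ in range(100):
            comp = rng.random(400) < pi
            x = np.where(comp, rng.normal(mu1, sigma, 400), rng.normal(mu2, sigma, 400))
            _, fit = sr.bimodality_index(x, seed=0)
            est.append([fit.mu1, fit.mu2, fit.sigma, fit.pi])
        est = np.array(est)
        mean, sem = est.mean(axis=0), est.std(axis=0, ddof=1) / 10
        for got, se, true in zip(mean, sem, [mu1, mu2, sigma, 0.5]):
            assert abs(got - true) < 3 * max(se, 1e-3)


class TestDip:
    def test_two_point_masses_quarter(self):
        x = np.r_[np.zeros(50), np.ones(50)]
        assert dip_statistic(x) == pytest.approx(0.25)

    def test_linear_ecdf_minimum(self):
        assert dip_statistic(np.arange(1, 11)) == pytest.approx(0.05)

    def test_uniform_sample_small(self):
        rng = np.random.default_rng(0)
        assert dip_statistic(rng.uniform(size=1000)) < 0.03

    def test_nonnegative_always(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            assert dip_statistic(rng.normal(size=rng.integers(5, 200))) >= 0

    def test_separated_spikes_large(self):
        rng = np.random.default_rng(2)
        x = np.r_[rng.normal(0, 0.01, 300), rng.normal(5, 0.01, 300)]
        assert dip_statistic(x) > 0.2


class TestEffectSizeSpecificity:
    def test_variance_basics(self):
        x = np.random.default_rng(0).normal(size=200)
        assert sr.effect_size_variance(np.full(10, 3.0)) == 0
        assert sr.effect_size_variance(2 * x) == pytest.approx(
            4 * sr.effect_size_variance(x)
        )

    def test_simpson_one_hot_and_uniform(self):
        one_hot = np.zeros(8)
        one_hot[3] = 1.0
        assert sr.simpson_index(one_hot) == pytest.approx(1.0)
        assert sr.simpson_index(np.ones(5)) == pytest.approx(1 / 5)

    def test_simpson_rectifies_negative_scores(self):
        col = np.array([-1.0, -0.5, 2.0])
        assert sr.simpson_index(col) == pytest.approx(1.0)

    def test_shannon_bounds(self):
        one_hot = np.zeros(6)
        one_hot[0] = 1.0
        assert sr.shannon_specificity(one_hot, invert=False) == pytest.approx(0.0)
        assert sr.shannon_specificity(np.ones(6), invert=False) == pytest.approx(
            np.log(6)
        )
        rng = np.random.default_rng(0)
        for _ in range(20):
            col = rng.random(7)
            assert sr.shannon_specificity(col, invert=False) <= np.log(7) + 1e-12
        assert sr.shannon_specificity(one_hot) == pytest.approx(1.0)
        assert sr.shannon_specificity(np.ones(6)) == pytest.approx(0.0)


class TestHomogeneity:
    def test_random_subsample_sv_near_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=2000)
        mask = rng.random(2000) < 0.3
        assert sr.scaled_variance(x, mask) == pytest.approx(1.0, abs=0.15)

    def test_constant_level_sv_zero(self):
        x = np.r_[np.full(50, 2.0), np.random.default_rng(1).normal(size=50)]
        mask = np.r_[np.ones(50, bool), np.zeros(50, bool)]
        assert sr.scaled_variance(x, mask) == 0.0

    def test_zero_total_variance_error(self):
        with pytest.raises(ValueError):
            sr.scaled_variance(np.ones(10), np.r_[np.ones(5, bool), np.zeros(5, bool)])

    def test_asv_split_factor_low(self):
        x = np.r_[np.zeros(100), np.ones(100)]
        levels = ["a"] * 100 + ["b"] * 100
        assert sr.asv_homogeneity(x, levels) < 0.5

    def test_asv_independent_factor_near_one(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=400)
        levels = np.where(rng.random(400) < 0.5, "a", "b")
        assert sr.asv_homogeneity(x, levels) == pytest.approx(1.0, abs=0.1)

    def test_arithmetic_at_least_geometric(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            x = rng.normal(size=300)
            levels = rng.choice(["a", "b", "c"], 300)
            assert sr.asv_homogeneity(x, levels, "arithmetic") >= sr.asv_homogeneity(
                x, levels, "geometric"
            ) - 1e-12


class TestAffineInvariance:
    def test_separability_metrics_affine_invariant_variance_not(self):
        x, labels = _two_clusters(seed=5)
        y = 3.0 * x + 7.0
        assert sr.silhouette_sep(y, labels) == pytest.approx(
            sr.silhouette_sep(x, labels)
        )
        assert sr.vrs(y, labels) == pytest.approx(sr.vrs(x, labels))
        assert sr.wvrs(y, labels) == pytest.approx(sr.wvrs(x, labels))
        assert sr.davies_bouldin_scaled(y, labels) == pytest.approx(
            sr.davies_bouldin_scaled(x, labels)
        )
        bi_x, _ = sr.bimodality_index(x, seed=0)
        bi_y, _ = sr.bimodality_index(y, seed=0)
        assert bi_y == pytest.approx(bi_x, rel=0.05)
        assert dip_statistic(y) == pytest.approx(dip_statistic(x), abs=1e-12)
        assert sr.effect_size_variance(y) == pytest.approx(
            9 * sr.effect_size_variance(x)
        )


class TestFISTable:
    def test_duplicated_factor_identical_columns(self, fca_table, factor_model):
        scores = np.column_stack([factor_model.scores[:, :3], factor_model.scores[:, 0]])
        table = sr.build_fis_table(scores, None, None, seed=0)
        assert np.allclose(table.values.iloc[:, 0], table.values.iloc[:, 3])

    def test_planted_bimodal_beats_noise(self):
        rng = np.random.default_rng(0)
        noise = rng.normal(size=500)
        bimodal = np.r_[rng.normal(0, 0.5, 250), rng.normal(4, 0.5, 250)]
        table = sr.build_fis_table(np.column_stack([bimodal, noise]), None, None, seed=0)
        assert table.values.loc["silhouette", "F1"] > table.values.loc["silhouette", "F2"]
        assert table.values.loc["variance", "F1"] > table.values.loc["variance", "F2"]

    def test_row_scaling_maps_to_unit_interval(self, factor_model, fca_table, fixture_data):
        _, cov = fixture_data
        table = sr.build_fis_table(factor_model, fca_table, cov, seed=0)
        scaled = table.scaled()
        v = scaled.values.to_numpy()
        assert scaled.row_scaled
        assert v.min() >= 0 and v.max() <= 1
        assert np.allclose(v.max(axis=1), 1.0)
        assert np.allclose(v.min(axis=1), 0.0)
        expect_rows = {
            "silhouette",
            "bimodality_index",
            "variance",
            "simpson",
            "asv_arithmetic[line]",
            "asv_arithmetic[protocol]",
        }
        assert set(table.values.index) == expect_rows
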