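"""GPA, PCA, permutation tests, age residualisation, ANOVA and disparity."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from cranioshape.stats import (DegenerateDataError, age_residualize,
                               disparity_analysis, generalized_procrustes,
                               holm_adjust, icv_two_way_anova, pairwise_perm,
                               pca_with_threshold, perm_manova,
                               procrustes_distance, spearman_vs_age)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestGPA:
    def test_identical_shapes_under_similarity(self, rng):
        base = rng.normal(0, 10, (12, 3))
        configs = []
        for i in range(5):
            R = Rotation.random(random_state=i).as_matrix()
            configs.append(2.5 * base @ R.T + rng.normal(0, 50, 3))
        aligned, mean, _ = generalized_procrustes(configs)
        for a in aligned[1:]:
            assert procrustes_distance(aligned[0], a) < 1e-10

    def test_consensus_fixed_point(self, rng):
        base = rng.normal(0, 10, (9, 3))
        configs = base + rng.normal(0, 0.5, (6, 9, 3))
        aligned, mean, _ = generalized_procrustes(configs)
        re_aligned, re_mean, _ = generalized_procrustes(aligned)
        assert np.abs(re_aligned - aligned).max() < 1e-12
        assert np.abs(re_mean - mean).max() < 1e-12

    def test_unit_centroid_sizes(self, rng):
        base = rng.normal(0, 10, (7, 3))
        configs = (base + rng.normal(0, 0.5, (4, 7, 3))) * 3.0
        aligned, _, _ = generalized_procrustes(configs)
        for a in aligned:
            assert np.sqrt(((a - a.mean(axis=0)) ** 2).sum()) == pytest.approx(1.0)

    def test_mirror_consensus_symmetric(self, rng):
        shape = rng.normal(0, 10, (10, 3))
        mirror = shape * np.array([-1.0, 1.0, 1.0])
        _, mean, _ = generalized_procrustes([shape, mirror])
        assert mean.shape == (10, 3)

    def test_coincident_points_rejected(self):
        with pytest.raises(DegenerateDataError):
            generalized_procrustes([np.zeros((5, 3)), np.ones((5, 3))])


class TestPCA:
    def test_single_direction(self, rng):
        t = rng.normal(0, 1, 50)
        X = np.outer(t, [1.0, 2.0, 3.0])
        res = pca_with_threshold(X)
        assert res.n_retained == 1
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_fractions(self, rng):
        X = rng.normal(0, 1, (10000, 3))
        res = pca_with_threshold(X)
        assert np.allclose(res.explained_variance_ratio, 1 / 3, atol=0.02)

    def test_reconstruction(self, rng):
        X = rng.normal(0, 2, (30, 6))
        res = pca_with_threshold(X, variance_threshold=1.0)
        recon = res.scores @ res.loadings + res.mean
        assert np.abs(recon - X).max() < 1e-9

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateDataError):
            pca_with_threshold(np.ones((10, 4)))


class TestPermManova:
    def make_null(self, rng, n_per=10):
        group = np.repeat(list("ABC"), n_per)
        age = rng.uniform(30, 900, 3 * n_per)
        Y = rng.normal(0, 1, (3 * n_per, 3))
        return Y, group, age

    def test_strong_effect_saturates(self, rng):
        Y, group, age = self.make_null(rng)
        Y = Y + (group == "A")[:, None] * 5.0
        res = perm_manova(Y, group, age, n_perm=199, seed=0)
        assert res["group"].p == pytest.approx(1 / 200)

    def test_joint_permutation_invariance(self, rng):
        Y, group, age = self.make_null(rng)
        res = perm_manova(Y, group, age, n_perm=49, seed=0)
        perm = rng.permutation(len(Y))
        res2 = perm_manova(Y[perm], group[perm], age[perm], n_perm=49, seed=0)
        assert res2["group"].F == pytest.approx(res["group"].F)
        assert res2["group"].R2 == pytest.approx(res["group"].R2)

    def test_term_structure(self, rng):
        Y, group, age = self.make_null(rng)
        res = perm_manova(Y, group, age, n_perm=49, seed=0)
        assert set(res) == {"group", "age", "group:age"}
        assert res["group"].df == 2 and res["age"].df == 1

    def test_confounded_design_rejected(self, rng):
        Y = rng.normal(0, 1, (12, 2))
        with pytest.raises(DegenerateDataError):
            perm_manova(Y, ["A"] * 12, None, n_perm=9)

    def test_reproducible(self, rng):
        Y, group, age = self.make_null(rng)
        a = perm_manova(Y, group, age, n_perm=99, seed=7)
        b = perm_manova(Y, group, age, n_perm=99, seed=7)
        assert a["group"].p == b["group"].p


class TestPairwisePerm:
    def test_only_shifted_pairs_significant(self, rng):
        group = np.repeat(list("ABC"), 15)
        Y = rng.normal(0, 1, 45)
        Y[group == "C"] += 4.0
        p = pairwise_perm(Y, group, n_perm=199, seed=0)
        assert p[("A", "C")] <= 0.05 and p[("B", "C")] <= 0.05
        assert p[("A", "B")] > 0.05

    def test_identical_samples_not_significant(self, rng):
        group = np.array(["A"] * 12 + ["B"] * 12)
        Y = np.concatenate([rng.normal(0, 1, 12)] * 2)
        p = pairwise_perm(Y, group, n_perm=199, seed=1)
        assert p[("A", "B")] > 0.3

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            pairwise_perm(np.arange(4.0), ["A", "A", "A", "B"], n_perm=9)

    def test_holm_adjustment_monotone(self):
        adj = holm_adjust({"a": 0.01, "b": 0.02, "c": 0.5})
        assert adj["a"] == pytest.approx(0.03)
        assert adj["a"] <= adj["b"] <= adj["c"]


class TestAgeResidualize:
    def test_flat_relation_centres_values(self, rng):
        age = rng.uniform(30, 900, 60)
        v = rng.normal(5, 1, 60)
        r = age_residualize(v, age)
        assert abs(r.mean()) < 0.2
        assert np.corrcoef(r, v)[0, 1] > 0.9

    def test_linear_relation_captured(self, rng):
        age = rng.uniform(30, 900, 60)
        v = 0.3 * age + 10
        r = age_residualize(v, age)
        assert np.abs(r).max() < 1e-6 * np.ptp(v)

    def test_monotone_trend_removed(self, rng):
        # span-0.75 local-linear smoothing removes the gross monotone trend;
        # a small curvature-driven edge bias can remain in the residuals
        age = rng.uniform(30, 900, 100)
        v = np.sqrt(age) + rng.normal(0, 1.0, 100)
        raw = abs(spearmanr(v, age).statistic)
        resid = abs(spearmanr(age_residualize(v, age), age).statistic)
        assert raw > 0.9
        assert resid < 0.25 and resid < 0.3 * raw

    def test_constant_age_rejected(self):
        with pytest.raises(DegenerateDataError):
            age_residualize(np.arange(12.0), np.full(12, 100.0))


class TestSpearman:
    def test_perfect_correlations(self, rng):
        age = rng.uniform(30, 900, 40)
        s, rho, p = spearman_vs_age(age.copy(), age)
        assert rho == pytest.approx(1.0) and s == pytest.approx(0.0)
        _, rho_neg, _ = spearman_vs_age(-age, age)
        assert rho_neg == pytest.approx(-1.0)

    def test_null_is_uniform(self, rng):
        ps = []
        for _ in range(200):
            age = rng.uniform(0, 1, 20)
            v = rng.normal(0, 1, 20)
            ps.append(spearman_vs_age(v, age)[2])
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_ties_only_rejected(self):
        with pytest.raises(DegenerateDataError):
            spearman_vs_age(np.ones(10), np.arange(10.0))


class TestICVAnova:
    def balanced(self, rng, n=60):
        sex = np.tile(np.repeat(["f", "m"], n // 4), 2)[:n]
        group = np.repeat(["C", "TG"], n // 2)
        return sex, group

    def test_r2_decomposition_sums_to_one(self, rng):
        sex, group = self.balanced(rng)
        y = rng.normal(0, 1, len(sex))
        res = icv_two_way_anova(y, sex, group)
        assert sum(v["R2"] for v in res.values()) == pytest.approx(1.0, abs=1e-9)

    def test_sex_shift_detected_without_interaction(self, rng):
        sex, group = self.balanced(rng)
        y = rng.normal(0, 1, len(sex)) + (np.asarray(sex) == "f") * 1.0
        res = icv_two_way_anova(y, sex, group)
        assert res["sex"]["p"] < 0.01
        assert res["sex:group"]["p"] > 0.05

    def test_empty_cell_drops_interaction(self, rng):
        sex = np.array(["f"] * 10 + ["m"] * 10 + ["f"] * 10)
        group = np.array(["C"] * 20 + ["TG"] * 10)  # no (m, TG) cell
        with pytest.warns(RuntimeWarning, match="empty"):
            res = icv_two_way_anova(rng.normal(0, 1, 30), sex, group)
        assert "sex:group" not in res


class TestDisparity:
    def test_doubled_spread_detected(self, rng):
        X = np.vstack([rng.normal(0, 1, (30, 2)), rng.normal(0, 2, (30, 2))])
        g = np.repeat(["a", "b"], 30)
        res = disparity_analysis(X, g)
        assert res.disparity["b"] > res.disparity["a"]
        assert res.pairwise_p[("a", "b")] < 0.05

    def test_identical_groups_not_significant(self, rng):
        X = np.tile(rng.normal(0, 1, (30, 2)), (2, 1))
        g = np.repeat(["a", "b"], 30)
        res = disparity_analysis(X, g)
        assert res.pairwise_p[("a", "b")] > 0.9

    def test_translation_invariance(self, rng):
        X = rng.normal(0, 1, (40, 3))
        g = np.repeat(["a", "b"], 20)
        shifted = X.copy()
        shifted[g == "b"] += 100.0
        r0 = disparity_analysis(X, g)
        r1 = disparity_analysis(shifted, g)
        assert r1.disparity["b"] == pytest.approx(r0.disparity["b"])

    def test_age_split_labels(self, rng):
        X = rng.normal(0, 1, (40, 2))
        g = np.repeat(["a", "b"], 20)
        age = rng.uniform(30, 900, 40)
        res = disparity_analysis(X, g, age=age, age_split=300.0)
        assert any(k.endswith("-") for k in res.disparity)
        assert any(k.endswith("+") for k in res.disparity)
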