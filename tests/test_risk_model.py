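import math

import numpy as np
import pytest

from polyphasia.formats_io import GenotypeMatrix, VariantRecord
from polyphasia.risk_model import (auc_rank, confusion_from_counts,
                                   confusion_metrics, fit_risk_model,
                                   hclust_average, loocv, risk_scores,
                                   select_top_variants, variant_odds_ratios)
from polyphasia.synth_geno import GenoSimConfig, simulate_case_control


def matrix_from_counts(counts, phenotype):
    counts = np.asarray(counts, float)
    variants = [VariantRecord(chrom="1", pos=100 + j, ref="A", alt="G")
                for j in range(counts.shape[1])]
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(counts.shape[0])],
        variants=variants, counts=counts,
        phenotype=np.asarray(phenotype, bool))


class TestOddsRatios:
    def test_hand_arithmetic(self):
        # 16 cases: 10 alt/22 ref; 14 controls: 2 alt/26 ref
        case_counts = [2] * 2 + [1] * 6 + [0] * 8      # 10 alt alleles
        control_counts = [1] * 2 + [0] * 12            # 2 alt alleles
        m = matrix_from_counts(
            np.array(case_counts + control_counts)[:, None],
            [True] * 16 + [False] * 14)
        o = variant_odds_ratios(m)[0]
        assert (o.case_alt, o.case_ref) == (10, 22)
        assert (o.control_alt, o.control_ref) == (2, 26)
        assert o.odds_ratio == pytest.approx((10 * 26) / (22 * 2), rel=1e-12)
        assert o.risk_class == "high"

    def test_equal_frequencies_neutral(self):
        m = matrix_from_counts([[1], [1], [1], [1]],
                               [True, True, False, False])
        o = variant_odds_ratios(m)[0]
        assert o.odds_ratio == 1.0 and o.risk_class == "neutral"

    def test_label_swap_inverts_or(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 3, size=(20, 8)).astype(float)
        pheno = np.array([True] * 11 + [False] * 9)
        a = variant_odds_ratios(matrix_from_counts(counts, pheno))
        b = variant_odds_ratios(matrix_from_counts(counts, ~pheno))
        for oa, ob in zip(a, b):
            assert oa.odds_ratio == pytest.approx(1 / ob.odds_ratio, rel=1e-9)
            if oa.risk_class != "neutral":
                assert {oa.risk_class, ob.risk_class} == {"high", "low"}

    def test_haldane_correction_on_zero_cell(self):
        m = matrix_from_counts([[2], [2], [0], [0]],
                               [True, True, False, False])
        o = variant_odds_ratios(m)[0]
        # cells 4/0 | 0/4 -> +0.5 everywhere -> (4.5*4.5)/(0.5*0.5)
        assert o.odds_ratio == pytest.approx(81.0, rel=1e-12)

    def test_missing_drops_sample_for_that_variant(self):
        m = matrix_from_counts([[1, np.nan], [0, 1], [1, 0], [0, 0]],
                               [True, True, False, False])
        o2 = variant_odds_ratios(m)[1]
        assert o2.case_alt + o2.case_ref == 2  # one case genotype only


class TestSelection:
    def or_list(self, counts, pheno):
        return variant_odds_ratios(matrix_from_counts(counts, pheno))

    def test_identity_at_full_k(self):
        rng = np.random.default_rng(0)
        ors = self.or_list(rng.integers(0, 3, (10, 6)).astype(float),
                           [True] * 5 + [False] * 5)
        assert set(select_top_variants(ors, k=6)) == \
            {o.variant.key for o in ors}

    def test_strong_or_outranks_neutral(self):
        counts = np.array([[2, 1], [2, 1], [0, 1], [0, 1]], float)
        ors = self.or_list(counts, [True, True, False, False])
        top = select_top_variants(ors, k=1)
        assert top == [ors[0].variant.key]  # OR >> 1 beats OR = 1

    def test_hand_ranked_fixture(self):
        # 20 variants with strictly decreasing |log OR| by construction
        rng = np.random.default_rng(1)
        n = 40
        pheno = np.array([True] * 20 + [False] * 20)
        cols = []
        for j in range(20):
            p_case = 0.05 + 0.9 * (19 - j) / 19
            col = np.concatenate([
                rng.binomial(2, p_case, 20), rng.binomial(2, 0.05, 20)])
            cols.append(col)
        counts = np.column_stack(cols).astype(float)
        ors = self.or_list(counts, pheno)
        expected = [o.variant.key for o in
                    sorted(ors, key=lambda o: -abs(o.log_or))[:16]]
        assert select_top_variants(ors, k=16) == expected


class TestLogisticFit:
    def test_intercept_closed_form_with_constant_feature(self):
        # an uninformative constant variant is dropped; intercept-only model
        X = np.ones((10, 1))
        y = np.array([1] * 6 + [0] * 4, bool)
        fit = fit_risk_model(X, y, variant_keys=["v0"])
        assert fit.dropped_constant == ["v0"]
        assert fit.coefficients[0] == 0.0
        assert fit.intercept == pytest.approx(math.log(6 / 4), abs=1e-6)

    def test_balanced_single_variant_closed_form(self):
        # perfectly balanced design: slope 0, intercept log(n_case/n_ctrl)
        X = np.array([[0.0], [1.0], [2.0], [0.0], [1.0], [2.0]])
        y = np.array([1, 1, 1, 0, 0, 0], bool)
        fit = fit_risk_model(X, y)
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-6)
        assert fit.intercept == pytest.approx(0.0, abs=1e-6)

    def test_matches_sklearn_ridge_logistic(self):
        from sklearn.linear_model import LogisticRegression
        rng = np.random.default_rng(3)
        X = rng.binomial(2, 0.3, size=(60, 4)).astype(float)
        logits = X @ np.array([1.0, -0.5, 0.2, 0.0]) - 0.4
        y = rng.random(60) < 1 / (1 + np.exp(-logits))
        fit = fit_risk_model(X, y, ridge_lambda=1e-3)
        ref = LogisticRegression(C=1e3, tol=1e-10, max_iter=5000)
        ref.fit(X, y)
        np.testing.assert_allclose(fit.coefficients, ref.coef_[0], atol=1e-4)
        assert fit.intercept == pytest.approx(ref.intercept_[0], abs=1e-4)

    def test_parameter_recovery_at_n2000(self):
        rng = np.random.default_rng(4)
        X = rng.binomial(2, 0.3, size=(2000, 1)).astype(float)
        logits = 2.0 * X[:, 0] - 1.2
        y = rng.random(2000) < 1 / (1 + np.exp(-logits))
        fit = fit_risk_model(X, y)
        assert abs(fit.coefficients[0] - 2.0) / 2.0 < 0.10

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_risk_model(np.zeros((4, 1)), np.ones(4, bool))

    def test_separation_stays_finite(self):
        X = np.array([[2.0], [2.0], [0.0], [0.0]])
        y = np.array([1, 1, 0, 0], bool)
        fit = fit_risk_model(X, y)
        assert np.isfinite(fit.coefficients).all() and np.isfinite(fit.intercept)


class TestRiskScores:
    def test_all_zero_genotypes(self):
        fit = fit_risk_model(np.array([[0.], [1.], [2.], [0.]]),
                             np.array([1, 1, 0, 0], bool))
        u, w, r = risk_scores(np.zeros((3, 1)), fit)
        np.testing.assert_array_equal(w, 0.0)
        np.testing.assert_allclose(r, 1 / (1 + np.exp(-fit.intercept)))
        assert np.all(u == 0)

    def test_hand_computed_three_variant_example(self):
        from polyphasia.risk_model import FitResult
        fit = FitResult(intercept=-0.5,
                        coefficients=np.array([0.8, -0.3, 1.2]),
                        variant_keys=["a", "b", "c"])
        counts = np.array([[1.0, 2.0, 0.0]])
        u, w, r = risk_scores(counts, fit, risk_classes=["high", "low", "high"])
        assert w[0] == pytest.approx(0.8 * 1 - 0.3 * 2, abs=1e-12)
        assert u[0] == 1.0  # risk alleles at the two high-risk variants
        assert r[0] == pytest.approx(1 / (1 + math.exp(0.5 - 0.2)), rel=1e-12)

    def test_missing_contributes_zero(self):
        from polyphasia.risk_model import FitResult
        fit = FitResult(intercept=0.0, coefficients=np.array([1.0]),
                        variant_keys=["a"])
        _, w, _ = risk_scores(np.array([[np.nan]]), fit)
        assert w[0] == 0.0


class TestLOOCV:
    def small_matrix(self, seed=0):
        m, _ = simulate_case_control(
            GenoSimConfig(n_cases=8, n_controls=7, n_variants=20), seed=seed)
        return m

    def test_deterministic_repeat(self):
        m = self.small_matrix()
        a = loocv(m, k=5)
        b = loocv(m, k=5)
        np.testing.assert_array_equal(a.predicted_risks, b.predicted_risks)
        assert a.fold_selected == b.fold_selected

    def test_no_leakage_from_held_out_label(self):
        m = self.small_matrix(seed=1)
        base = loocv(m, k=5)
        i = 3
        corrupted = GenotypeMatrix(
            sample_ids=list(m.sample_ids), variants=list(m.variants),
            counts=m.counts.copy(), phenotype=m.phenotype.copy())
        corrupted.phenotype[i] = ~corrupted.phenotype[i]
        alt = loocv(corrupted, k=5)
        assert base.fold_selected[i] == alt.fold_selected[i]
        np.testing.assert_allclose(alt.fold_fits[i].coefficients,
                                   base.fold_fits[i].coefficients, atol=1e-9)
        assert alt.predicted_risks[i] == pytest.approx(
            base.predicted_risks[i], abs=1e-9)

    def test_pooled_is_union_of_folds(self):
        m = self.small_matrix(seed=2)
        res = loocv(m, k=5)
        assert set(res.pooled_variants) == set().union(*map(set,
                                                            res.fold_selected))

    def test_too_few_samples_rejected(self):
        m, _ = simulate_case_control(
            GenoSimConfig(n_cases=2, n_controls=2, n_variants=5), seed=0)
        sub = m.subset_samples([0, 1, 2])
        with pytest.raises(ValueError):
            loocv(sub, k=2)


class TestConfusionMetrics:
    def test_study_confusion_matrix(self):
        m = confusion_from_counts(tp=13, fp=2, tn=12, fn=3)
        assert m.accuracy == pytest.approx(83.33, abs=0.005)
        assert m.sensitivity == pytest.approx(81.25, abs=0.005)
        assert m.specificity == pytest.approx(85.71, abs=0.005)
        assert m.mcc == pytest.approx(0.67, abs=0.005)

    def test_perfect_separation(self):
        risks = np.array([0.9, 0.8, 0.1, 0.2])
        labels = np.array([True, True, False, False])
        m = confusion_metrics(risks, labels)
        assert (m.accuracy, m.mcc, m.auc) == (100.0, 1.0, 1.0)

    def test_permutation_auc_centers_at_half(self):
        rng = np.random.default_rng(0)
        risks = rng.random(30)
        aucs = []
        for _ in range(2000):
            labels = np.zeros(30, bool)
            labels[rng.choice(30, 16, replace=False)] = True
            aucs.append(auc_rank(risks, labels))
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.01)

    def test_single_class_labels(self):
        m = confusion_metrics(np.array([0.2, 0.9]), np.array([True, True]))
        assert m.specificity is None and m.auc is None
        assert m.sensitivity == 50.0

    def test_out_of_range_risks_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(np.array([1.5]), np.array([True]))


class TestClustering:
    def test_two_samples_merge_at_distance(self):
        merges, order = hclust_average(np.array([[0.0], [3.0]]), ["a", "b"])
        assert merges.shape == (1, 4)
        assert merges[0, 2] == pytest.approx(3.0)
        assert set(order) == {"a", "b"}

    def test_hand_computed_upgma_line(self):
        # points 0,1,10,11: merges (0,1) and (10,11) at height 1, then the
        # two pairs at the mean of the four inter-pair distances,
        # (10 + 11 + 9 + 10)/4 = 10
        merges, _ = hclust_average(np.array([[0.0], [1.0], [10.0], [11.0]]),
                                   list("abcd"))
        heights = sorted(merges[:, 2])
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(1.0)
        assert heights[2] == pytest.approx(10.0)

    def test_heights_monotone_and_permutation_stable(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(12, 2))
        ids = [f"s{i}" for i in range(12)]
        merges, _ = hclust_average(pts, ids)
        assert np.all(np.diff(merges[:, 2]) >= -1e-12)
        perm = rng.permutation(12)
        merges2, _ = hclust_average(pts[perm], [ids[i] for i in perm])
        np.testing.assert_allclose(sorted(merges[:, 2]),
                                   sorted(merges2[:, 2]), atol=1e-9)

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            hclust_average(np.array([[0.0], [1.0]]), ["a", "a"])
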