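import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import (auc_bruteforce, bh_stepup_oracle,
                      delong_variance_oracle, youden_bruteforce)
from preclad import discrimination as disc


class TestRocAuc:
    def test_small_example_three_concordant_of_four_pairs(self):
        res = disc.roc_auc([1, 3, 2, 4], [0, 0, 1, 1])
        assert res.auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = disc.roc_auc([0, 0, 1, 1], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_all_tied_scores(self):
        res = disc.roc_auc([2, 2, 2, 2], [0, 1, 0, 1])
        assert res.auc == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            disc.roc_auc([1, 2, 3], [1, 1, 1])

    def test_variance_shrinks_with_n(self, rng):
        vars_ = []
        for n in (100, 200, 400, 800):
            s = rng.normal(0, 1, n)
            y = (rng.random(n) < 0.5).astype(int)
            y[:2] = [0, 1]
            s[y == 1] += 1.0
            vars_.append(disc.roc_auc(s, y).auc_var)
        assert vars_[0] > vars_[1] > vars_[2] > vars_[3]

    def test_ci_within_unit_interval(self, rng):
        s = rng.normal(0, 1, 50)
        y = (rng.random(50) < 0.3).astype(int)
        y[:2] = [0, 1]
        r = disc.roc_auc(s, y)
        assert 0 <= r.ci_low <= r.auc <= r.ci_high <= 1


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_auc_equals_pair_counting_property(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(4, 50))
    scores = r.integers(0, 8, n).astype(float)  # many ties
    labels = r.integers(0, 2, n)
    labels[:2] = [0, 1]
    assert disc.roc_auc(scores, labels).auc == pytest.approx(
        auc_bruteforce(scores, labels), abs=1e-12)


class TestDeLong:
    def test_identical_scores_degenerate(self, rng):
        s = rng.normal(0, 1, 40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        res = disc.delong_test(s, s, y)
        assert res.p == 1.0 and res.delta_auc == 0.0 and res.degenerate

    def test_monotone_transform_degenerate(self, rng):
        s = rng.normal(0, 1, 40)
        y = (rng.random(40) < 0.5).astype(int)
        y[:2] = [0, 1]
        res = disc.delong_test(s, np.exp(2.0 * s), y)
        assert res.p == 1.0 and res.delta_auc == 0.0

    def test_symmetry_under_model_swap(self, rng):
        s1 = rng.normal(0, 1, 60)
        s2 = s1 + rng.normal(0, 1, 60)
        y = (rng.random(60) < 0.4).astype(int)
        y[:2] = [0, 1]
        a = disc.delong_test(s1, s2, y)
        b = disc.delong_test(s2, s1, y)
        assert a.z == pytest.approx(-b.z)
        assert a.p == pytest.approx(b.p)

    def test_variance_matches_placement_oracle(self, rng):
        n = 30
        y = np.array([0, 1] * 15)
        s1 = rng.normal(0, 1, n) + y
        s2 = 0.5 * s1 + rng.normal(0, 1, n)
        res = disc.delong_test(s1, s2, y)
        var = delong_variance_oracle(s1, s2, y)
        # z = dAUC / sqrt(var): recover var from the statistic
        assert (res.delta_auc / res.z) ** 2 == pytest.approx(var, abs=1e-10)

    def test_null_calibration_small(self, rng):
        # correlated but uninformative scores: ~5% nominal rejections
        rejections = 0
        reps = 400
        for _ in range(reps):
            u = rng.normal(0, 1, 120)
            s1 = u + rng.normal(0, 1, 120)
            s2 = u + rng.normal(0, 1, 120)
            y = np.zeros(120, int)
            y[:60] = 1
            if disc.delong_test(s1, s2, y).p < 0.05:
                rejections += 1
        assert 0.02 <= rejections / reps <= 0.09


class TestOperatingPoints:
    def test_perfect_separation_both_points_perfect(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        s = np.array([1, 2, 3, 7, 8, 9], float)
        youden, fixed = disc.operating_points(s, y)
        assert youden.sensitivity == youden.specificity == 1.0
        assert fixed.sensitivity == 1.0 and fixed.specificity == 1.0

    def test_all_tied_scores_zero_j(self):
        y = np.array([0, 1, 0, 1])
        s = np.ones(4)
        youden, _ = disc.operating_points(s, y)
        assert youden.sensitivity + youden.specificity - 1 == pytest.approx(0.0)

    def test_youden_matches_bruteforce(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 40))
            s = rng.integers(0, 10, n).astype(float)
            y = rng.integers(0, 2, n)
            y[:2] = [0, 1]
            youden, _ = disc.operating_points(s, y)
            j, cut, sens, spec = youden_bruteforce(s, y)
            assert youden.sensitivity + youden.specificity - 1 == pytest.approx(j)
            assert youden.specificity == pytest.approx(spec)

    def test_fixed_sensitivity_reached(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            s = rng.normal(0, 1, n)
            y = rng.integers(0, 2, n)
            y[:7] = 1
            y[7:9] = 0
            _, fixed = disc.operating_points(s, y)
            assert fixed.sensitivity >= 0.85
            assert fixed.attained


class TestRiskModel:
    def test_intercept_only_scores_uninformative(self, rng):
        y = np.array([0, 1] * 20)
        X = np.ones((40, 1))  # constant predictor: separation-free flat fit
        scores, info = disc.fit_risk_model(y, X)
        assert np.allclose(scores, scores[0])
        assert disc.roc_auc(scores, y).auc == 0.5

    def test_perfect_separation_flagged_auc_one(self):
        y = np.array([0] * 10 + [1] * 10)
        X = np.arange(20.0)[:, None]
        scores, info = disc.fit_risk_model(y, X)
        assert info["separation"]
        assert disc.roc_auc(scores, y).auc == 1.0

    def test_coefficient_recovery(self, rng):
        n = 2000
        X = rng.normal(0, 1, (n, 2))
        eta = -0.3 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        _, info = disc.fit_risk_model(y, X)
        est = info["params"]
        assert est[1] == pytest.approx(1.2, rel=0.15)
        assert est[2] == pytest.approx(-0.7, rel=0.15)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            disc.fit_risk_model(np.ones(10, int), np.random.rand(10, 1))


class TestFdr:
    def test_single_p_unchanged(self):
        assert disc.fdr_adjust([0.37])[0] == pytest.approx(0.37)

    def test_hand_computed_stepup(self):
        # p*m/rank = [.04,.04,.04,.04]; cumulative minimum keeps .04
        adj = disc.fdr_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, 0.04)

    def test_all_ones(self):
        assert np.allclose(disc.fdr_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            disc.fdr_adjust([0.5, 1.2])


@settings(deadline=None, max_examples=60, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_fdr_matches_oracle_and_preserves_order(seed):
    r = np.random.default_rng(seed)
    p = r.random(int(r.integers(1, 25)))
    adj = disc.fdr_adjust(p)
    assert np.allclose(adj, bh_stepup_oracle(p), atol=1e-12)
    assert (adj >= p - 1e-12).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(adj[order]) >= -1e-12).all()


class TestModelComparisonTable:
    def test_row_count_base_plus_twelve(self, preprocessed):
        pre, _ = preprocessed
        tab = disc.model_comparison_table(pre, "csf")
        assert len(tab) == 13  # base + 6 alone + 6 combined

    def test_age_stratification_adds_strata(self, preprocessed):
        pre, _ = preprocessed
        tab = disc.model_comparison_table(pre, "csf", age_cutoff=65.0)
        assert set(tab.stratum) == {"all", "age<=65", "age>65"}

    def test_fdr_at_least_raw(self, preprocessed):
        pre, _ = preprocessed
        tab = disc.model_comparison_table(pre, "cl30")
        m = tab.p_vs_base.notna()
        assert (tab.p_fdr[m] >= tab.p_vs_base[m] - 1e-12).all()

    def test_single_class_stratum_skipped_with_warning(self, preprocessed):
        pre, _ = preprocessed
        young = pre[pre.age < pre.age.quantile(0.1)].copy()
        young.loc[:, "csf_ab4240"] = 0.05  # everyone positive
        with pytest.warns(UserWarning, match="single"):
            tab = disc.model_comparison_table(young, "csf")
        assert len(tab) == 0

    def test_render_plain_text(self, preprocessed):
        pre, _ = preprocessed
        txt = disc.render_table(disc.model_comparison_table(pre, "csf"))
        assert "base_risk_factors" in txt and "AUC" in txt
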