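"""Evaluation analytics: error indices, reliability, savings, validity."""

import numpy as np
import pytest

from catia.evaluation import (
    DiagnosticRule,
    apply_diagnostic_rule,
    concurrent_validity,
    conditional_stats,
    marginal_reliability,
    roc_predictive_validity,
    savings_and_correlations,
)
from catia.cat import CATRecord, CATStep
from catia.grm import ThetaEstimate
from catia.responses import ResponseMatrix


def fake_record(theta, se, n_used):
    steps = tuple(CATStep(f"I-{k}", 0, theta, se) for k in range(n_used))
    return CATRecord(ThetaEstimate(theta, se, n_used, tuple(s.item_id for s in steps)),
                     steps, "se_reached")


class TestConditionalStats:
    def test_perfect_estimates_have_zero_error(self):
        th = np.linspace(-2, 2, 100)
        cs = conditional_stats(th, th, np.full(100, 0.2))
        assert cs.cbias == cs.cmae == cs.crmse == 0.0
        assert cs.csee == pytest.approx(0.2)

    def test_constant_shift(self):
        th = np.linspace(-2, 2, 100)
        cs = conditional_stats(th, th + 0.1, np.full(100, 0.3))
        assert cs.cbias == pytest.approx(0.1)
        assert cs.cmae == pytest.approx(0.1)
        assert cs.crmse == pytest.approx(0.1)

    def test_error_inequalities_hold_per_bin(self):
        rng = np.random.default_rng(5)
        th = rng.standard_normal(2000)
        est = th + rng.normal(0, 0.3, 2000)
        cs = conditional_stats(th, est, np.full(2000, 0.3))
        assert cs.crmse >= cs.cmae >= abs(cs.cbias)
        filled = cs.bin_counts > 0
        assert np.all(cs.bin_crmse[filled] >= cs.bin_cmae[filled] - 1e-12)
        assert np.all(cs.bin_cmae[filled] >= np.abs(cs.bin_cbias[filled]) - 1e-12)

    def test_empty_bins_are_missing_not_zero(self):
        th = np.zeros(10)
        cs = conditional_stats(th, th, np.ones(10))
        assert np.isnan(cs.bin_cmae[0])
        assert cs.bin_counts[0] == 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            conditional_stats(np.zeros(3), np.zeros(4), np.ones(4))


class TestMarginalReliability:
    @pytest.mark.parametrize(
        "mean_se,expected", [(0.159, 0.975), (0.203, 0.959), (0.293, 0.914),
                             (0.380, 0.856), (0.454, 0.794)]
    )
    def test_published_reliability_column(self, mean_se, expected):
        """MR = 1 - (mean SE)^2 reproduces the instrument's reliability table."""
        assert round(marginal_reliability([mean_se]), 3) == expected

    def test_zero_error_limit(self):
        assert marginal_reliability(np.zeros(5)) == 1.0

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            marginal_reliability([])


class TestSavings:
    def test_reference_against_itself(self):
        recs = [fake_record(t, 0.2, 59) for t in np.linspace(-1, 1, 20)]
        summary = savings_and_correlations({"none": recs}, 59)
        row = summary.rows[0]
        assert row["r_vs_full_bank"] == pytest.approx(1.0)
        assert row["savings_pct"] == 0.0

    def test_printed_item_usage_gives_printed_savings(self):
        # 131 persons at 28 items + 69 at 27 -> mean 27.655 on a 59-item bank
        used = np.r_[np.full(131, 28), np.full(69, 27)]
        assert used.mean() == pytest.approx(27.655)
        thetas = np.linspace(-1, 1, 200)
        recs_full = [fake_record(t, 0.16, 59) for t in thetas]
        recs = [fake_record(t, 0.2, int(u)) for t, u in zip(thetas, used)]
        summary = savings_and_correlations({"none": recs_full, "se<=0.2": recs}, 59)
        row = next(r for r in summary.rows if r["rule"] == "se<=0.2")
        assert round(row["savings_pct"], 1) == 53.1

    def test_mismatched_person_sets_raise(self):
        a = [fake_record(0.0, 0.2, 10)] * 5
        b = [fake_record(0.0, 0.2, 10)] * 6
        with pytest.raises(ValueError):
            savings_and_correlations({"none": a, "se<=0.3": b}, 59)


class TestConcurrentValidity:
    def test_perfectly_aligned_score(self):
        rng = np.random.default_rng(8)
        scores = rng.integers(0, 5, (200, 6))
        rm = ResponseMatrix(tuple(f"IAT-{j}" for j in range(6)), scores)
        sums = (scores + 1).sum(axis=1).astype(float)
        z = (sums - sums.mean()) / sums.std()
        out = concurrent_validity(z, rm)
        assert out["IAT"]["r"] == pytest.approx(1.0)

    def test_invariant_to_linear_rescaling(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 5, (150, 4))
        rm = ResponseMatrix(tuple(f"GAS-{j}" for j in range(4)), scores)
        theta = rng.standard_normal(150)
        r1 = concurrent_validity(theta, rm)["GAS"]["r"]
        r2 = concurrent_validity(3.0 * theta + 11.0, rm)["GAS"]["r"]
        assert r1 == pytest.approx(r2)

    def test_zero_variance_sum_reported_undefined(self):
        rm = ResponseMatrix(("CIAT-1",), np.full((30, 1), 2))
        out = concurrent_validity(np.random.default_rng(1).standard_normal(30), rm)
        assert out["CIAT"]["undefined"]


class TestROC:
    def test_perfect_separation(self):
        theta = np.r_[np.linspace(-2, -1, 50), np.linspace(1, 2, 50)]
        labels = np.r_[np.zeros(50), np.ones(50)]
        out = roc_predictive_validity(theta, labels)
        assert out["auc"] == 1.0
        assert out["youden"] == pytest.approx(1.0)

    def test_null_predictor_near_half(self):
        rng = np.random.default_rng(10)
        theta = rng.standard_normal(2000)
        labels = rng.integers(0, 2, 2000)
        out = roc_predictive_validity(theta, labels)
        n1, n0 = labels.sum(), 2000 - labels.sum()
        se = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
        assert abs(out["auc"] - 0.5) <= 3 * se

    def test_rank_formula_equals_pairwise_enumeration(self):
        """AUC via midranks is exactly the mean pairwise win rate with ties at 1/2."""
        rng = np.random.default_rng(11)
        theta = np.round(rng.standard_normal(300), 1)  # heavy ties
        labels = (rng.random(300) < 0.4).astype(int)
        out = roc_predictive_validity(theta, labels)
        pos, neg = theta[labels == 1], theta[labels == 0]
        brute = np.mean(
            [(x > neg).mean() + 0.5 * (x == neg).mean() for x in pos]
        )
        assert out["auc"] == pytest.approx(brute, abs=1e-12)

    def test_delong_ci_available(self):
        rng = np.random.default_rng(12)
        theta = rng.standard_normal(200)
        labels = (theta + rng.standard_normal(200) > 0).astype(int)
        hm = roc_predictive_validity(theta, labels)
        dl = roc_predictive_validity(theta, labels, ci_method="delong")
        assert hm["auc"] == dl["auc"]
        assert dl["ci95"][0] < dl["auc"] < dl["ci95"][1]

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_predictive_validity(np.ones(10), np.ones(10))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(13)
        theta = np.round(rng.standard_normal(500), 1)
        labels = (theta + rng.standard_normal(500) > 0.3).astype(int)
        out = roc_predictive_validity(theta, labels)
        assert out["auc"] == pytest.approx(roc_auc_score(labels, theta), abs=1e-12)


class TestDiagnosticRules:
    def _rm(self, rows, prefix="IAT", n_items=None):
        rows = np.asarray(rows)
        n_items = n_items or rows.shape[1]
        ids = tuple(f"{prefix}-{j}" for j in range(n_items))
        return ResponseMatrix(ids, rows), ids

    def test_low_scores_are_negative(self):
        rm, ids = self._rm(np.zeros((3, 20), dtype=int))
        rule = DiagnosticRule("sum_gt", ids, threshold=39)
        assert not apply_diagnostic_rule(rm, rule).any()

    def test_boundary_sum_is_strictly_negative(self):
        # sum of exactly 39 (1-5 coding) must not be diagnosed: "exceed" is strict
        scores_1based = np.array([2] * 19 + [1])
        assert scores_1based.sum() == 39
        rm, ids = self._rm((scores_1based - 1)[None, :])
        rule = DiagnosticRule("sum_gt", ids, threshold=39)
        assert not apply_diagnostic_rule(rm, rule)[0]
        scores_1based[-1] = 2  # sum 40 -> positive
        rm, ids = self._rm((scores_1based - 1)[None, :])
        assert apply_diagnostic_rule(rm, rule)[0]

    def test_count_rule_on_designated_items(self):
        scores_1based = np.array([[5, 5, 5, 5, 1, 1, 1], [5, 5, 5, 1, 1, 1, 1]])
        rm, ids = self._rm(scores_1based - 1, prefix="GAS")
        rule = DiagnosticRule("count_ge", ids, score=4, count=4)
        labels = apply_diagnostic_rule(rm, rule)
        assert labels[0] and not labels[1]

    def test_missing_items_listed(self):
        rm, ids = self._rm(np.zeros((2, 3), dtype=int))
        rule = DiagnosticRule("sum_gt", ids + ("IAT-99",))
        with pytest.raises(KeyError, match="IAT-99"):
            apply_diagnostic_rule(rm, rule)
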