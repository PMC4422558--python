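"""Validation pipeline: predictions, regression, group comparison, rank test."""

import itertools
import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sp_stats

from cocarbon import (
    CompositionModel,
    GrowthTable,
    PairObservation,
    PredictionRecord,
    group_deviation_summary,
    mann_whitney_exact,
    predict_pairs,
    regress_measured_on_predicted,
    run_full_analysis,
    write_report,
)


def find_record(records, s1, s2):
    key = {s1, s2}
    return next(r for r in records if {r.substrate_1, r.substrate_2} == key)


def make_records(xy, group="A"):
    return [
        PredictionRecord(
            substrate_1=f"u{i}", substrate_2=f"l{i}", group=group,
            measured=y, predicted=x,
            relative_deviation=abs(y - x) / x,
        )
        for i, (x, y) in enumerate(xy)
    ]


class TestPredictPairs:
    def test_printed_table_predictions(self, table1, model):
        records = predict_pairs(table1, model)
        assert len(records) == 22
        succ_man = find_record(records, "succinate", "mannose")
        assert succ_man.predicted == pytest.approx(0.6385838250607427, abs=1e-9)
        assert succ_man.measured == 0.64
        glyc_gluc = find_record(records, "glycerol", "glucose")
        assert glyc_gluc.group == "B"
        assert glyc_gluc.predicted == pytest.approx(0.9247352178743365, abs=1e-9)
        assert glyc_gluc.measured == 0.84

    def test_perfect_prediction_has_zero_deviation(self, model):
        from cocarbon import compose_growth_rates

        mixed = compose_growth_rates([0.4, 0.6], model)
        table = GrowthTable(
            singles={"a": 0.4, "b": 0.6},
            pairs=(PairObservation("a", "b", mixed, "A"),),
        )
        (rec,) = predict_pairs(table, model)
        assert rec.relative_deviation == pytest.approx(0.0, abs=1e-12)

    def test_denominator_switch(self, table1, model):
        by_pred = predict_pairs(table1, model, denominator="predicted")
        by_meas = predict_pairs(table1, model, denominator="measured")
        for p, m in zip(by_pred, by_meas):
            assert p.relative_deviation * p.predicted == pytest.approx(
                m.relative_deviation * m.measured, rel=1e-12
            )

    def test_missing_single_rate_is_constructor_error(self):
        with pytest.raises(ValueError, match="no declared single rate"):
            GrowthTable(
                singles={"a": 0.4},
                pairs=(PairObservation("a", "sorbitol", 0.5, "A"),),
            )


class TestRegression:
    def test_hand_computed_line(self):
        records = make_records([(0.5, 0.5), (0.6, 0.7), (0.7, 0.9)])
        res = regress_measured_on_predicted(records)
        assert res.slope == pytest.approx(2.0, abs=1e-10)
        assert res.offset == pytest.approx(-0.5, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_identity_line(self):
        records = make_records([(0.4, 0.4), (0.6, 0.6), (0.8, 0.8), (0.9, 0.9)])
        res = regress_measured_on_predicted(records)
        assert res.slope == pytest.approx(1.0, abs=1e-10)
        assert res.offset == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_group_a_statistics_match_published(self, table1, model):
        records = predict_pairs(table1, model)
        res = regress_measured_on_predicted(records, group_filter="A")
        assert res.n == 15
        assert res.slope == pytest.approx(0.99, abs=0.005)
        assert res.offset == pytest.approx(0.00, abs=0.005)
        assert res.r_squared == pytest.approx(0.92, abs=0.005)
        assert res.slope_ci_95[0] < res.slope < res.slope_ci_95[1]
        assert res.offset_ci_95[0] < res.offset < res.offset_ci_95[1]

    def test_too_few_records(self):
        with pytest.raises(ValueError):
            regress_measured_on_predicted(make_records([(0.5, 0.5), (0.6, 0.7)]))

    def test_exchanged_axes_slope_product_is_r_squared(self, table1, model):
        records = [r for r in predict_pairs(table1, model) if r.group == "A"]
        forward = regress_measured_on_predicted(records)
        swapped = [
            PredictionRecord(
                substrate_1=r.substrate_1, substrate_2=r.substrate_2, group=r.group,
                measured=r.predicted, predicted=r.measured,
                relative_deviation=r.relative_deviation,
            )
            for r in records
        ]
        backward = regress_measured_on_predicted(swapped)
        assert forward.slope * backward.slope == pytest.approx(
            forward.r_squared, abs=1e-10
        )


def brute_force_mw(a, b):
    """Enumerate all group assignments of the pooled data; oracle for the DP."""
    pooled = np.concatenate([a, b])
    ranks = sp_stats.rankdata(pooled)
    n_a = len(a)
    r_obs = ranks[:n_a].sum()
    sums = [sum(ranks[list(c)]) for c in itertools.combinations(range(len(pooled)), n_a)]
    sums = np.array(sums)
    p_le = np.mean(sums <= r_obs + 1e-9)
    p_ge = np.mean(sums >= r_obs - 1e-9)
    return min(1.0, 2 * min(p_le, p_ge))


class TestMannWhitney:
    def test_single_tied_pair(self):
        res = mann_whitney_exact([5], [5])
        assert res.p_two_sided == 1.0
        assert res.u_statistic == 0.5

    def test_complete_separation_two_by_two(self):
        res = mann_whitney_exact([1, 2], [3, 4])
        assert res.u_statistic == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_agrees_with_scipy_exact_without_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(size=rng.integers(2, 8))
            ours = mann_whitney_exact(a, b)
            ref = sp_stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.u_statistic == pytest.approx(float(ref.statistic))
            assert ours.p_two_sided == pytest.approx(float(ref.pvalue), rel=1e-9)

    @given(
        a=st.lists(st.integers(0, 4), min_size=1, max_size=5),
        b=st.lists(st.integers(0, 4), min_size=1, max_size=5),
    )
    @settings(derandomize=True, max_examples=150)
    def test_matches_enumeration_with_ties(self, a, b):
        ours = mann_whitney_exact(a, b)
        assert ours.p_two_sided == pytest.approx(brute_force_mw(a, b), rel=1e-9)

    def test_large_samples_fall_back_to_normal(self):
        rng = np.random.default_rng(1)
        res = mann_whitney_exact(rng.normal(size=20), rng.normal(size=20))
        assert res.method == "normal"
        assert 0 < res.p_two_sided <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestGroupComparison:
    def test_published_group_means_and_p(self, table1, model):
        records = predict_pairs(table1, model)
        cmp_ = group_deviation_summary(records)
        assert round(100 * cmp_.mean_dev_a) == 3
        assert round(100 * cmp_.mean_dev_b) == 12
        assert cmp_.p_two_sided < 2e-5
        assert cmp_.method == "exact"
        assert cmp_.u_statistic == 0.0  # complete separation of the deviations

    def test_identical_groups_give_p_one(self):
        records = make_records([(0.5, 0.55), (0.6, 0.66)], group="A") + make_records(
            [(0.5, 0.55), (0.6, 0.66)], group="B"
        )
        assert group_deviation_summary(records).p_two_sided == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_deviation_summary(make_records([(0.5, 0.5)] * 4, group="A"))


class TestTableInvariants:
    def test_group_a_mixed_rates_exceed_both_singles(self, table1):
        for pair in table1.group("A"):
            assert pair.rate > table1.singles[pair.substrate_1]
            assert pair.rate > table1.singles[pair.substrate_2]

    def test_predictions_below_speed_limit_and_subadditive(self, table1, model):
        for r in predict_pairs(table1, model):
            assert r.predicted < model.lambda_c
            assert r.predicted < table1.singles[r.substrate_1] + table1.singles[r.substrate_2]

    def test_duplicate_pair_rejected(self):
        with pytest.raises(ValueError, match="more than once"):
            GrowthTable(
                singles={"a": 0.4, "b": 0.6},
                pairs=(
                    PairObservation("a", "b", 0.7, "A"),
                    PairObservation("b", "a", 0.7, "A"),
                ),
            )


class TestFullAnalysis:
    def test_report_bundles_everything(self, table1, model, tmp_path):
        report = run_full_analysis(table1, model)
        assert all(report.property_checks.values())
        csv_path, json_path = write_report(report, tmp_path)
        payload = json.loads(json_path.read_text())
        assert payload["regression_group_a"]["n"] == 15
        assert payload["group_comparison"]["method"] == "exact"
        # deviation means recomputed across the constant's +/- 0.05/h band
        assert set(payload["lambda_c_sensitivity"]) == {"1.11", "1.21"}
        for entry in payload["lambda_c_sensitivity"].values():
            assert 0 < entry["mean_relative_deviation_a"] < 0.10
        import pandas as pd

        frame = pd.read_csv(csv_path)
        assert len(frame) == 22
        assert set(frame["group"]) == {"A", "B"}

    def test_errors_propagate(self, model):
        table = GrowthTable(
            singles={"a": 0.4, "b": 0.6},
            pairs=(PairObservation("a", "b", 0.7, "A"),),
        )
        with pytest.raises(ValueError):  # only one group-A record, no group B
            run_full_analysis(table, model)
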