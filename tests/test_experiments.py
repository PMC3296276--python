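"""The four in-silico experiments and their contracted ensemble phenotypes.

The shared session fixtures provide 100-run baseline/protected ensembles
and 60-run intervention-timing conditions under common random numbers;
Monte-Carlo comparisons use overlap of 95% confidence intervals of
end-of-run means.
"""

import numpy as np
import pytest

import adcycle as a
from adcycle.experiments import (
    CalibrationError,
    NO_INTERVENTION,
    condition_seed,
    close_to_zero,
    run_baseline,
    run_binding_block,
    run_clearance_sweep,
    run_ros_block,
)

from conftest import SEED, ci_overlap, end_mean, end_se


class TestBaselineCalibration:
    def test_majority_form_both_aggregates(self, baseline_records):
        n = len(baseline_records)
        both = sum(r.first_passage["first_plaque"] is not None
                   and r.first_passage["first_tangle"] is not None
                   for r in baseline_records) / n
        assert both > 0.5

    def test_nonzero_minority_form_neither(self, baseline_records):
        none = sum(r.first_passage["first_plaque"] is None
                   and r.first_passage["first_tangle"] is None
                   for r in baseline_records)
        assert none > 0

    def test_tangles_precede_plaques_in_the_ensemble_median(self, baseline_summary):
        assert baseline_summary.median_first_tangle is not None
        assert baseline_summary.median_first_plaque is not None
        assert (baseline_summary.median_first_tangle
                < baseline_summary.median_first_plaque)

    def test_single_run_summary_is_that_run(self):
        summary = run_baseline(1, base_seed=5)
        assert summary.n_runs == 1
        assert np.all(summary.sd_series["total_p53"] == 0)

    def test_miscalibrated_network_trips_the_contract_check(self):
        # without oligomerisation the cycle cannot ignite: no aggregates form
        with pytest.raises(CalibrationError):
            run_baseline(100, base_seed=SEED, params={"k_oligomer": 0.0},
                         check_calibration=True)


class TestProtectedCondition:
    def test_day0_boost_prevents_all_aggregation(self, day0_records):
        for r in day0_records:
            assert np.all(r.series["abeta_plaque"] == 0)
            assert np.all(r.series["tau_tangles"] == 0)

    def test_day0_p53_stays_at_basal_levels(self, day0_records, baseline_records):
        protected_end = end_mean(day0_records, "total_p53")
        baseline_end = end_mean(baseline_records, "total_p53")
        assert protected_end < 0.05 * baseline_end


class TestClearanceSweep:
    def test_end_plaque_burden_increases_with_intervention_day(
            self, day0_records, day2_records, day4_records, day6_records,
            day8_records, baseline_records):
        ordered = [day0_records, day2_records, day4_records, day6_records,
                   day8_records, baseline_records]
        means = [end_mean(r, "abeta_plaque") for r in ordered]
        ses = [end_se(r, "abeta_plaque") for r in ordered]
        for i in range(len(means) - 1):
            # non-decreasing within Monte-Carlo error
            slack = 1.96 * (ses[i] + ses[i + 1])
            assert means[i] <= means[i + 1] + slack

    def test_day2_leaves_traces_of_tau_and_ros_but_no_plaques(
            self, day2_records, baseline_records):
        tangles = end_mean(day2_records, "tau_tangles")
        assert 0 < tangles < 0.5 * end_mean(baseline_records, "tau_tangles")
        assert end_mean(day2_records, "ROS") > 0
        assert close_to_zero(end_mean(day2_records, "abeta_plaque"),
                             end_mean(baseline_records, "abeta_plaque"))

    def test_late_intervention_does_not_significantly_reduce_tangles(
            self, day6_records, day8_records, baseline_records):
        assert ci_overlap(day6_records, baseline_records, "tau_tangles")
        assert ci_overlap(day8_records, baseline_records, "tau_tangles")

    def test_late_intervention_still_lowers_plaques(
            self, day8_records, baseline_records):
        gap = end_mean(baseline_records, "abeta_plaque") - end_mean(
            day8_records, "abeta_plaque")
        assert gap > 1.96 * (end_se(baseline_records, "abeta_plaque")
                             + end_se(day8_records, "abeta_plaque"))

    def test_condition_order_does_not_change_results(self):
        forward = run_clearance_sweep([2, NO_INTERVENTION], n_runs=3,
                                      base_seed=SEED)
        backward = run_clearance_sweep([NO_INTERVENTION, 2], n_runs=3,
                                       base_seed=SEED)
        for label in (2.0, NO_INTERVENTION):
            for key in forward[label].mean_series:
                assert np.array_equal(forward[label].mean_series[key],
                                      backward[label].mean_series[key])

    def test_rejects_day_outside_horizon(self):
        with pytest.raises(ValueError):
            run_clearance_sweep([42], n_runs=1, base_seed=0)


@pytest.fixture(scope="module")
def ros_block_summary():
    return run_ros_block(40, base_seed=SEED, check_calibration=False)


@pytest.fixture(scope="module")
def binding_block_records():
    model = a.apply_intervention(a.build_default_network(),
                                 a.InterventionSpec("binding_block"))
    records, _ = a.run_ensemble(model, 40, SEED, 0.05)
    return records


class TestRosBlockade:

    def test_pathology_species_end_close_to_zero(self, ros_block_summary,
                                                 baseline_summary):
        for obs in ("abeta_plaque", "tau_tangles", "damDNA", "GSK3b_p53"):
            value = float(ros_block_summary.mean_series[obs][-1])
            reference = float(baseline_summary.mean_series[obs][-1])
            assert close_to_zero(value, reference), (obs, value, reference)

    def test_results_match_day0_clearance_condition(self, ros_block_summary,
                                                    day0_records):
        day0_p53 = end_mean(day0_records, "total_p53")
        blocked_p53 = float(ros_block_summary.mean_series["total_p53"][-1])
        assert abs(blocked_p53 - day0_p53) < 0.25 * day0_p53

    def test_without_any_stress_source_damage_is_identically_zero(self):
        summary = run_ros_block(1, base_seed=1, params={"k_ros_basal": 0.0})
        assert np.all(summary.mean_series["damDNA"] == 0)


class TestBindingBlockade:
    def test_no_plaques_or_tangles(self, binding_block_records, baseline_summary):
        records = binding_block_records
        for obs in ("abeta_plaque", "tau_tangles"):
            value = end_mean(records, obs)
            assert close_to_zero(value, float(baseline_summary.mean_series[obs][-1]))

    def test_complex_is_structurally_impossible(self, binding_block_records):
        for r in binding_block_records:
            assert np.all(r.series["GSK3b_p53"] == 0)

    def test_p53_still_rises(self, binding_block_records):
        p53 = np.mean([r.series["total_p53"] for r in binding_block_records],
                      axis=0)
        assert p53[-1] > p53[0]

    def test_wrapper_applies_the_same_protocol(self):
        summary = run_binding_block(3, base_seed=SEED)
        assert summary.n_runs == 3
        assert np.all(summary.mean_series["GSK3b_p53"] == 0)
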