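"""Threshold fitting against brute-force oracles and the routing rule."""

import numpy as np
import pytest

from screenref import (
    confident_subset,
    fit_safety_net_threshold,
    fit_standalone_threshold,
    fit_triage_threshold,
    route_cohort,
    triaging_performance,
    weighted_sensitivity,
)
from screenref.errors import (
    DegenerateCohortError,
    InfeasibleConfigError,
    TargetRangeError,
    UnfittedConfigError,
)
from screenref.referral import (
    AVERAGE,
    OperatingConfig,
    READER_1,
    SAMPLED,
    route_labels,
    select_reader_calls,
    system_calls,
)

from conftest import make_cohort


def brute_force_triage(scores, labels, target):
    """Independent oracle: loop over every candidate threshold."""
    cancer = np.array([l == "C" for l in labels])
    best = None
    for theta in sorted(set(list(scores) + [0.0])):
        frac = np.mean(np.asarray(scores)[cancer] >= theta)
        if frac >= target:
            best = theta
    return best


def brute_force_safety_net(scores, labels, target):
    normal = np.array([l == "N" for l in labels])
    for theta in sorted(set(scores)):
        frac = np.mean(np.asarray(scores)[normal] <= theta)
        if frac >= target:
            return theta
    return None


CANCER_SCORES = [0.2, 0.5, 0.6, 0.8, 0.9, 0.95, 0.97, 0.99, 0.99, 1.0]


class TestTriageThreshold:
    def test_ninety_percent_target_keeps_nine_of_ten(self):
        cohort = make_cohort(CANCER_SCORES, "C" * 10)
        w = np.ones(10)
        assert fit_triage_threshold(cohort, w, 0.9) == 0.5
        assert brute_force_triage(CANCER_SCORES, "C" * 10, 0.9) == 0.5

    def test_full_sensitivity_returns_min_cancer_score(self):
        cohort = make_cohort(CANCER_SCORES, "C" * 10)
        assert fit_triage_threshold(cohort, np.ones(10), 1.0) == min(CANCER_SCORES)

    @pytest.mark.parametrize("target", [0.5, 0.7, 0.85, 0.9, 0.95, 1.0])
    def test_tied_scores_match_brute_force(self, target):
        # 20 scores with triplicate ties at the decision boundary
        scores = [0.1, 0.3, 0.3, 0.3, 0.5, 0.5, 0.5, 0.7, 0.7, 0.7,
                  0.75, 0.8, 0.8, 0.8, 0.9, 0.9, 0.9, 0.95, 0.99, 1.0]
        labels = "C" * 20
        cohort = make_cohort(scores, labels)
        assert fit_triage_threshold(cohort, np.ones(20), target) == \
            brute_force_triage(scores, labels, target)

    def test_candidates_include_normals_scores(self):
        # a normal's score between two cancer scores is a valid candidate
        cohort = make_cohort([0.2, 0.35, 0.5], "CNC")
        assert fit_triage_threshold(cohort, np.ones(3), 0.5) == 0.5
        assert fit_triage_threshold(cohort, np.ones(3), 1.0) == 0.2

    def test_target_out_of_range(self):
        cohort = make_cohort(CANCER_SCORES, "C" * 10)
        for bad in (0.0, 1.2, -0.3):
            with pytest.raises(TargetRangeError):
                fit_triage_threshold(cohort, np.ones(10), bad)

    def test_no_cancers_is_degenerate(self):
        cohort = make_cohort([0.1, 0.2], "NN")
        with pytest.raises(DegenerateCohortError):
            fit_triage_threshold(cohort, np.ones(2), 0.9)


class TestSafetyNetThreshold:
    def test_ninety_percent_target_is_ninth_smallest(self):
        scores = [round(0.01 * k, 2) for k in range(1, 11)]
        cohort = make_cohort(scores, "N" * 10)
        fitted = fit_safety_net_threshold(cohort, np.ones(10), 0.9)
        assert fitted == sorted(scores)[8] == \
            brute_force_safety_net(scores, "N" * 10, 0.9)

    def test_full_specificity_is_max_normal_score(self):
        scores = [0.05, 0.5, 0.31, 0.12]
        cohort = make_cohort(scores, "N" * 4)
        assert fit_safety_net_threshold(cohort, np.ones(4), 1.0) == max(scores)

    def test_infeasible_pair_raises(self):
        # cancers high, normals low: a modest SN target lands below theta_low
        cohort = make_cohort([0.9, 0.95, 1.0, 0.05, 0.1, 0.15], "CCCNNN")
        with pytest.raises(InfeasibleConfigError):
            OperatingConfig.fit(cohort, np.ones(6), nt_target=1.0, sn_target=0.6)


class TestStandaloneThreshold:
    def test_two_thirds_target_picks_middle_score(self):
        cohort = make_cohort([0.3, 0.6, 0.9], "CCC")
        sa = fit_standalone_threshold(cohort, np.ones(3), 2 / 3)
        assert sa.threshold == 0.6

    def test_fitted_threshold_reproduces_target_on_validation(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.random(400), 3)
        labels = "".join("C" if rng.random() < 0.5 else "N" for _ in range(400))
        cohort = make_cohort(scores, labels)
        w = np.ones(400)
        target = 0.86
        sa = fit_standalone_threshold(cohort, w, target)
        calls = (cohort.scores >= sa.threshold).astype(float)
        achieved = weighted_sensitivity(calls, cohort, w)
        n_cancer = sum(c == "C" for c in labels)
        assert achieved >= target
        assert achieved <= target + 1.0 / n_cancer + 1e-9  # within one score step

    def test_full_target_is_min_cancer_score(self):
        cohort = make_cohort([0.3, 0.6, 0.9, 0.2], "CCCN")
        assert fit_standalone_threshold(cohort, np.ones(4), 1.0).threshold == 0.3


class TestRouting:
    def test_worked_six_study_cohort(self, worked_cohort, worked_config):
        routed = route_cohort(worked_cohort, worked_config, READER_1)
        assert list(routed["route"]) == [
            "TRIAGE", "SAFETY_NET", "REFER", "REFER", "TRIAGE", "SAFETY_NET"]
        assert list(routed["system_call"]) == [
            "NEGATIVE", "POSITIVE", "POSITIVE", "NEGATIVE", "NEGATIVE", "POSITIVE"]
        assert list(routed["reader_call_used"]) == [
            "", "", "RECALL", "NO_RECALL", "", ""]

    def test_triage_ignores_reader_and_safety_net_overrides_miss(self):
        cohort = make_cohort([0.01, 0.99], "NC", ["R", "N"])
        config = OperatingConfig(0.9, 0.9, theta_low=0.05, theta_high=0.95)
        routed = route_cohort(cohort, config, READER_1)
        assert list(routed["route"]) == ["TRIAGE", "SAFETY_NET"]
        assert list(routed["system_call"]) == ["NEGATIVE", "POSITIVE"]

    def test_scores_equal_to_thresholds_are_referred(self):
        cohort = make_cohort([0.05, 0.95, 0.5], "CNC", ["R", "R", "N"])
        config = OperatingConfig(0.9, 0.9, theta_low=0.05, theta_high=0.95)
        assert list(route_labels(cohort.scores, config)) == ["REFER"] * 3

    def test_unfitted_config_raises(self, worked_cohort):
        with pytest.raises(UnfittedConfigError):
            route_cohort(worked_cohort, OperatingConfig(0.97, 0.98), AVERAGE)

    def test_partition_covers_every_study_once(self, medium_cohort):
        cohort, _ = medium_cohort
        config = OperatingConfig(0.9, 0.9, theta_low=0.4, theta_high=0.9)
        routes = route_labels(cohort.scores, config)
        counts = {r: int((routes == r).sum()) for r in np.unique(routes)}
        assert sum(counts.values()) == cohort.n
        w = np.ones(cohort.n)
        fractions = [w[routes == r].sum() / w.sum() for r in counts]
        assert sum(fractions) == pytest.approx(1.0, abs=1e-12)

    def test_sampled_selector_is_seeded(self, medium_cohort):
        cohort, _ = medium_cohort
        a = select_reader_calls(cohort, SAMPLED, np.random.default_rng(5))
        b = select_reader_calls(cohort, SAMPLED, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestTriagingPerformance:
    def test_worked_cohort_one_sixth(self, worked_cohort, worked_config):
        w = np.ones(6)
        assert triaging_performance(worked_cohort, w, worked_config) == \
            pytest.approx(1 / 6)

    def test_zero_threshold_triages_nothing(self, worked_cohort):
        config = OperatingConfig(0.9, 0.9, theta_low=0.0, theta_high=1.0)
        assert triaging_performance(worked_cohort, np.ones(6), config) == 0.0

    def test_monotone_in_nt_and_flat_in_sn(self, small_val_test):
        """Triage depends only on theta_low: flat across SN targets, and
        non-increasing as the NT target rises."""
        val, test, _ = small_val_test
        w_val, w_test = np.ones(val.n), np.ones(test.n)
        previous = 1.1
        for nt in (0.95, 0.97, 0.98, 0.99):
            values = []
            for sn in (0.95, 0.97, 0.99):
                config = OperatingConfig.fit(val, w_val, nt, sn)
                values.append(triaging_performance(test, w_test, config))
            assert len(set(values)) == 1
            assert values[0] <= previous
            previous = values[0]


class TestConfidentSubset:
    def test_full_band_refers_everything(self, worked_cohort):
        config = OperatingConfig(0.9, 0.9, theta_low=0.0, theta_high=1.0)
        assert confident_subset(worked_cohort, config).n == 0

    def test_collapsed_band_keeps_all_but_exact_ties(self):
        cohort = make_cohort([0.2, 0.5, 0.8, 0.5], "CNCN")
        config = OperatingConfig(0.9, 0.9, theta_low=0.5, theta_high=0.5)
        sub = confident_subset(cohort, config)
        assert sub.n == 2 and set(sub.scores) == {0.2, 0.8}

    def test_worked_cohort_keeps_four(self, worked_cohort, worked_config):
        sub = confident_subset(worked_cohort, worked_config)
        assert sub.n == 4
        assert list(sub.study_ids) == ["id0", "id1", "id4", "id5"]


def test_system_calls_accept_fractional_readers(worked_cohort, worked_config):
    fractional = np.full(6, 0.5)
    calls = system_calls(worked_cohort, worked_config, fractional)
    assert list(calls) == [0.0, 1.0, 0.5, 0.5, 0.0, 1.0]
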