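"""Weighted metrics: reader averaging, ROC/AUROC against independent oracles."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from screenref import (
    OperatingPoint,
    compute_prevalence_weights,
    confident_subset_auroc,
    delta_metrics,
    reader_averaged_point_estimate,
    weighted_roc,
    weighted_sensitivity,
    weighted_specificity,
)
from screenref.errors import DegenerateCohortError
from screenref.metrics import DECISION_REFERRAL, RADIOLOGIST, STANDALONE_AI
from screenref.referral import OperatingConfig, StandaloneConfig

from conftest import make_cohort


def brute_force_auroc(scores, labels, weights=None):
    """Pairwise Mann-Whitney count with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    cancer = np.array([l == "C" for l in labels])
    w = np.ones(len(scores)) if weights is None else np.asarray(weights)
    num = den = 0.0
    for i in np.flatnonzero(cancer):
        for j in np.flatnonzero(~cancer):
            pair_w = w[i] * w[j]
            den += pair_w
            if scores[i] > scores[j]:
                num += pair_w
            elif scores[i] == scores[j]:
                num += 0.5 * pair_w
    return num / den


class TestSensitivitySpecificity:
    def test_all_cancers_positive_gives_one(self):
        cohort = make_cohort([0.9, 0.8, 0.1], "CCN")
        assert weighted_sensitivity([1, 1, 0], cohort, np.ones(3)) == 1.0
        assert weighted_specificity([1, 1, 0], cohort, np.ones(3)) == 1.0

    def test_worked_cohort_combined_calls(self, worked_cohort, worked_config):
        """Cancer at s=0.02 is triaged to NEGATIVE; normal at 0.97 hits the
        safety net: both Se and Sp land at 2/3."""
        from screenref.referral import system_calls

        reader = worked_cohort.reader_matrix[:, 0]
        calls = system_calls(worked_cohort, worked_config, reader)
        w = np.ones(6)
        assert weighted_sensitivity(calls, worked_cohort, w) == pytest.approx(2 / 3)
        assert weighted_specificity(calls, worked_cohort, w) == pytest.approx(2 / 3)

    def test_degenerate_label_raises(self):
        cohort = make_cohort([0.5, 0.6], "CC")
        with pytest.raises(DegenerateCohortError):
            weighted_specificity([1, 1], cohort, np.ones(2))
        with pytest.raises(DegenerateCohortError):
            weighted_sensitivity([0], make_cohort([0.5], "N"), np.ones(1))


class TestReaderAveraging:
    def test_split_readers_contribute_half(self):
        cohort = make_cohort([0.5, 0.3], "CN", ["R", "N"], ["N", "N"])
        config = OperatingConfig(0.9, 0.9, theta_low=0.1, theta_high=0.9)
        point = reader_averaged_point_estimate(
            cohort, np.ones(2), DECISION_REFERRAL, config=config)
        assert point.sensitivity == 0.5

    def test_two_referred_cancers_average_to_half(self):
        cohort = make_cohort([0.5, 0.5, 0.2], "CCN",
                             ["R", "N", "N"], ["R", "N", "N"])
        point = reader_averaged_point_estimate(cohort, np.ones(3), RADIOLOGIST)
        assert point.sensitivity == 0.5

    def test_identical_readers_equal_single_reader(self, medium_cohort):
        cohort, _ = medium_cohort
        data = cohort.data.copy()
        data["reader_2"] = data["reader_1"]
        from screenref import Cohort

        twin = Cohort.from_dataframe(data, cohort.population_prevalence)
        w = compute_prevalence_weights(twin)
        averaged = reader_averaged_point_estimate(twin, w, RADIOLOGIST)
        single = twin.reader_matrix[:, 0]
        assert averaged.sensitivity == weighted_sensitivity(single, twin, w)
        assert averaged.specificity == weighted_specificity(single, twin, w)

    def test_averaging_is_linear_in_the_readers(self, medium_cohort):
        """The averaged estimate equals the mean of the two single-reader
        evaluations, for every pathway that consults a reader."""
        cohort, _ = medium_cohort
        w = compute_prevalence_weights(cohort)
        config = OperatingConfig(0.9, 0.9, theta_low=0.45, theta_high=0.92)
        from screenref.metrics import pathway_calls

        for pathway in (RADIOLOGIST, DECISION_REFERRAL):
            per_reader = [
                weighted_sensitivity(
                    pathway_calls(cohort, pathway, config=config,
                                  reader_calls=cohort.reader_matrix[:, j]),
                    cohort, w)
                for j in (0, 1)]
            averaged = reader_averaged_point_estimate(
                cohort, w, pathway, config=config).sensitivity
            assert averaged == pytest.approx(np.mean(per_reader), abs=1e-12)

    def test_standalone_ignores_readers(self, medium_cohort):
        cohort, _ = medium_cohort
        w = compute_prevalence_weights(cohort)
        sa = StandaloneConfig(threshold=0.8, sensitivity_target=0.86)
        point = reader_averaged_point_estimate(cohort, w, STANDALONE_AI,
                                               standalone=sa)
        expected = weighted_sensitivity(
            (cohort.scores >= 0.8).astype(float), cohort, w)
        assert point.sensitivity == expected


class TestRoc:
    def test_perfect_separation_and_pure_ties(self):
        separated = make_cohort([0.9, 0.8, 0.2, 0.1], "CCNN")
        assert weighted_roc(separated, np.ones(4)).auroc == 1.0
        tied = make_cohort([0.5] * 4, "CCNN")
        assert weighted_roc(tied, np.ones(4)).auroc == 0.5

    def test_five_by_five_toy_matches_pair_enumeration(self):
        scores = [0.9, 0.6, 0.6, 0.4, 0.95, 0.1, 0.6, 0.3, 0.8, 0.2]
        labels = "CCCCC" + "NNNNN"
        cohort = make_cohort(scores, labels)
        curve = weighted_roc(cohort, np.ones(10))
        assert curve.auroc == pytest.approx(
            brute_force_auroc(scores, labels), abs=1e-12)

    def test_weighted_auroc_matches_sklearn(self, medium_cohort):
        cohort, _ = medium_cohort
        w = compute_prevalence_weights(cohort)
        ours = weighted_roc(cohort, w).auroc
        theirs = roc_auc_score(cohort.is_cancer, cohort.scores, sample_weight=w)
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_staircase_shape_and_endpoints(self, medium_cohort):
        cohort, _ = medium_cohort
        curve = weighted_roc(cohort, compute_prevalence_weights(cohort))
        assert curve.fpr[0] == 0.0 and curve.tpr[0] == 0.0
        assert curve.fpr[-1] == 1.0 and curve.tpr[-1] == 1.0
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)
        assert curve.thresholds[0] == np.inf

    def test_invariant_under_monotone_transform(self, medium_cohort):
        cohort, _ = medium_cohort
        w = compute_prevalence_weights(cohort)
        base = weighted_roc(cohort, w).auroc
        warped = weighted_roc(cohort, w, scores=cohort.scores ** 3).auroc
        assert warped == pytest.approx(base, abs=1e-12)

    def test_single_label_degenerate(self):
        with pytest.raises(DegenerateCohortError):
            weighted_roc(make_cohort([0.1, 0.9], "CC"), np.ones(2))


class TestConfidentSubsetAuroc:
    def test_empty_subset_raises_with_counts(self, worked_cohort):
        config = OperatingConfig(0.9, 0.9, theta_low=0.0, theta_high=1.0)
        with pytest.raises(DegenerateCohortError, match="0 records"):
            confident_subset_auroc(worked_cohort, np.ones(6), config)

    def test_worked_cohort_matches_pair_enumeration(self, worked_cohort,
                                                    worked_config):
        value = confident_subset_auroc(worked_cohort, np.ones(6), worked_config)
        # confident studies: scores .01(N), .99(C), .02(C), .97(N)
        assert value == pytest.approx(
            brute_force_auroc([0.01, 0.99, 0.02, 0.97], "NCCN"), abs=1e-12)

    def test_wide_referral_band_raises_subset_auroc(self, medium_cohort):
        """Extremes are easier to rank: excluding the ambiguous middle
        lifts the AUROC of what remains."""
        cohort, _ = medium_cohort
        w = compute_prevalence_weights(cohort)
        config = OperatingConfig(0.9, 0.9, theta_low=0.35, theta_high=0.95)
        assert confident_subset_auroc(cohort, w, config) > \
            weighted_roc(cohort, w).auroc


class TestDelta:
    def test_identical_points_and_antisymmetry(self):
        a = OperatingPoint(0.897, 0.938, DECISION_REFERRAL)
        b = OperatingPoint(0.857, 0.933, RADIOLOGIST)
        assert delta_metrics(a, a) == (0.0, 0.0)
        d_ab = delta_metrics(a, b)
        d_ba = delta_metrics(b, a)
        assert d_ab[0] == pytest.approx(-d_ba[0])
        assert d_ab[1] == pytest.approx(-d_ba[1])

    def test_reported_in_percentage_points(self):
        a = OperatingPoint(0.897, 0.90, DECISION_REFERRAL)
        b = OperatingPoint(0.857, 0.90, RADIOLOGIST)
        assert delta_metrics(a, b)[0] == pytest.approx(4.0)
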