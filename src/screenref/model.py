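"""Model-style front end: fit a decision-referral system and summarise it.

``DecisionReferral`` is constructed from a validation cohort (used to fit
thresholds) and a test cohort (used to evaluate them), mirroring the
model/results split of the statistical-modelling packages: ``fit()``
returns a :class:`DecisionReferralResults` carrying the fitted operating
configuration, per-pathway estimates with bootstrap CIs, permutation
p-values for the pathway deltas, triaging performance, AUROCs, and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import Cohort
from .inference import (
    AUROC,
    SENSITIVITY,
    SPECIFICITY,
    TRIAGE,
    InferenceSettings,
    MetricEstimate,
    PermutationResult,
    bootstrap_ci,
    permutation_test,
)
from .metrics import (
    DECISION_REFERRAL,
    PATHWAYS,
    RADIOLOGIST,
    STANDALONE_AI,
    OperatingPoint,
    confident_subset_auroc,
    delta_metrics,
    pathway_calls,
    reader_averaged_point_estimate,
    weighted_roc,
)
from .referral import (
    OperatingConfig,
    StandaloneConfig,
    confident_subset,
    fit_standalone_threshold,
    triaging_performance,
)
from .weighting import compute_prevalence_weights, effective_sample_size


class DecisionReferral:
    """Decision-referral evaluation model.

    Parameters
    ----------
    validation : Cohort
        Split on which thresholds are fitted.
    test : Cohort
        Split on which the pathways are evaluated.
    nt_target, sn_target : float
        Algorithmic sensitivity/specificity targets of the triage and
        safety-net thresholds.
    standalone_sensitivity_target : float, optional
        Sensitivity target of the standalone single-threshold pathway;
        defaults to the measured validation radiologist sensitivity.
    weighted_validation : bool
        Whether threshold fitting uses enrichment weights (default) or raw
        counts; echoed into the results.
    """

    def __init__(self, validation: Cohort, test: Cohort,
                 nt_target: float = 0.97, sn_target: float = 0.98,
                 standalone_sensitivity_target: Optional[float] = None,
                 weighted_validation: bool = True):
        self.validation = validation
        self.test = test
        self.nt_target = nt_target
        self.sn_target = sn_target
        self.standalone_sensitivity_target = standalone_sensitivity_target
        self.weighted_validation = weighted_validation
        self.validation_weights = compute_prevalence_weights(validation)
        self.test_weights = compute_prevalence_weights(test)

    @classmethod
    def from_cohort(cls, cohort: Cohort, **kwargs) -> "DecisionReferral":
        """Build from a single cohort carrying a VALIDATION/TEST split column."""
        validation, test = cohort.split_cohorts()
        return cls(validation, test, **kwargs)

    @classmethod
    def from_dataframes(cls, validation: pd.DataFrame, test: pd.DataFrame,
                        population_prevalence: float, **kwargs) -> "DecisionReferral":
        return cls(Cohort.from_dataframe(validation, population_prevalence),
                   Cohort.from_dataframe(test, population_prevalence), **kwargs)

    def fit(self, settings: Optional[InferenceSettings] = None,
            inference: bool = True) -> "DecisionReferralResults":
        """Fit thresholds on validation, evaluate all pathways on test.

        With ``inference=False`` only point estimates are computed (no
        bootstrap CIs or permutation p-values), which is much faster.
        """
        settings = settings or InferenceSettings()
        fit_w = (self.validation_weights if self.weighted_validation
                 else np.ones(self.validation.n))
        config = OperatingConfig.fit(self.validation, self.validation_weights,
                                     self.nt_target, self.sn_target,
                                     weighted=self.weighted_validation)
        target = self.standalone_sensitivity_target
        if target is None:
            target = reader_averaged_point_estimate(
                self.validation, fit_w, RADIOLOGIST).sensitivity
        standalone = fit_standalone_threshold(self.validation, fit_w, target)

        test, w = self.test, self.test_weights
        points = {
            pathway: reader_averaged_point_estimate(
                test, w, pathway, config=config, standalone=standalone)
            for pathway in PATHWAYS}

        estimates: dict[tuple[str, str], MetricEstimate] = {}
        p_values: dict[tuple[str, str], PermutationResult] = {}
        if inference:
            for pathway in PATHWAYS:
                for metric in (SENSITIVITY, SPECIFICITY):
                    estimates[(pathway, metric)] = bootstrap_ci(
                        test, w, pathway, metric, config=config,
                        standalone=standalone,
                        n_bootstrap=settings.n_bootstrap, seed=settings.seed)
            estimates[("AI", AUROC)] = bootstrap_ci(
                test, w, STANDALONE_AI, AUROC, standalone=standalone,
                n_bootstrap=settings.n_bootstrap, seed=settings.seed)
            estimates[(DECISION_REFERRAL, TRIAGE)] = bootstrap_ci(
                test, w, DECISION_REFERRAL, TRIAGE, config=config,
                n_bootstrap=settings.n_bootstrap, seed=settings.seed)

            reader_matrix = test.reader_matrix
            per_reader = {
                DECISION_REFERRAL: np.column_stack([
                    pathway_calls(test, DECISION_REFERRAL, config=config,
                                  reader_calls=reader_matrix[:, j])
                    for j in (0, 1)]),
                STANDALONE_AI: pathway_calls(test, STANDALONE_AI,
                                             standalone=standalone),
            }
            for pathway in (DECISION_REFERRAL, STANDALONE_AI):
                for metric in (SENSITIVITY, SPECIFICITY):
                    p_values[(pathway, metric)] = permutation_test(
                        test, w, per_reader[pathway], reader_matrix, metric,
                        n_permutations=settings.n_permutations,
                        seed=settings.seed)

        roc = weighted_roc(test, w)
        subset = confident_subset(test, config)
        auroc_confident = confident_subset_auroc(test, w, config)

        return DecisionReferralResults(
            model=self, config=config, standalone=standalone,
            operating_points=points, estimates=estimates, p_values=p_values,
            triage=triaging_performance(test, w, config),
            roc=roc, auroc=roc.auroc, auroc_confident=auroc_confident,
            n_confident=subset.n,
            ess_test=effective_sample_size(w), settings=settings)


@dataclass
class DecisionReferralResults:
    """Fitted thresholds plus everything measured on the test split."""

    model: DecisionReferral
    config: OperatingConfig
    standalone: StandaloneConfig
    operating_points: dict[str, OperatingPoint]
    estimates: dict[tuple[str, str], MetricEstimate]
    p_values: dict[tuple[str, str], PermutationResult]
    triage: float
    roc: object
    auroc: float
    auroc_confident: float
    n_confident: int
    ess_test: float
    settings: InferenceSettings = field(default_factory=InferenceSettings)

    # ------------------------------------------------------------------ #
    # derived quantities

    @property
    def delta_sensitivity(self) -> float:
        """Decision referral minus radiologist sensitivity, percentage points."""
        return delta_metrics(self.operating_points[DECISION_REFERRAL],
                             self.operating_points[RADIOLOGIST])[0]

    @property
    def delta_specificity(self) -> float:
        return delta_metrics(self.operating_points[DECISION_REFERRAL],
                             self.operating_points[RADIOLOGIST])[1]

    def to_frame(self) -> pd.DataFrame:
        """One row per pathway: Se/Sp (with CIs when available), deltas, p."""
        radio = self.operating_points[RADIOLOGIST]
        rows = []
        for pathway in PATHWAYS:
            point = self.operating_points[pathway]
            row = {"pathway": pathway,
                   "sensitivity": point.sensitivity,
                   "specificity": point.specificity}
            for metric, col in ((SENSITIVITY, "se"), (SPECIFICITY, "sp")):
                est = self.estimates.get((pathway, metric))
                row[f"{col}_ci_low"] = est.ci_low if est else np.nan
                row[f"{col}_ci_high"] = est.ci_high if est else np.nan
                perm = self.p_values.get((pathway, metric))
                row[f"p_delta_{col}"] = perm.p_two_sided if perm else np.nan
            d_se, d_sp = delta_metrics(point, radio)
            row["delta_se_pp"] = d_se if pathway != RADIOLOGIST else np.nan
            row["delta_sp_pp"] = d_sp if pathway != RADIOLOGIST else np.nan
            rows.append(row)
        return pd.DataFrame(rows)

    # ------------------------------------------------------------------ #

    def summary(self) -> str:
        """Human-readable results table (percentages to one decimal)."""
        cfg = self.config
        lines = [
            "Decision-referral evaluation",
            "=" * 64,
            f"Configuration           {cfg.name}"
            f"   (thresholds {cfg.theta_low:.4f} / {cfg.theta_high:.4f})",
            f"Standalone threshold    {self.standalone.threshold:.4f} "
            f"(Se target {self.standalone.sensitivity_target:.3f})",
            f"Validation fitting      "
            f"{'weighted' if cfg.weighted else 'unweighted'}",
            f"Test cohort             n={self.model.test.n} "
            f"(cancers={int(self.model.test.is_cancer.sum())}), "
            f"pi={self.model.test.population_prevalence:g}, "
            f"ESS={self.ess_test:.1f}",
            "-" * 64,
        ]
        header = (f"{'pathway':<20}{'Se %':>8}{'Sp %':>8}"
                  f"{'dSe pp':>9}{'dSp pp':>9}{'p(Se)':>10}")
        lines.append(header)
        radio = self.operating_points[RADIOLOGIST]
        for pathway in PATHWAYS:
            point = self.operating_points[pathway]
            d_se, d_sp = delta_metrics(point, radio)
            perm = self.p_values.get((pathway, SENSITIVITY))
            p_txt = f"{perm.p_two_sided:.4f}" if perm else ""
            delta_txt = ("", "") if pathway == RADIOLOGIST else (
                f"{d_se:+.1f}", f"{d_sp:+.1f}")
            lines.append(f"{pathway:<20}{100 * point.sensitivity:>8.1f}"
                         f"{100 * point.specificity:>8.1f}"
                         f"{delta_txt[0]:>9}{delta_txt[1]:>9}{p_txt:>10}")
        lines += [
            "-" * 64,
            f"Triaging performance    {100 * self.triage:.1f}% of studies "
            "auto-negative and truly normal",
            f"AUROC (all studies)     {self.auroc:.3f}",
            f"AUROC (confident set)   {self.auroc_confident:.3f} "
            f"on {self.n_confident} studies",
        ]
        if self.estimates:  # resampling actually ran
            lines.append(
                f"Resampling              B={self.settings.n_bootstrap}, "
                f"P={self.settings.n_permutations}, seed={self.settings.seed}")
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC of the AI score with the three operating points overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.plot(self.roc.fpr, self.roc.tpr,
                label=f"AI (AUROC {self.auroc:.3f})", color="C0")
        markers = {RADIOLOGIST: ("o", "C3"), STANDALONE_AI: ("s", "C4"),
                   DECISION_REFERRAL: ("P", "C2")}
        for pathway, (marker, color) in markers.items():
            point = self.operating_points[pathway]
            ax.plot(1 - point.specificity, point.sensitivity, marker,
                    color=color, label=pathway.replace("_", " ").title())
        ax.plot([0, 1], [0, 1], ":", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend(loc="lower right", fontsize=8)
        return ax
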