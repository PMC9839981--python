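"""Stratified reporting and the multi-configuration operating-point grid.

``stratified_report`` breaks sensitivity down by a stratum column (biopsy
score, ACR density, lesion-size bin, finding type, site, manufacturer, or
any user column), comparing the three pathways per level with a paired
permutation p-value and the conventional significance markers. Missing
stratum values form an explicit "unknown" level rather than disappearing.

``operating_point_grid`` fits every (NT, SN) target pair on the
validation split, evaluates it on the test split, and emits one row per
configuration plus radiologist and standalone-AI anchor rows — the
layout of a multi-configuration results table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort
from .errors import InfeasibleConfigError
from .inference import (
    SENSITIVITY,
    SPECIFICITY,
    InferenceSettings,
    bootstrap_ci,
    permutation_test,
)
from .metrics import (
    DECISION_REFERRAL,
    RADIOLOGIST,
    STANDALONE_AI,
    pathway_calls,
    reader_averaged_point_estimate,
)
from .referral import (
    OperatingConfig,
    StandaloneConfig,
    fit_standalone_threshold,
    triaging_performance,
)
from .weighting import compute_prevalence_weights

#: p-value cutpoints for 1-4 significance markers.
SIGNIFICANCE_CUTPOINTS = (0.05, 0.01, 0.001, 0.0001)

#: Default lesion-size bins (mm); configurable placeholders, edges inclusive
#: on the upper side: <=10, 11-20, >20.
DEFAULT_LESION_BINS = (10.0, 20.0)

UNKNOWN_LEVEL = "unknown"


def significance_tier(p: float) -> str:
    """Map a p-value to 'ns' or 1-4 stars at 0.05/0.01/0.001/0.0001."""
    stars = sum(p <= cut for cut in SIGNIFICANCE_CUTPOINTS)
    return "*" * stars if stars else "ns"


def lesion_size_bins(sizes: pd.Series,
                     edges: Sequence[float] = DEFAULT_LESION_BINS) -> pd.Series:
    """Bin lesion sizes into labelled intervals; NaN stays missing."""
    edges = list(edges)
    cut_edges = [0.0, *edges, np.inf]
    labels = [f"<= {edges[0]:g} mm"]
    labels += [f"{lo:g}-{hi:g} mm" for lo, hi in zip(edges[:-1], edges[1:])]
    labels += [f"> {edges[-1]:g} mm"]
    return pd.cut(pd.to_numeric(sizes, errors="coerce"), bins=cut_edges,
                  labels=labels, include_lowest=True).astype(object)


@dataclass
class SubgroupReport:
    """Per-level sensitivity comparison across pathways for one stratifier."""

    stratifier: str
    table: pd.DataFrame
    min_count: int

    def __str__(self):
        return (f"Subgroup report by {self.stratifier} "
                f"({len(self.table)} levels)\n{self.table.to_string(index=False)}")


def _stratifier_levels(cohort: Cohort, stratifier: str) -> pd.Series:
    if stratifier == "lesion_size_bin":
        if "lesion_size_mm" not in cohort.data.columns:
            raise KeyError("cohort has no lesion_size_mm column")
        values = lesion_size_bins(cohort.data["lesion_size_mm"])
    else:
        if stratifier not in cohort.data.columns:
            raise KeyError(f"unknown stratifier {stratifier!r}; cohort columns: "
                           f"{list(cohort.data.columns)}")
        values = cohort.data[stratifier].astype(object)
    return values.where(values.notna(), UNKNOWN_LEVEL).astype(str)


def stratified_report(cohort: Cohort, weights, config: OperatingConfig,
                      stratifier: str,
                      standalone: Optional[StandaloneConfig] = None,
                      settings: InferenceSettings = InferenceSettings(),
                      min_count: int = 10) -> SubgroupReport:
    """Sensitivity by stratum level for all three pathways.

    Levels whose cancer count falls below ``min_count`` are still reported
    but flagged unstable. The per-level p-value is a paired permutation
    test of decision referral vs the radiologist on that level's records.
    """
    levels = _stratifier_levels(cohort, stratifier)
    w = np.asarray(weights, dtype=float)
    rows = []
    for level in pd.unique(levels):
        mask = (levels == level).to_numpy()
        sub = cohort.subset(mask)
        sub_w = w[mask]
        n_cancer = int(sub.is_cancer.sum())
        row = {"level": level, "n": int(mask.sum()), "n_cancers": n_cancer,
               "unstable": n_cancer < min_count}
        if n_cancer == 0:
            rows.append(row)
            continue
        se = {}
        for pathway, cfg in ((RADIOLOGIST, None), (DECISION_REFERRAL, config)):
            point = reader_averaged_point_estimate(
                sub, sub_w, pathway, config=cfg, standalone=standalone)
            se[pathway] = point.sensitivity
        if standalone is not None:
            se[STANDALONE_AI] = reader_averaged_point_estimate(
                sub, sub_w, STANDALONE_AI, standalone=standalone).sensitivity
        reader_matrix = sub.reader_matrix
        calls_ref = np.column_stack([
            pathway_calls(sub, DECISION_REFERRAL, config=config,
                          reader_calls=reader_matrix[:, j]) for j in (0, 1)])
        perm = permutation_test(sub, sub_w, calls_ref, reader_matrix,
                                SENSITIVITY,
                                n_permutations=settings.n_permutations,
                                seed=settings.seed)
        row.update({
            "se_radiologist": se[RADIOLOGIST],
            "se_standalone_ai": se.get(STANDALONE_AI, np.nan),
            "se_decision_referral": se[DECISION_REFERRAL],
            "delta_se_pp": 100.0 * (se[DECISION_REFERRAL] - se[RADIOLOGIST]),
            "p_value": perm.p_two_sided,
            "significance": significance_tier(perm.p_two_sided),
        })
        rows.append(row)
    table = pd.DataFrame(rows)
    return SubgroupReport(stratifier=stratifier, table=table, min_count=min_count)


def _grid_row(name, se=None, sp=None, delta_se=None, p_se=None,
              delta_sp=None, p_sp=None, triage=None, feasible=True,
              theta_low=None, theta_high=None):
    def fmt(est):
        return (np.nan, np.nan, np.nan) if est is None else (
            est.point, est.ci_low, est.ci_high)

    se_p, se_lo, se_hi = fmt(se)
    sp_p, sp_lo, sp_hi = fmt(sp)
    return {
        "configuration": name, "feasible": feasible,
        "theta_low": theta_low, "theta_high": theta_high,
        "sensitivity": se_p, "se_ci_low": se_lo, "se_ci_high": se_hi,
        "specificity": sp_p, "sp_ci_low": sp_lo, "sp_ci_high": sp_hi,
        "delta_se_pp": delta_se, "p_delta_se": p_se,
        "delta_sp_pp": delta_sp, "p_delta_sp": p_sp,
        "triaging_performance": triage,
    }


def operating_point_grid(validation: Cohort, test: Cohort,
                         nt_targets: Sequence[float],
                         sn_targets: Sequence[float],
                         settings: InferenceSettings = InferenceSettings(),
                         standalone_target: Optional[float] = None,
                         weighted_validation: bool = True) -> pd.DataFrame:
    """One row per (NT, SN) configuration plus the two anchor pathways.

    Configurations are fitted on the validation split and evaluated on the
    test split; rows are sorted by sensitivity with the anchors first.
    Infeasible pairs (safety-net threshold below triage threshold) are
    emitted with ``feasible=False`` and empty metrics. With
    ``settings.n_bootstrap == 0`` the CI columns stay empty (fast mode).
    """
    if not len(nt_targets) or not len(sn_targets):
        raise ValueError("nt_targets and sn_targets must be non-empty")
    val_w = compute_prevalence_weights(validation)
    test_w = compute_prevalence_weights(test)
    reader_matrix = test.reader_matrix

    def estimate(pathway, metric, cfg=None, sa=None):
        if settings.n_bootstrap == 0:
            point = reader_averaged_point_estimate(
                test, test_w, pathway, config=cfg, standalone=sa)
            value = point.sensitivity if metric == SENSITIVITY else point.specificity
            return _PointOnly(value)
        return bootstrap_ci(test, test_w, pathway, metric, config=cfg,
                            standalone=sa, n_bootstrap=settings.n_bootstrap,
                            seed=settings.seed)

    def perm_p(calls_a, calls_b, metric):
        return permutation_test(test, test_w, calls_a, calls_b, metric,
                                n_permutations=settings.n_permutations,
                                seed=settings.seed).p_two_sided

    # anchors
    radio_se = estimate(RADIOLOGIST, SENSITIVITY)
    radio_sp = estimate(RADIOLOGIST, SPECIFICITY)
    if standalone_target is None:
        standalone_target = reader_averaged_point_estimate(
            validation, val_w if weighted_validation else np.ones(validation.n),
            RADIOLOGIST).sensitivity
    standalone = fit_standalone_threshold(
        validation, val_w if weighted_validation else np.ones(validation.n),
        standalone_target)
    sa_calls = pathway_calls(test, STANDALONE_AI, standalone=standalone)
    sa_se = estimate(STANDALONE_AI, SENSITIVITY, sa=standalone)
    sa_sp = estimate(STANDALONE_AI, SPECIFICITY, sa=standalone)
    sa_point = reader_averaged_point_estimate(test, test_w, STANDALONE_AI,
                                              standalone=standalone)
    radio_point = reader_averaged_point_estimate(test, test_w, RADIOLOGIST)
    sa_triage = float(
        (1.0 - test.population_prevalence) * sa_point.specificity)

    rows = [
        _grid_row("Radiologist", se=radio_se, sp=radio_sp),
        _grid_row("AI standalone", se=sa_se, sp=sa_sp,
                  delta_se=100.0 * (sa_point.sensitivity - radio_point.sensitivity),
                  p_se=perm_p(sa_calls, reader_matrix, SENSITIVITY),
                  delta_sp=100.0 * (sa_point.specificity - radio_point.specificity),
                  p_sp=perm_p(sa_calls, reader_matrix, SPECIFICITY),
                  triage=sa_triage, theta_low=standalone.threshold,
                  theta_high=standalone.threshold),
    ]

    config_rows = []
    for nt in nt_targets:
        for sn in sn_targets:
            name = f"NT@{nt:g}+SN@{sn:g}"
            try:
                config = OperatingConfig.fit(
                    validation, val_w, nt, sn, weighted=weighted_validation)
            except InfeasibleConfigError:
                config_rows.append(_grid_row(name, feasible=False))
                continue
            dr_calls = np.column_stack([
                pathway_calls(test, DECISION_REFERRAL, config=config,
                              reader_calls=reader_matrix[:, j]) for j in (0, 1)])
            dr_point = reader_averaged_point_estimate(
                test, test_w, DECISION_REFERRAL, config=config)
            config_rows.append(_grid_row(
                name,
                se=estimate(DECISION_REFERRAL, SENSITIVITY, cfg=config),
                sp=estimate(DECISION_REFERRAL, SPECIFICITY, cfg=config),
                delta_se=100.0 * (dr_point.sensitivity - radio_point.sensitivity),
                p_se=perm_p(dr_calls, reader_matrix, SENSITIVITY),
                delta_sp=100.0 * (dr_point.specificity - radio_point.specificity),
                p_sp=perm_p(dr_calls, reader_matrix, SPECIFICITY),
                triage=triaging_performance(test, test_w, config),
                theta_low=config.theta_low, theta_high=config.theta_high,
            ))
    config_rows.sort(key=lambda r: (np.isnan(r["sensitivity"]), r["sensitivity"]))
    return pd.DataFrame(rows + config_rows)


class _PointOnly:
    """Duck-typed stand-in for a MetricEstimate when CIs are disabled."""

    def __init__(self, point):
        self.point = float(point)
        self.ci_low = np.nan
        self.ci_high = np.nan
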