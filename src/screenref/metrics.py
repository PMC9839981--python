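"""Weighted screening accuracy metrics.

Sensitivity and specificity accept fractional recall calls so that the
two readers' decisions can be averaged per study (a referred cancer with
one recalling reader contributes 0.5 detected). ROC curves are the exact
weighted staircase swept over every distinct score, with thresholds
including +inf so both endpoints (0,0) and (1,1) exist; AUROC is the
weighted Mann-Whitney statistic with ties credited 1/2, which the
trapezoid over the staircase computes exactly.

Tables report percentage points with one decimal; everything internal is
kept at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import Cohort
from .errors import DegenerateCohortError
from .referral import (
    AVERAGE,
    OperatingConfig,
    StandaloneConfig,
    confident_subset,
    select_reader_calls,
    system_calls,
)

RADIOLOGIST = "RADIOLOGIST"
STANDALONE_AI = "STANDALONE_AI"
DECISION_REFERRAL = "DECISION_REFERRAL"
PATHWAYS = (RADIOLOGIST, STANDALONE_AI, DECISION_REFERRAL)


@dataclass(frozen=True)
class OperatingPoint:
    sensitivity: float
    specificity: float
    pathway: str
    config_name: str = ""


@dataclass(frozen=True)
class RocCurve:
    """Weighted empirical ROC: staircase points plus the area under it."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # call positive iff score >= threshold
    auroc: float


# ---------------------------------------------------------------------- #
# array kernels (shared with the resampling machinery)


def _wmean(calls, mask, weights):
    w = weights[mask]
    if w.size == 0:
        return np.nan
    return float(np.dot(np.asarray(calls, dtype=float)[mask], w) / w.sum())


def _sensitivity(calls, is_cancer, weights):
    return _wmean(calls, is_cancer, weights)


def _specificity(calls, is_cancer, weights):
    return 1.0 - _wmean(calls, ~is_cancer, weights)


def _roc_points(scores, is_cancer, weights):
    """Staircase (fpr, tpr, thresholds) over distinct scores, descending."""
    order = np.argsort(-scores, kind="mergesort")
    s, y, w = scores[order], is_cancer[order], weights[order]
    tp = np.cumsum(w * y)
    fp = np.cumsum(w * ~y)
    # one staircase vertex per distinct score: last index of each tie group
    last = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tp[last] / tp[-1]]
    fpr = np.r_[0.0, fp[last] / fp[-1]]
    thresholds = np.r_[np.inf, s[last]]
    return fpr, tpr, thresholds


def _auroc(scores, is_cancer, weights):
    fpr, tpr, _ = _roc_points(scores, is_cancer, weights)
    return float(np.trapezoid(tpr, fpr))


# ---------------------------------------------------------------------- #
# public operations


def weighted_sensitivity(calls, cohort: Cohort, weights) -> float:
    """Weighted fraction of cancer mass called positive; calls may be fractional."""
    calls = np.asarray(calls, dtype=float)
    is_cancer = cohort.is_cancer
    if not is_cancer.any():
        raise DegenerateCohortError("sensitivity undefined: no cancers in cohort")
    return _sensitivity(calls, is_cancer, np.asarray(weights, dtype=float))


def weighted_specificity(calls, cohort: Cohort, weights) -> float:
    """Weighted fraction of normal mass called negative; calls may be fractional."""
    calls = np.asarray(calls, dtype=float)
    is_cancer = cohort.is_cancer
    if is_cancer.all():
        raise DegenerateCohortError("specificity undefined: no normals in cohort")
    return _specificity(calls, is_cancer, np.asarray(weights, dtype=float))


def pathway_calls(cohort: Cohort, pathway: str,
                  config: Optional[OperatingConfig] = None,
                  standalone: Optional[StandaloneConfig] = None,
                  reader_calls: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-study recall probability for one evaluation pathway.

    ``reader_calls`` defaults to the reader average (point-estimate rule);
    the standalone pathway ignores readers entirely (documented no-op).
    """
    if reader_calls is None:
        reader_calls = select_reader_calls(cohort, AVERAGE)
    if pathway == RADIOLOGIST:
        return np.asarray(reader_calls, dtype=float)
    if pathway == STANDALONE_AI:
        if standalone is None:
            raise ValueError("standalone pathway requires a StandaloneConfig")
        return (cohort.scores >= standalone.threshold).astype(float)
    if pathway == DECISION_REFERRAL:
        if config is None:
            raise ValueError("decision-referral pathway requires an OperatingConfig")
        return system_calls(cohort, config, reader_calls)
    raise ValueError(f"unknown pathway {pathway!r}")


def reader_averaged_point_estimate(cohort: Cohort, weights, pathway: str,
                                   config: Optional[OperatingConfig] = None,
                                   standalone: Optional[StandaloneConfig] = None,
                                   ) -> OperatingPoint:
    """Point estimate with the two readers' decisions averaged per study."""
    calls = pathway_calls(cohort, pathway, config=config, standalone=standalone)
    name = ""
    if pathway == DECISION_REFERRAL and config is not None:
        name = config.name
    elif pathway == STANDALONE_AI and standalone is not None:
        name = standalone.name
    return OperatingPoint(
        sensitivity=weighted_sensitivity(calls, cohort, weights),
        specificity=weighted_specificity(calls, cohort, weights),
        pathway=pathway,
        config_name=name,
    )


def weighted_roc(cohort: Cohort, weights, scores: Optional[np.ndarray] = None
                 ) -> RocCurve:
    """Weighted empirical ROC of the AI score (or any supplied ranking)."""
    scores = cohort.scores if scores is None else np.asarray(scores, dtype=float)
    is_cancer = cohort.is_cancer
    if not is_cancer.any() or is_cancer.all():
        raise DegenerateCohortError(
            f"ROC undefined on single-label cohort "
            f"(cancers={int(is_cancer.sum())}, normals={int((~is_cancer).sum())})")
    w = np.asarray(weights, dtype=float)
    fpr, tpr, thresholds = _roc_points(scores, is_cancer, w)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds,
                    auroc=float(np.trapezoid(tpr, fpr)))


def confident_subset_auroc(cohort: Cohort, weights, config: OperatingConfig
                           ) -> float:
    """AUROC restricted to the studies the AI decides on its own."""
    s = cohort.scores
    mask = (s < config.theta_low) | (s > config.theta_high)
    sub = confident_subset(cohort, config)
    n_cancer = int(sub.is_cancer.sum()) if sub.n else 0
    if sub.n == 0 or n_cancer == 0 or n_cancer == sub.n:
        raise DegenerateCohortError(
            f"confident subset is degenerate: {sub.n} records, "
            f"{n_cancer} cancers, {sub.n - n_cancer} normals")
    return weighted_roc(sub, np.asarray(weights, dtype=float)[mask]).auroc


def delta_metrics(a: OperatingPoint, b: OperatingPoint) -> tuple[float, float]:
    """(delta Se, delta Sp) of a minus b, in percentage points."""
    return (100.0 * (a.sensitivity - b.sensitivity),
            100.0 * (a.specificity - b.specificity))
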