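"""Decision-referral configuration: threshold fitting and study routing.

The two-part system splits the score axis with a lower (normal-triage)
threshold ``theta_low`` and an upper (safety-net) threshold ``theta_high``:

* ``s < theta_low``       -> TRIAGE: auto-negative, no reader involved;
* ``s > theta_high``      -> SAFETY_NET: auto-positive, overrides the reader;
* otherwise               -> REFER: the reader's recall decision stands.

Scores exactly equal to a threshold are referred — confident calls require
strictly clearing a threshold. Thresholds are fitted on the validation
split against *algorithmic* targets: the triage threshold is the largest
candidate keeping at least ``nt_target`` of the (weighted) cancer mass at
or above it, the safety-net threshold the smallest candidate keeping at
least ``sn_target`` of the (weighted) normal mass at or below it.
Candidates are the observed validation scores (plus 0 for the triage
side), and the conservative side of each target is chosen; no
interpolation is performed. A standalone single-threshold configuration
is fitted the same way against a sensitivity target and calls positive
iff ``s >= theta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import NO_RECALL, RECALL, Cohort
from .errors import (
    DegenerateCohortError,
    InfeasibleConfigError,
    TargetRangeError,
    UnfittedConfigError,
)

TRIAGE = "TRIAGE"
REFER = "REFER"
SAFETY_NET = "SAFETY_NET"

READER_1 = "reader_1"
READER_2 = "reader_2"
AVERAGE = "average"
SAMPLED = "sampled"

_TOL = 1e-12  # feasibility slack when comparing weighted fractions to targets


@dataclass(frozen=True)
class OperatingConfig:
    """A normal-triage + safety-net operating point.

    ``nt_target`` is the desired algorithmic sensitivity of the triage
    threshold (fraction of cancer mass kept above ``theta_low``);
    ``sn_target`` the desired algorithmic specificity of the safety net
    (fraction of normal mass kept below ``theta_high``).
    """

    nt_target: float
    sn_target: float
    theta_low: Optional[float] = None
    theta_high: Optional[float] = None
    weighted: bool = True  # whether thresholds were fitted with weights

    @property
    def name(self) -> str:
        return f"NT@{self.nt_target:g}+SN@{self.sn_target:g}"

    @property
    def fitted(self) -> bool:
        return self.theta_low is not None and self.theta_high is not None

    @classmethod
    def fit(cls, validation: Cohort, weights: np.ndarray,
            nt_target: float, sn_target: float,
            weighted: bool = True) -> "OperatingConfig":
        """Fit both thresholds on the validation split.

        Raises :class:`InfeasibleConfigError` when the fitted safety-net
        threshold falls below the triage threshold.
        """
        w = weights if weighted else np.ones(validation.n)
        low = fit_triage_threshold(validation, w, nt_target)
        high = fit_safety_net_threshold(validation, w, sn_target)
        if high < low:
            raise InfeasibleConfigError(
                f"NT@{nt_target:g}+SN@{sn_target:g}: safety-net threshold "
                f"{high:.6g} below triage threshold {low:.6g}")
        return cls(nt_target, sn_target, low, high, weighted)


@dataclass(frozen=True)
class StandaloneConfig:
    """Single-threshold standalone operating point: positive iff s >= threshold."""

    threshold: float
    sensitivity_target: float

    @property
    def name(self) -> str:
        return f"AI standalone (Se target {self.sensitivity_target:g})"


@dataclass(frozen=True)
class RoutedDecision:
    """Per-study routing outcome for one reader-selection rule."""

    study_id: str
    route: str
    system_call: str  # POSITIVE / NEGATIVE / SPLIT (averaged disagreeing readers)
    reader_call_used: Optional[str] = None


def _check_target(value: float, what: str) -> float:
    if not (0.0 < value <= 1.0):
        raise TargetRangeError(f"{what} must lie in (0, 1], got {value!r}")
    return float(value)


def _weighted_tail_threshold(scores, weights, member, target, side):
    """Shared candidate sweep for both threshold fits.

    side='ge': largest theta with weighted member fraction scoring >= theta
    at least ``target``; side='le': smallest theta with fraction <= theta at
    least ``target``.
    """
    scores = np.asarray(scores, dtype=float)
    weights = np.asarray(weights, dtype=float)
    member_scores = scores[member]
    member_w = weights[member]
    order = np.argsort(member_scores, kind="mergesort")
    sorted_scores = member_scores[order]
    cum_w = np.concatenate([[0.0], np.cumsum(member_w[order])])
    total = cum_w[-1]

    candidates = np.unique(scores)
    if side == "ge":
        candidates = np.unique(np.concatenate([candidates, [0.0]]))
        # weight of member scores >= theta
        idx = np.searchsorted(sorted_scores, candidates, side="left")
        frac = (total - cum_w[idx]) / total
        feasible = frac >= target - _TOL
        return float(candidates[feasible].max())
    # weight of member scores <= theta
    idx = np.searchsorted(sorted_scores, candidates, side="right")
    frac = cum_w[idx] / total
    feasible = frac >= target - _TOL
    return float(candidates[feasible].min())


def fit_triage_threshold(validation: Cohort, weights: np.ndarray,
                         nt_target: float) -> float:
    """Largest threshold keeping >= nt_target of the weighted cancer mass above it."""
    _check_target(nt_target, "nt_target")
    cancers = validation.is_cancer
    if not cancers.any():
        raise DegenerateCohortError("validation cohort contains no cancers")
    return _weighted_tail_threshold(validation.scores, weights, cancers,
                                    nt_target, side="ge")


def fit_safety_net_threshold(validation: Cohort, weights: np.ndarray,
                             sn_target: float) -> float:
    """Smallest threshold keeping >= sn_target of the weighted normal mass below it."""
    _check_target(sn_target, "sn_target")
    normals = ~validation.is_cancer
    if not normals.any():
        raise DegenerateCohortError("validation cohort contains no normals")
    return _weighted_tail_threshold(validation.scores, weights, normals,
                                    sn_target, side="le")


def fit_standalone_threshold(validation: Cohort, weights: np.ndarray,
                             target_sensitivity: float) -> StandaloneConfig:
    """Largest threshold achieving at least the target weighted sensitivity."""
    _check_target(target_sensitivity, "target_sensitivity")
    cancers = validation.is_cancer
    if not cancers.any():
        raise DegenerateCohortError("validation cohort contains no cancers")
    theta = _weighted_tail_threshold(validation.scores, weights, cancers,
                                     target_sensitivity, side="ge")
    return StandaloneConfig(threshold=theta, sensitivity_target=target_sensitivity)


# ---------------------------------------------------------------------- #
# routing


def _require_fitted(config: OperatingConfig) -> OperatingConfig:
    if not isinstance(config, OperatingConfig) or not config.fitted:
        raise UnfittedConfigError(
            "OperatingConfig has no fitted thresholds; call OperatingConfig.fit "
            "or set theta_low/theta_high explicitly")
    return config


def route_labels(scores: np.ndarray, config: OperatingConfig) -> np.ndarray:
    """Vectorised route per study (TRIAGE / REFER / SAFETY_NET)."""
    _require_fitted(config)
    s = np.asarray(scores, dtype=float)
    return np.where(s < config.theta_low, TRIAGE,
                    np.where(s > config.theta_high, SAFETY_NET, REFER))


def _system_calls(scores: np.ndarray, theta_low: float, theta_high: float,
                  reader_calls: np.ndarray) -> np.ndarray:
    """Array kernel: combined system call, fractional reader calls allowed."""
    s = np.asarray(scores, dtype=float)
    return np.where(s < theta_low, 0.0,
                    np.where(s > theta_high, 1.0,
                             np.asarray(reader_calls, dtype=float)))


def system_calls(cohort: Cohort, config: OperatingConfig,
                 reader_calls: np.ndarray) -> np.ndarray:
    """Combined decision per study as a recall probability in [0, 1].

    ``reader_calls`` is the per-study reader decision used on referral; it
    may be fractional (reader averaging contributes 0, 0.5 or 1).
    """
    _require_fitted(config)
    return _system_calls(cohort.scores, config.theta_low, config.theta_high,
                         reader_calls)


def select_reader_calls(cohort: Cohort, reader_selector: str,
                        rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """Per-study reader recall indicator under one selection rule."""
    matrix = cohort.reader_matrix
    if reader_selector == READER_1:
        return matrix[:, 0]
    if reader_selector == READER_2:
        return matrix[:, 1]
    if reader_selector == AVERAGE:
        return matrix.mean(axis=1)
    if reader_selector == SAMPLED:
        if rng is None:
            raise ValueError("reader_selector='sampled' requires an rng")
        picks = rng.integers(0, 2, size=cohort.n)
        return matrix[np.arange(cohort.n), picks]
    raise ValueError(f"unknown reader_selector {reader_selector!r}")


def route_cohort(test: Cohort, config: OperatingConfig,
                 reader_selector: str = AVERAGE,
                 rng: Optional[np.random.Generator] = None) -> pd.DataFrame:
    """Route every study and record the combined decision.

    Returns a frame with columns study_id, route, p_positive, system_call,
    reader_call_used. ``p_positive`` is the recall probability of the
    combined system (fractional only under reader averaging on a
    disagreement, in which case system_call is ``SPLIT``).
    """
    _require_fitted(config)
    reader = select_reader_calls(test, reader_selector, rng)
    routes = route_labels(test.scores, config)
    calls = system_calls(test, config, reader)
    referred = routes == REFER
    reader_used = np.where(referred,
                           np.where(reader >= 0.5, RECALL, NO_RECALL), "")
    # with averaged, disagreeing readers the referred call is genuinely split
    token = np.where(calls > 0.5, "POSITIVE",
                     np.where(calls < 0.5, "NEGATIVE", "SPLIT"))
    reader_used = np.where(referred & (token == "SPLIT"), "", reader_used)
    return pd.DataFrame({
        "study_id": test.study_ids,
        "route": routes,
        "p_positive": calls,
        "system_call": token,
        "reader_call_used": reader_used,
    })


def triaging_performance(test: Cohort, weights: np.ndarray,
                         config: OperatingConfig) -> float:
    """Weighted fraction of ALL studies that are truly normal and triaged.

    The automatable share of the worklist: safety-net studies are also
    automated but are reported separately, not counted here.
    """
    _require_fitted(config)
    w = np.asarray(weights, dtype=float)
    triaged_normal = (~test.is_cancer) & (test.scores < config.theta_low)
    return float(w[triaged_normal].sum() / w.sum())


def confident_subset(test: Cohort, config: OperatingConfig) -> Cohort:
    """Records outside the referral band [theta_low, theta_high], order kept."""
    _require_fitted(config)
    s = test.scores
    mask = (s < config.theta_low) | (s > config.theta_high)
    return test.subset(mask)


def with_thresholds(nt_target: float, sn_target: float,
                    theta_low: float, theta_high: float) -> OperatingConfig:
    """Build a config from explicit thresholds (no fitting)."""
    if theta_high < theta_low:
        raise InfeasibleConfigError(
            f"theta_high {theta_high:.6g} below theta_low {theta_low:.6g}")
    return OperatingConfig(nt_target, sn_target, theta_low, theta_high)
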