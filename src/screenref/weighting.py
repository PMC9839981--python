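"""Enrichment correction for cancer-oversampled cohorts.

Study datasets deliberately over-represent cancers relative to screening
prevalence. Per-label inverse-probability weights restore the population
mix: each record gets

    w_i = target_proportion(label_i) / sample_proportion(label_i)

with targets (pi, 1 - pi) for cancer/normal. Weighted label proportions
then equal the population's exactly. Weights enter every metric in ratio
form, so their overall scale is irrelevant and no normalisation is applied.

Because the default weights are constant within a label, weighted
sensitivity and specificity coincide with their unweighted counterparts;
weighting matters only for cross-label quantities such as triaging
performance, ROC curves and AUROC. A generic stratum hook supports
target proportions over any categorical column.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort import CANCER, NORMAL, Cohort
from .errors import DegenerateCohortError


@dataclass(frozen=True)
class WeightingScheme:
    """Per-level bookkeeping of one weighting: targets, sample mix, weights."""

    target_proportions: Mapping[str, float]
    sample_proportions: Mapping[str, float]
    weights: Mapping[str, float]

    def __post_init__(self):
        total = sum(self.target_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"target proportions must sum to 1, got {total}")
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be strictly positive")


def stratum_weights(cohort: Cohort, column: str,
                    targets: Mapping[str, float]) -> tuple[np.ndarray, WeightingScheme]:
    """Weights matching the proportions of ``column`` levels to ``targets``.

    Extension hook for weighting schemes finer than the two-label default.
    """
    values = cohort.data[column].astype(str)
    counts = values.value_counts()
    n = len(values)
    sample_props, level_weights = {}, {}
    for level, target in targets.items():
        count = int(counts.get(level, 0))
        if count == 0:
            raise DegenerateCohortError(
                f"no records with {column}={level}; cannot weight towards it")
        sample_props[level] = count / n
        level_weights[level] = float(target) / sample_props[level]
    unknown = set(counts.index) - set(targets)
    if unknown:
        raise DegenerateCohortError(
            f"levels of {column} without a target proportion: {sorted(unknown)}")
    scheme = WeightingScheme(dict(targets), sample_props, level_weights)
    return values.map(level_weights).to_numpy(dtype=float), scheme


def compute_prevalence_weights(cohort: Cohort) -> np.ndarray:
    """Per-study weights taking the cohort to the population cancer rate.

    After weighting, the weighted prevalence equals
    ``cohort.population_prevalence`` to machine precision.
    """
    pi = cohort.population_prevalence
    weights, _ = stratum_weights(cohort, "label", {CANCER: pi, NORMAL: 1.0 - pi})
    return weights


def weighting_scheme(cohort: Cohort) -> WeightingScheme:
    pi = cohort.population_prevalence
    _, scheme = stratum_weights(cohort, "label", {CANCER: pi, NORMAL: 1.0 - pi})
    return scheme


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size, (sum w)^2 / sum w^2.

    Reported alongside weighted estimates as a diagnostic of how much the
    enrichment correction inflates variance.
    """
    w = np.asarray(weights, dtype=float)
    if w.size == 0 or np.any(w <= 0):
        raise ValueError("weights must be a non-empty strictly positive vector")
    return float(w.sum() ** 2 / np.square(w).sum())
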