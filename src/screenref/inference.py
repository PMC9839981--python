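"""Resampling inference: two-step bootstrap CIs and paired permutation tests.

Reader variability and sampling variability are both real sources of
uncertainty in a double-reader evaluation, so every bootstrap replicate
(a) samples one of the two recorded reader decisions per study and then
(b) resamples studies with replacement, recomputing the metric on the
replicate (the standalone-AI pathway skips step (a) since it uses no
reader). CIs are the 2.5/97.5 percentile of the replicate distribution;
the point estimate always comes from the reader-averaged evaluation of
the original cohort. Replicates on which the metric is undefined (e.g. a
resample without cancers) are redrawn and counted.

The paired permutation test for a difference between two decision
pathways samples one reader per trial where a reader decision is needed
and then swaps the per-study (a, b) call pair with probability 1/2; the
two-sided p-value uses add-one smoothing, p = (1 + #{|D*| >= |D_obs|}) /
(P + 1), which keeps p positive and the test valid. For small cohorts
with reader-free calls the full 2^k swap distribution can be enumerated
exactly.

All resampling is a pure function of (inputs, seed): one root seed is
split into per-purpose child streams so adding a metric never perturbs
another's draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import Cohort
from .errors import DegenerateCohortError
from .metrics import (
    RADIOLOGIST,
    STANDALONE_AI,
    _auroc,
    _sensitivity,
    _specificity,
    pathway_calls,
)
from .referral import OperatingConfig, StandaloneConfig, _system_calls

SENSITIVITY = "sensitivity"
SPECIFICITY = "specificity"
AUROC = "auroc"
TRIAGE = "triage"
METRICS = (SENSITIVITY, SPECIFICITY, AUROC, TRIAGE)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class InferenceSettings:
    """Resampling configuration echoed into every output artifact."""

    n_bootstrap: int = 1000
    n_permutations: int = 10_000
    seed: int = 0


@dataclass(frozen=True)
class MetricEstimate:
    point: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    seed: int
    metric: str = ""
    pathway: str = ""
    n_redrawn: int = 0

    def __str__(self):
        return (f"{self.point:.4f} (95% CI {self.ci_low:.4f}-{self.ci_high:.4f}, "
                f"B={self.n_bootstrap})")


@dataclass(frozen=True)
class PermutationResult:
    delta_observed: float
    p_two_sided: float
    n_permutations: int
    seed: int
    method: str = "monte-carlo"


def _per_label_weights(is_cancer: np.ndarray, pi: float) -> np.ndarray:
    n = is_cancer.size
    n_cancer = int(is_cancer.sum())
    if n_cancer in (0, n):
        # single-label resample: within-label metrics are ratios, so any
        # constant weight is equivalent
        return np.ones(n)
    w_cancer = pi / (n_cancer / n)
    w_normal = (1.0 - pi) / ((n - n_cancer) / n)
    return np.where(is_cancer, w_cancer, w_normal)


def _replicate_metric(metric, calls, scores, is_cancer, weights, config):
    if metric == SENSITIVITY:
        return _sensitivity(calls, is_cancer, weights)
    if metric == SPECIFICITY:
        return _specificity(calls, is_cancer, weights)
    if metric == AUROC:
        return _auroc(scores, is_cancer, weights)
    if metric == TRIAGE:
        triaged = (~is_cancer) & (scores < config.theta_low)
        return float(weights[triaged].sum() / weights.sum())
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def _point_estimate(metric, cohort, weights, pathway, config, standalone):
    calls = pathway_calls(cohort, pathway, config=config, standalone=standalone)
    return _replicate_metric(metric, calls, cohort.scores, cohort.is_cancer,
                             np.asarray(weights, dtype=float), config)


def _pathway_replicate_calls(pathway, scores, reader, config, standalone):
    if pathway == RADIOLOGIST:
        return reader
    if pathway == STANDALONE_AI:
        return (scores >= standalone.threshold).astype(float)
    return _system_calls(scores, config.theta_low, config.theta_high, reader)


def bootstrap_ci(cohort: Cohort, weights, pathway: str, metric: str,
                 config: Optional[OperatingConfig] = None,
                 standalone: Optional[StandaloneConfig] = None,
                 n_bootstrap: int = 1000, seed: int = 0,
                 recompute_weights: bool = True) -> MetricEstimate:
    """Two-step bootstrap percentile CI of one pathway metric.

    With ``recompute_weights`` (default) the per-label enrichment weights
    are refit on every resample so the weighted prevalence stays pinned to
    the population value.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be >= 2")
    reader_rng, resample_rng = (np.random.default_rng(s)
                                for s in np.random.SeedSequence(seed).spawn(2))
    scores = cohort.scores
    is_cancer = cohort.is_cancer
    reader_matrix = cohort.reader_matrix
    base_w = np.asarray(weights, dtype=float)
    pi = cohort.population_prevalence
    uses_reader = pathway != STANDALONE_AI

    point = _point_estimate(metric, cohort, base_w, pathway, config, standalone)

    n = cohort.n
    rows = np.arange(n)
    stats = np.empty(n_bootstrap)
    n_redrawn = 0
    for b in range(n_bootstrap):
        for _ in range(_MAX_REDRAWS):
            idx = resample_rng.integers(0, n, n)
            y = is_cancer[idx]
            n_cancer = int(y.sum())
            needs_cancer = metric in (SENSITIVITY, AUROC)
            needs_normal = metric in (SPECIFICITY, AUROC, TRIAGE)
            if (needs_cancer and n_cancer == 0) or (needs_normal and n_cancer == n):
                n_redrawn += 1
                continue
            break
        else:
            raise DegenerateCohortError(
                f"metric {metric} undefined on {_MAX_REDRAWS} consecutive resamples")
        s = scores[idx]
        w = _per_label_weights(y, pi) if recompute_weights else base_w[idx]
        reader = (reader_matrix[idx, reader_rng.integers(0, 2, n)]
                  if uses_reader else None)
        calls = _pathway_replicate_calls(pathway, s, reader, config, standalone)
        stats[b] = _replicate_metric(metric, calls, s, y, w, config)

    lo, hi = np.percentile(stats, [2.5, 97.5])
    return MetricEstimate(point=point, ci_low=float(lo), ci_high=float(hi),
                          n_bootstrap=n_bootstrap, seed=seed, metric=metric,
                          pathway=pathway, n_redrawn=n_redrawn)


def bootstrap_delta_ci(cohort: Cohort, weights, pathway_a: str, pathway_b: str,
                       metric: str,
                       config_a: Optional[OperatingConfig] = None,
                       config_b: Optional[OperatingConfig] = None,
                       standalone: Optional[StandaloneConfig] = None,
                       n_bootstrap: int = 1000, seed: int = 0,
                       recompute_weights: bool = True) -> MetricEstimate:
    """Paired bootstrap CI for a pathway difference, in percentage points.

    Both pathways are evaluated on the SAME resample and the same sampled
    reader decisions, preserving the pairing that the observed difference
    rests on.
    """
    reader_rng, resample_rng = (np.random.default_rng(s)
                                for s in np.random.SeedSequence(seed).spawn(2))
    scores, is_cancer = cohort.scores, cohort.is_cancer
    reader_matrix = cohort.reader_matrix
    base_w = np.asarray(weights, dtype=float)
    pi = cohort.population_prevalence

    point = 100.0 * (
        _point_estimate(metric, cohort, base_w, pathway_a, config_a, standalone)
        - _point_estimate(metric, cohort, base_w, pathway_b, config_b, standalone))

    n = cohort.n
    stats = np.empty(n_bootstrap)
    n_redrawn = 0
    for b in range(n_bootstrap):
        for _ in range(_MAX_REDRAWS):
            idx = resample_rng.integers(0, n, n)
            y = is_cancer[idx]
            if ((metric in (SENSITIVITY, AUROC) and not y.any())
                    or (metric in (SPECIFICITY, AUROC, TRIAGE) and y.all())):
                n_redrawn += 1
                continue
            break
        else:
            raise DegenerateCohortError(
                f"metric {metric} undefined on {_MAX_REDRAWS} consecutive resamples")
        s = scores[idx]
        w = _per_label_weights(y, pi) if recompute_weights else base_w[idx]
        reader = reader_matrix[idx, reader_rng.integers(0, 2, n)]
        va = _replicate_metric(metric,
                               _pathway_replicate_calls(pathway_a, s, reader,
                                                        config_a, standalone),
                               s, y, w, config_a)
        vb = _replicate_metric(metric,
                               _pathway_replicate_calls(pathway_b, s, reader,
                                                        config_b, standalone),
                               s, y, w, config_b)
        stats[b] = 100.0 * (va - vb)

    lo, hi = np.percentile(stats, [2.5, 97.5])
    return MetricEstimate(point=point, ci_low=float(lo), ci_high=float(hi),
                          n_bootstrap=n_bootstrap, seed=seed,
                          metric=f"delta_{metric}",
                          pathway=f"{pathway_a}-{pathway_b}", n_redrawn=n_redrawn)


# ---------------------------------------------------------------------- #
# permutation test


def _as_reader_indexed(calls, n) -> np.ndarray:
    """Normalise calls to an (n, 2) array: column j = call if reader j is used."""
    arr = np.asarray(calls, dtype=float)
    if arr.ndim == 1:
        arr = np.column_stack([arr, arr])
    if arr.shape != (n, 2):
        raise ValueError(f"calls must have shape ({n},) or ({n}, 2), got {arr.shape}")
    return arr


def permutation_test(cohort: Cohort, weights, calls_a, calls_b, metric: str,
                     n_permutations: int = 10_000, seed: int = 0,
                     method: str = "auto", _chunk: int = 512
                     ) -> PermutationResult:
    """Paired two-sided permutation test for a Se or Sp difference (a - b).

    ``calls_a``/``calls_b`` are per-study recall calls of the two pathways,
    either a single vector or an (n, 2) array giving the call under each
    reader; reader-dependent calls are averaged per study (the estimator
    used for point estimates). Each trial swaps the per-study (a, b) call
    pair — both readers' calls as a block — with probability 1/2 and
    recomputes the difference; under the null that the two pathways are
    exchangeable this sign-flip group is exact. Because the statistic
    lives on a coarse lattice (call differences are multiples of half a
    label weight), ties with the observed value carry real mass and are
    credited 1/2 (mid-p); full credit would make the test noticeably
    conservative. p = (1 + #{|D*| > |D_obs|} + 0.5 #{|D*| = |D_obs|}) /
    (P + 1), and identical arms give p = 1 by convention.
    ``method='exact'`` enumerates all 2^k patterns over the k discordant
    studies instead of sampling.
    """
    if metric not in (SENSITIVITY, SPECIFICITY):
        raise ValueError("permutation test supports sensitivity or specificity")
    if n_permutations < 100 and method != "exact":
        raise ValueError("n_permutations must be >= 100")
    n = cohort.n
    a = _as_reader_indexed(calls_a, n)
    b = _as_reader_indexed(calls_b, n)

    w = np.asarray(weights, dtype=float)
    mask = cohort.is_cancer if metric == SENSITIVITY else ~cohort.is_cancer
    if not mask.any():
        raise DegenerateCohortError(f"{metric} undefined: relevant label absent")
    wm = np.where(mask, w, 0.0)
    sign = 1.0 if metric == SENSITIVITY else -1.0  # Sp flips call polarity
    denom = wm.sum()

    # per-study reader-averaged contribution of the (a - b) difference
    d = sign * wm * (a.mean(axis=1) - b.mean(axis=1)) / denom
    delta_obs = float(d.sum())
    tol = 1e-12

    nz = d[d != 0.0]
    k = nz.size
    if k == 0:  # the two arms make identical calls on every relevant study
        return PermutationResult(delta_observed=0.0, p_two_sided=1.0,
                                 n_permutations=0, seed=seed, method="degenerate")

    def _tally(deltas):
        greater = np.abs(deltas) > abs(delta_obs) + tol
        tied = np.abs(np.abs(deltas) - abs(delta_obs)) <= tol
        return float(np.count_nonzero(greater) + 0.5 * np.count_nonzero(tied))

    if method == "auto":
        method = "exact" if k <= 16 else "monte-carlo"

    if method == "exact":
        if k > 20:
            raise ValueError(
                f"exact enumeration infeasible for {k} discordant studies")
        patterns = ((np.arange(2 ** k)[:, None] >> np.arange(k)) & 1)
        signs = 1.0 - 2.0 * patterns  # 0 -> keep, 1 -> swap (flips the sign)
        p = _tally(signs @ nz) / 2 ** k
        return PermutationResult(delta_observed=delta_obs, p_two_sided=p,
                                 n_permutations=2 ** k, seed=seed,
                                 method="exact")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    count = 0.0
    done = 0
    while done < n_permutations:
        c = min(_chunk, n_permutations - done)
        signs = 1.0 - 2.0 * (rng.random((c, k)) < 0.5)
        count += _tally(signs @ nz)
        done += c
    p = (1.0 + count) / (n_permutations + 1.0)
    return PermutationResult(delta_observed=delta_obs, p_two_sided=p,
                             n_permutations=n_permutations, seed=seed,
                             method="monte-carlo")
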