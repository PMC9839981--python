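"""Synthetic enriched double-reader screening cohorts with known truth.

The generator draws, per study, a latent Gaussian triple
(AI, reader 1, reader 2) with an explicit 3x3 correlation matrix

    [[1,        rho_ra, rho_ra],
     [rho_ra,   1,      rho_rr],
     [rho_ra,   rho_rr, 1     ]]

shared by both classes. The AI latent is shifted for cancers
(binormal model: cancers N(mu, sigma^2), normals N(0, 1)) and mapped to a
score in [0, 1] through the standard-normal CDF — a monotone map, so
AUROC is unaffected and scores must not be read as calibrated
probabilities. Reader calls threshold the reader latents; because the
class-conditional reader marginals stay standard normal whatever the
correlations, the cuts are plain Gaussian quantiles of the target
sensitivity/specificity and calibration is exact by construction.

Positive AI/reader correlation makes the exams the AI scores ambiguously
also harder for readers — the mechanism that lets the confident subset's
AUROC exceed overall performance.

Labels are drawn at the enriched prevalence min(E*pi, 0.5), emulating
deliberate oversampling of suspicious studies; the population prevalence
pi travels with the cohort so weighting can undo the enrichment.

Closed-form oracles: AUROC = Phi(mu / sqrt(1 + sigma^2)); and, in the
reader/AI-independence regime, combined sensitivity, specificity and
triaging performance of any threshold pair.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CANCER, NORMAL, NO_RECALL, RECALL, TEST, Cohort
from .errors import CorrelationStructureError, OutOfRegimeError

#: Default demo parameters echo a realistic modern screening regime:
#: AUROC ~ 0.95, reader Se 0.87 / Sp 0.934, prevalence 6 per 1000 —
#: illustrative, not fitted to any dataset.
_DEFAULT_MU = 2.326


@dataclass(frozen=True)
class SubgroupLevel:
    """One level of a synthetic stratum: name, mixing proportion, and a shift
    applied to the cancer AI latent mean (negative = harder for the AI)."""

    name: str
    proportion: float
    mu_shift: float = 0.0


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth parameters of a synthetic cohort."""

    n_studies: int = 10_000
    population_prevalence: float = 0.006
    enrichment_factor: float = 10.0
    binormal_mu: float = _DEFAULT_MU
    binormal_sigma: float = 1.0
    reader_se: float = 0.87
    reader_sp: float = 0.934
    rho_reader_ai: float = 0.3
    rho_inter_reader: float = 0.4
    subgroup_spec: Optional[Mapping[str, Sequence[SubgroupLevel]]] = None
    lesion_size_log_mm: Optional[tuple[float, float]] = (2.48, 0.5)
    split: str = TEST
    seed: int = 0

    def __post_init__(self):
        if self.n_studies < 1:
            raise ValueError("n_studies must be positive")
        if not 0 < self.population_prevalence < 1:
            raise ValueError("population_prevalence must lie in (0, 1)")
        if self.enrichment_factor < 1:
            raise ValueError("enrichment_factor must be >= 1")
        if self.binormal_mu < 0 or self.binormal_sigma <= 0:
            raise ValueError("binormal_mu must be >= 0 and binormal_sigma > 0")
        for name in ("reader_se", "reader_sp"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        for name in ("rho_reader_ai", "rho_inter_reader"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")

    @property
    def enriched_prevalence(self) -> float:
        return min(self.enrichment_factor * self.population_prevalence, 0.5)

    @property
    def correlation_matrix(self) -> np.ndarray:
        ra, rr = self.rho_reader_ai, self.rho_inter_reader
        return np.array([[1.0, ra, ra], [ra, 1.0, rr], [ra, rr, 1.0]])


def closed_form_auroc(params: GeneratorParams) -> float:
    """Binormal AUROC: Phi(mu / sqrt(1 + sigma^2))."""
    return float(norm.cdf(params.binormal_mu /
                          np.sqrt(1.0 + params.binormal_sigma ** 2)))


def calibrate_reader_thresholds(params: GeneratorParams) -> dict[str, float]:
    """Class-conditional cuts on the reader latent.

    The reader latent is marginally N(0, 1) within each class for any
    admissible correlation structure, so the cuts are exact quantiles:
    recall a cancer iff latent > Phi^-1(1 - Se), recall a normal iff
    latent > Phi^-1(Sp).
    """
    return {CANCER: float(norm.ppf(1.0 - params.reader_se)),
            NORMAL: float(norm.ppf(params.reader_sp))}


def _latent_thresholds(theta_low: float, theta_high: float) -> tuple[float, float]:
    """Map score-space thresholds back to the normal latent scale."""
    with np.errstate(divide="ignore"):
        return float(norm.ppf(theta_low)), float(norm.ppf(theta_high))


@dataclass(frozen=True)
class GroundTruth:
    """Oracle bookkeeping for one generated cohort."""

    params: GeneratorParams
    auroc: float
    reader_thresholds: Mapping[str, float]
    enriched_prevalence: float

    def routing_probabilities(self, theta_low: float, theta_high: float
                              ) -> dict[str, tuple[float, float, float]]:
        """Per class: (P triage, P refer, P safety-net) at the given thresholds."""
        t_low, t_high = _latent_thresholds(theta_low, theta_high)
        mu, sigma = self.params.binormal_mu, self.params.binormal_sigma
        out = {}
        for label, (m, s) in ((CANCER, (mu, sigma)), (NORMAL, (0.0, 1.0))):
            p_lo = float(norm.cdf((t_low - m) / s))
            p_hi = float(norm.sf((t_high - m) / s))
            out[label] = (p_lo, 1.0 - p_lo - p_hi, p_hi)
        return out

    def combined_metrics(self, theta_low: float, theta_high: float
                         ) -> tuple[float, float, float]:
        """Closed-form (Se, Sp, triaging performance) of the combined system.

        Valid only when the reader latents are independent of the AI latent
        (rho_reader_ai = 0): then the referred subset's reader operating
        point equals the marginal one and the pathway factorises.
        """
        if self.params.rho_reader_ai != 0.0:
            raise OutOfRegimeError(
                "closed-form combined metrics require rho_reader_ai = 0 "
                f"(got {self.params.rho_reader_ai})")
        p = self.routing_probabilities(theta_low, theta_high)
        tri_c, ref_c, sn_c = p[CANCER]
        tri_n, ref_n, sn_n = p[NORMAL]
        se = sn_c + ref_c * self.params.reader_se
        sp = tri_n + ref_n * self.params.reader_sp
        triage = (1.0 - self.params.population_prevalence) * tri_n
        return se, sp, triage


def closed_form_combined_metrics(params: GeneratorParams, theta_low: float,
                                 theta_high: float) -> tuple[float, float, float]:
    """Module-level convenience over :meth:`GroundTruth.combined_metrics`."""
    truth = GroundTruth(params, closed_form_auroc(params),
                        calibrate_reader_thresholds(params),
                        params.enriched_prevalence)
    return truth.combined_metrics(theta_low, theta_high)


def generate_cohort(params: GeneratorParams) -> tuple[Cohort, GroundTruth]:
    """Draw one enriched double-reader cohort; byte-identical per seed."""
    corr = params.correlation_matrix
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise CorrelationStructureError(
            f"latent correlation matrix is not positive definite for "
            f"rho_reader_ai={params.rho_reader_ai}, "
            f"rho_inter_reader={params.rho_inter_reader}") from exc

    rng = np.random.default_rng(params.seed)
    n = params.n_studies
    is_cancer = rng.random(n) < params.enriched_prevalence
    latents = rng.standard_normal((n, 3)) @ chol.T

    # optional subgroup columns; shifts act on the cancer AI latent mean
    mu = np.where(is_cancer, params.binormal_mu, 0.0)
    subgroup_columns: dict[str, np.ndarray] = {}
    if params.subgroup_spec:
        for column, levels in params.subgroup_spec.items():
            props = np.array([lv.proportion for lv in levels], dtype=float)
            props = props / props.sum()
            idx = rng.choice(len(levels), size=n, p=props)
            subgroup_columns[column] = np.array([levels[i].name for i in idx])
            shifts = np.array([lv.mu_shift for lv in levels])[idx]
            mu = mu + np.where(is_cancer, shifts, 0.0)

    sigma = np.where(is_cancer, params.binormal_sigma, 1.0)
    z_ai = mu + sigma * latents[:, 0]
    scores = norm.cdf(z_ai)

    cuts = calibrate_reader_thresholds(params)
    cut = np.where(is_cancer, cuts[CANCER], cuts[NORMAL])
    reader_1 = latents[:, 1] > cut
    reader_2 = latents[:, 2] > cut

    data = pd.DataFrame({
        "study_id": [f"S{i:07d}" for i in range(n)],
        "ai_score": scores,
        "label": np.where(is_cancer, CANCER, NORMAL),
        "reader_1": np.where(reader_1, RECALL, NO_RECALL),
        "reader_2": np.where(reader_2, RECALL, NO_RECALL),
        "split": params.split,
    })
    for column, values in subgroup_columns.items():
        data[column] = values
    if params.lesion_size_log_mm is not None:
        log_mean, log_sd = params.lesion_size_log_mm
        sizes = np.exp(rng.normal(log_mean, log_sd, size=n))
        data["lesion_size_mm"] = np.where(is_cancer, np.round(sizes, 1), np.nan)

    cohort = Cohort.from_dataframe(data, params.population_prevalence)
    truth = GroundTruth(params=params,
                        auroc=closed_form_auroc(params),
                        reader_thresholds=cuts,
                        enriched_prevalence=params.enriched_prevalence)
    return cohort, truth


def params_to_dict(params: GeneratorParams) -> dict:
    """JSON-serialisable snapshot (subgroup levels flattened to dicts)."""
    d = asdict(params)
    if params.subgroup_spec:
        d["subgroup_spec"] = {
            col: [asdict(lv) for lv in levels]
            for col, levels in params.subgroup_spec.items()}
    return d


def params_from_dict(d: Mapping) -> GeneratorParams:
    d = dict(d)
    if d.get("subgroup_spec"):
        d["subgroup_spec"] = {
            col: tuple(SubgroupLevel(**lv) for lv in levels)
            for col, levels in d["subgroup_spec"].items()}
    if d.get("lesion_size_log_mm") is not None:
        d["lesion_size_log_mm"] = tuple(d["lesion_size_log_mm"])
    return GeneratorParams(**d)
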