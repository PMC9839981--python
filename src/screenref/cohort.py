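"""Screening-cohort containers and the CSV interchange format.

A cohort is one tabular dataset of screening exams: a continuous AI
malignancy score in [0, 1], two independent reader decisions recorded
before any consensus conference, a ground-truth label (biopsy-confirmed
screen-detected cancer vs follow-up-proven normal), a split role, and
optional stratum attributes. Because study datasets oversample cancers,
the cohort also carries the assumed real-screening cancer rate
(``population_prevalence``) that downstream weighting corrects towards.

Interchange is plain UTF-8 comma-separated text with a mandatory header.
Labels and decisions are stored as literal tokens (``CANCER``/``NORMAL``,
``RECALL``/``NO_RECALL``) rather than 0/1 so that polarity mistakes fail
loudly. Missing optional values are empty cells, never sentinel numbers.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterator, Mapping
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import (
    CohortValidationError,
    DuplicateStudyIdError,
    SchemaError,
    ScoreRangeError,
    TokenError,
)

# Literal tokens of the interchange format.
CANCER = "CANCER"
NORMAL = "NORMAL"
RECALL = "RECALL"
NO_RECALL = "NO_RECALL"
VALIDATION = "VALIDATION"
TEST = "TEST"

LABELS = (CANCER, NORMAL)
READER_CALLS = (RECALL, NO_RECALL)
SPLITS = (VALIDATION, TEST)

REQUIRED_COLUMNS = ("study_id", "ai_score", "label", "reader_1", "reader_2", "split")
#: Optional columns with package-level semantics; any further column is kept
#: verbatim and treated as a user-defined stratum.
KNOWN_STRATA = ("site", "manufacturer", "acr_density", "lesion_size_mm",
                "finding_type", "biopsy_score")
#: Lesion attributes may only be present on cancer records.
CANCER_ONLY_COLUMNS = ("lesion_size_mm",)


@dataclass(frozen=True)
class StudyRecord:
    """One screening exam."""

    study_id: str
    ai_score: float
    label: str
    reader_1: str
    reader_2: str
    split: str
    site: Optional[str] = None
    manufacturer: Optional[str] = None
    acr_density: Optional[str] = None
    lesion_size_mm: Optional[float] = None
    finding_type: Optional[str] = None
    biopsy_score: Optional[str] = None


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value))


def _frame_violations(data: pd.DataFrame, population_prevalence: float):
    """Collect (exception class, message) pairs for every broken invariant.

    Shared between the raising constructor and the reporting validator so the
    two can never disagree about what counts as valid.
    """
    violations: list[tuple[type, str]] = []

    missing = [c for c in REQUIRED_COLUMNS if c not in data.columns]
    if missing:
        violations.append(
            (SchemaError, f"missing required column(s): {', '.join(missing)}"))
        return violations  # nothing else is checkable

    if len(data) == 0:
        violations.append((CohortValidationError, "cohort has no records"))
        return violations

    if not (0.0 < float(population_prevalence) < 1.0):
        violations.append((CohortValidationError,
                           f"population_prevalence must lie strictly in (0, 1), "
                           f"got {population_prevalence!r}"))

    ids = data["study_id"].astype(str)
    dup = ids[ids.duplicated()].unique()
    if dup.size:
        violations.append(
            (DuplicateStudyIdError,
             f"duplicate study_id values: {', '.join(map(str, dup[:5]))}"
             + ("..." if dup.size > 5 else "")))

    scores = pd.to_numeric(data["ai_score"], errors="coerce")
    bad_score = data.loc[scores.isna() | (scores < 0.0) | (scores > 1.0), "study_id"]
    for sid in bad_score.head(5):
        violations.append(
            (ScoreRangeError, f"study {sid}: ai_score must be a number in [0, 1]"))

    for col, allowed in (("label", LABELS), ("reader_1", READER_CALLS),
                         ("reader_2", READER_CALLS), ("split", SPLITS)):
        bad = data.loc[~data[col].isin(allowed), "study_id"]
        for sid in bad.head(5):
            violations.append(
                (TokenError, f"study {sid}: {col} must be one of {allowed}"))

    for col in CANCER_ONLY_COLUMNS:
        if col not in data.columns:
            continue
        values = pd.to_numeric(data[col], errors="coerce")
        present = data[col].notna()
        on_normals = data.loc[present & (data["label"] == NORMAL), "study_id"]
        for sid in on_normals.head(5):
            violations.append(
                (CohortValidationError,
                 f"study {sid}: {col} set on a NORMAL record (cancer-only attribute)"))
        nonpositive = data.loc[present & ~(values > 0.0), "study_id"]
        for sid in nonpositive.head(5):
            violations.append(
                (CohortValidationError, f"study {sid}: {col} must be a positive number"))

    return violations


@dataclass
class Cohort:
    """An ordered collection of study records with its sampling bookkeeping.

    ``source_counts`` records how many records of each label were sampled into
    the dataset; together with ``population_prevalence`` it drives the
    enrichment correction in :mod:`screenref.weighting`.
    """

    data: pd.DataFrame
    population_prevalence: float
    source_counts: Mapping[str, int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.source_counts is None:
            self.source_counts = self._count_labels()

    def _count_labels(self) -> dict[str, int]:
        counts = self.data["label"].value_counts() if "label" in self.data else {}
        return {CANCER: int(counts.get(CANCER, 0)), NORMAL: int(counts.get(NORMAL, 0))}

    # ------------------------------------------------------------------ #
    # constructors

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, population_prevalence: float) -> "Cohort":
        """Validate a raw frame and build a cohort; raises named errors."""
        data = data.reset_index(drop=True).copy()
        violations = _frame_violations(data, population_prevalence)
        if violations:
            error_cls, message = violations[0]
            raise error_cls(message)
        data["study_id"] = data["study_id"].astype(str)
        data["ai_score"] = pd.to_numeric(data["ai_score"])
        if "lesion_size_mm" in data.columns:
            data["lesion_size_mm"] = pd.to_numeric(data["lesion_size_mm"])
        return cls(data=data, population_prevalence=float(population_prevalence))

    # ------------------------------------------------------------------ #
    # array views used throughout the package

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def study_ids(self) -> np.ndarray:
        return self.data["study_id"].to_numpy()

    @property
    def scores(self) -> np.ndarray:
        return self.data["ai_score"].to_numpy(dtype=float)

    @property
    def is_cancer(self) -> np.ndarray:
        return (self.data["label"] == CANCER).to_numpy()

    @property
    def reader_matrix(self) -> np.ndarray:
        """(n, 2) float array of reader recall indicators."""
        return np.column_stack(
            [(self.data[c] == RECALL).to_numpy(dtype=float)
             for c in ("reader_1", "reader_2")])

    @property
    def strata(self) -> tuple[str, ...]:
        """Names of all non-required columns (stratum attributes)."""
        return tuple(c for c in self.data.columns if c not in REQUIRED_COLUMNS)

    @property
    def records(self) -> Iterator[StudyRecord]:
        known = [f.name for f in dataclasses.fields(StudyRecord)]
        for row in self.data.itertuples(index=False):
            kwargs = {k: getattr(row, k) for k in known if hasattr(row, k)}
            kwargs = {k: (None if _is_missing(v) else v) for k, v in kwargs.items()}
            yield StudyRecord(**kwargs)

    # ------------------------------------------------------------------ #

    def subset(self, mask: np.ndarray) -> "Cohort":
        """Row subset preserving order; sampling counts are recomputed."""
        sub = self.data.loc[np.asarray(mask, dtype=bool)].reset_index(drop=True)
        return Cohort(data=sub, population_prevalence=self.population_prevalence)

    def split_cohorts(self) -> tuple["Cohort", "Cohort"]:
        """Return the (validation, test) cohorts per the ``split`` column."""
        is_val = (self.data["split"] == VALIDATION).to_numpy()
        return self.subset(is_val), self.subset(~is_val)


# ---------------------------------------------------------------------- #
# interchange


def read_cohort(path, population_prevalence: float) -> Cohort:
    """Read a cohort CSV.

    Required columns: study_id, ai_score, label, reader_1, reader_2, split.
    Unknown columns are preserved as strata; row order is preserved.
    """
    try:
        data = pd.read_csv(path, dtype={"study_id": str})
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header row") from exc
    return Cohort.from_dataframe(data, population_prevalence)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV such that :func:`read_cohort` round-trips it."""
    if len(cohort.data) == 0:
        raise CohortValidationError("refusing to write an empty cohort")
    cohort.data.to_csv(path, index=False)


def validate_cohort(cohort: Cohort) -> list[str]:
    """Report every violated invariant; empty list means the cohort is valid.

    Never raises — intended for data QC reports.
    """
    messages = [m for _, m in
                _frame_violations(cohort.data, cohort.population_prevalence)]
    if "label" in cohort.data.columns:
        actual = Cohort(cohort.data, 0.5)._count_labels()
        for lab in LABELS:
            if int(cohort.source_counts.get(lab, 0)) != actual[lab]:
                messages.append(
                    f"source_counts[{lab}]={cohort.source_counts.get(lab)} "
                    f"inconsistent with records ({actual[lab]})")
    return messages
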