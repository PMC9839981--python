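"""Named exception hierarchy.

Every user-facing failure mode gets its own class so callers (and the CLI)
can distinguish schema problems from statistical degeneracies without
string matching.
"""


class ScreenRefError(Exception):
    """Base class for all screenref errors."""


class SchemaError(ScreenRefError):
    """A required column is missing or the file layout is wrong."""


class ScoreRangeError(ScreenRefError):
    """An AI score is missing, non-numeric, or outside [0, 1]."""


class DuplicateStudyIdError(ScreenRefError):
    """Two records share a study_id within one cohort."""


class TokenError(ScreenRefError):
    """A label, reader decision, or split value is not a recognised token."""


class CohortValidationError(ScreenRefError):
    """A cohort-level invariant is violated (empty cohort, bad prevalence, ...)."""


class DegenerateCohortError(ScreenRefError):
    """An operation needs both labels (or a specific label) and the cohort lacks it."""


class TargetRangeError(ScreenRefError, ValueError):
    """An operating target (NT / SN / sensitivity) is outside (0, 1]."""


class InfeasibleConfigError(ScreenRefError):
    """The fitted safety-net threshold falls below the triage threshold."""


class UnfittedConfigError(ScreenRefError):
    """An OperatingConfig without fitted thresholds was used for routing."""


class OutOfRegimeError(ScreenRefError):
    """A closed-form oracle was called outside the regime where it is valid."""


class CorrelationStructureError(ScreenRefError):
    """The requested latent correlation matrix is not positive definite."""


class ConfigError(ScreenRefError):
    """A run configuration file is missing a required key or has a bad value."""
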