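"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`DualSubtypeError`
so callers can catch the package's errors without swallowing unrelated ones.
"""


class DualSubtypeError(Exception):
    """Base class for all errors raised by dualsubtype."""


class ConfigurationError(DualSubtypeError, ValueError):
    """Invalid configuration values (proportions, rates, schema violations)."""


class EmptyCohortError(ConfigurationError):
    """A cohort of zero samples was requested or supplied."""


class GeneLookupError(DualSubtypeError, KeyError):
    """A required gene is absent from the expression matrix or profile."""

    def __init__(self, missing):
        self.missing = tuple(missing)
        super().__init__(f"missing gene(s): {', '.join(self.missing)}")


class TrainingError(DualSubtypeError, ValueError):
    """Centroid training is impossible (e.g. a class with <2 samples)."""


class UndefinedScoreError(DualSubtypeError, ValueError):
    """A correlation score is undefined (zero-variance restriction)."""


class BootstrapFailureError(DualSubtypeError, RuntimeError):
    """More than half of the bootstrap replicates were degenerate."""


class ClassificationError(DualSubtypeError, RuntimeError):
    """Single/dual calling failed for a sample (e.g. missing threshold)."""


class StratificationError(DualSubtypeError, ValueError):
    """A clinical stratum required by the mixture weights is empty."""


class DegenerateTableError(DualSubtypeError, ValueError):
    """A contingency table has a zero expected count."""


class InsufficientDataError(DualSubtypeError, ValueError):
    """Too few observations for the requested statistic."""


class MissingStatusError(DualSubtypeError, ValueError):
    """Clinical receptor status cannot be derived from the available fields."""


class SchemaError(DualSubtypeError, ValueError):
    """A file or table violates the documented schema."""


class SeparationError(DualSubtypeError, RuntimeError):
    """(Quasi-)complete separation in a logistic regression."""
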