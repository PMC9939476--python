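"""Exception hierarchy.

Every error the package raises for a user-facing contract violation
derives from :class:`ThyroCascadeError`, so callers (and the CLI) can
distinguish contract failures from programming errors.
"""


class ThyroCascadeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(ThyroCascadeError):
    """A cohort file is missing a mandatory column or is otherwise malformed."""


class VocabularyError(ThyroCascadeError):
    """A category token cannot be mapped onto its closed vocabulary."""


class IntegrityError(ThyroCascadeError):
    """A cohort-level invariant is violated (e.g. duplicate patient ids)."""


class DegenerateTableError(ThyroCascadeError):
    """A contingency table has a zero margin, so the test is undefined."""


class CohortMismatchError(ThyroCascadeError):
    """Two binary tables claimed to describe the same cohort do not."""


class StratumEmptyError(ThyroCascadeError):
    """An event or non-event stratum required by an estimator is empty."""


class RuleCoverageError(ThyroCascadeError):
    """A cascade rule does not cover a first-stage category present in the data."""


class CostModelError(ThyroCascadeError):
    """A consumed test has no unit cost in the cost model."""


class ConfigError(ThyroCascadeError):
    """A simulation configuration is invalid (e.g. probabilities not summing to 1)."""


class InfeasibilityError(ThyroCascadeError):
    """A reconstruction constraint set is mutually inconsistent."""
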