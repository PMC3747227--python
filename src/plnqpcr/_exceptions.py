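"""Exception hierarchy for the package.

Every error raised on a user-facing path derives from :class:`QpcrError`
so callers (and the CLI) can catch one base class.
"""


class QpcrError(Exception):
    """Base class for all package errors."""


class SchemaError(QpcrError):
    """Input table does not have the declared columns or layout."""


class ParseError(QpcrError):
    """A cell could not be interpreted as a number or a known sentinel."""


class UniquenessError(QpcrError):
    """Duplicate (sample, technical replicate[, gene]) records."""


class EfficiencyLookupError(QpcrError):
    """A gene lacks an amplification-efficiency (or Cq1) entry."""


class DesignError(QpcrError):
    """The requested fixed/random structure cannot be built from the data."""


class ConfigurationError(QpcrError):
    """Inconsistent or incomplete run configuration."""


class NormalizationError(QpcrError):
    """Control-gene normalization could not be carried out."""


class DegenerateSampleError(QpcrError):
    """A posterior sample has zero variance (no information to test)."""


class StateError(QpcrError):
    """An operation needs state (e.g. retained latents) that is absent."""
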