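"""Exception hierarchy for the whisker-connectome pipeline.

Every stage raises a subclass of :class:`WhiskerConnectomeError` so that the
pipeline driver can halt with the stage name and the offending identifiers.
"""


class WhiskerConnectomeError(Exception):
    """Base class for all package errors."""


class SchemaError(WhiskerConnectomeError):
    """An experiment record or config file violates its schema."""


class OntologyError(WhiskerConnectomeError):
    """An acronym or structure id cannot be resolved in the ontology."""


class ConfigError(WhiskerConnectomeError):
    """A panel / generator / pipeline configuration violates its invariants."""


class DimensionError(WhiskerConnectomeError):
    """Array shapes are inconsistent (volume vs mask, matrix blocks)."""


class DegenerateInputError(WhiskerConnectomeError):
    """Input is structurally valid but degenerate (all-zero injection, empty graph)."""


class MissingFieldError(WhiskerConnectomeError):
    """A required field (e.g. specificity) is unset on a record."""


class CalibrationError(WhiskerConnectomeError):
    """Threshold calibration is infeasible on the given reference set."""


class EmptySetError(WhiskerConnectomeError):
    """An operation was asked to aggregate over an empty collection."""
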