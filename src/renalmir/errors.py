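"""Exception hierarchy shared across the pipeline stages."""


class RenalMirError(Exception):
    """Base class for all package errors."""


class ConfigurationError(RenalMirError, ValueError):
    """Invalid configuration (thresholds, cohort spec, pipeline config)."""


class DomainError(RenalMirError, ValueError):
    """Input value outside the operation's domain."""


class InsufficientDataError(RenalMirError, ValueError):
    """Too few usable observations for the requested fit or test."""


class DegenerateDataError(RenalMirError, ValueError):
    """Data with no usable variation (constant group, zero-variance fit)."""


class MarkerMissingError(RenalMirError, KeyError):
    """A required miRNA marker is absent from a sample or table."""

    def __init__(self, marker: str, context: str = ""):
        self.marker = marker
        msg = f"required marker {marker!r} is missing"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return self.args[0]


class SchemaError(RenalMirError, ValueError):
    """A tabular input does not match the expected column contract."""


class UsageError(RenalMirError, RuntimeError):
    """An operation was invoked on input it is not defined for."""


class ThresholdDerivationError(RenalMirError, ValueError):
    """Training data cannot support the requested cutoff derivation."""
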