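"""Exception hierarchy shared across the package."""


class OdormixError(Exception):
    """Base class for all package-specific errors."""


class DomainError(OdormixError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(OdormixError, ValueError):
    """A configuration object or registry entry is invalid or missing."""


class DataError(OdormixError, ValueError):
    """A dataset violates a structural requirement (degenerate feature, bad value)."""


class SizeError(DataError):
    """A collection is too small (or too large) for the requested operation."""


class ParseError(DataError):
    """A file could not be parsed; the message names the offending row/column."""


class StateError(OdormixError, RuntimeError):
    """An object is not in the state the operation requires (e.g. unfitted model)."""


class PipelineError(OdormixError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
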