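"""Exception hierarchy shared across pipeline stages."""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PipelineError, ValueError):
    """Invalid configuration or parameter value."""


class ParseError(PipelineError, ValueError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class IntegrityError(PipelineError, ValueError):
    """Referential-integrity violation between input tables."""


class EmptyInputError(PipelineError, ValueError):
    """An operation received an empty table, network or panel."""


class InsufficientDataError(PipelineError, ValueError):
    """Too few observations for the requested statistic."""


class GranularityError(PipelineError, ValueError):
    """Monthly/weekly granularity mismatch or unsupported granularity."""


class DependencyError(PipelineError, RuntimeError):
    """A pipeline stage is missing an artifact a prior stage produces."""
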