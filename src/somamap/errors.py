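"""Exception hierarchy shared across somamap modules."""


class SomamapError(Exception):
    """Base class for all somamap errors."""


class SwcParseError(SomamapError):
    """Malformed SWC content; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class SkeletonValidationError(SomamapError):
    """Skeleton violates a structural invariant (dangling parent, cycle, ...)."""


class EmptyResultError(SomamapError):
    """An operation produced an empty result where at least one element is required."""


class SchemaError(SomamapError):
    """A tabular input is missing required columns or has bad dtypes."""


class AnnotationError(SomamapError):
    """Neuron ids present in the data are missing from the annotation table."""

    def __init__(self, message: str, missing_ids: list[str] | None = None):
        self.missing_ids = list(missing_ids or [])
        if self.missing_ids:
            shown = ", ".join(self.missing_ids[:10])
            more = "" if len(self.missing_ids) <= 10 else f" (+{len(self.missing_ids) - 10} more)"
            message = f"{message}: {shown}{more}"
        super().__init__(message)


class ConfigError(SomamapError):
    """Invalid configuration value."""
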