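"""Exception hierarchy for inkcog."""


class InkcogError(Exception):
    """Base class for all package errors."""


class MalformedStreamError(InkcogError):
    """Pen-event stream violates the down/move/up phase grammar."""


class SessionParseError(InkcogError):
    """A session file record could not be parsed or validated."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ApplicabilityError(InkcogError):
    """A feature or component class is not applicable to the task."""


class FeatureUndefinedError(InkcogError):
    """The feature is undefined for this session (e.g. no strokes)."""


class AnnotationError(InkcogError):
    """A scoring annotation is missing fields or belongs to the wrong task family."""


class ConfigError(InkcogError):
    """Invalid simulation or pipeline configuration."""

    def __init__(self, message: str, fields: list[str] | None = None):
        self.fields = fields or []
        if self.fields:
            message = f"{message} (offending fields: {', '.join(self.fields)})"
        super().__init__(message)


class InsufficientDataError(InkcogError):
    """Too few observations for the requested statistic."""


class UndefinedStatisticError(InkcogError):
    """The statistic is undefined on this input (e.g. constant vector)."""


class UndefinedMetricError(InkcogError):
    """Classification metric undefined (e.g. single-class labels)."""
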