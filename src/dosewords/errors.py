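"""Exception types shared across the package."""


class DosewordsError(Exception):
    """Base class for package errors."""


class ConfigurationError(DosewordsError):
    """Invalid generator / pipeline configuration."""


class ValidationError(DosewordsError):
    """Malformed input records.

    ``offenders`` lists human-readable descriptions (with line numbers where
    available) of every offending record, not just the first.
    """

    def __init__(self, message: str, offenders: list[str] | None = None):
        self.offenders = list(offenders or [])
        if self.offenders:
            message = message + "\n  " + "\n  ".join(self.offenders)
        super().__init__(message)


class InsufficientDataError(DosewordsError):
    """Too little data for the requested summary (e.g. <3 surviving bins)."""


class UndefinedRateError(DosewordsError):
    """A rate whose denominator is zero."""
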