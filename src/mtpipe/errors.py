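"""Exception hierarchy for the pipeline.

Exit-code mapping used by the CLI: DataError -> 1, ConfigError -> 2.
"""


class MtpipeError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(MtpipeError):
    """Invalid dialect, geometry, or pipeline configuration."""


class DataError(MtpipeError):
    """Malformed or internally inconsistent subject data."""


class StreamParseError(DataError):
    """A delimited stream contained a non-numeric token.

    Carries enough context (subject, column, token position) to locate
    the offending cell in the raw export.
    """

    def __init__(self, message, subject_id=None, column=None, position=None):
        super().__init__(message)
        self.subject_id = subject_id
        self.column = column
        self.position = position


class MeasureUndefined(MtpipeError):
    """A trajectory measure is undefined for this trial.

    Raised for degenerate trials (too few samples, zero duration, no
    vertical progress).  Callers building tables catch this and emit an
    explicit missing value instead.
    """


class GenerationError(MtpipeError):
    """The simulator could not produce a terminating trial under the config."""


class ModelError(MtpipeError):
    """The regression model could not be specified or fit."""
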