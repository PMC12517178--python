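"""Exception hierarchy for the doc-eeg pipeline.

Every error raised on purpose by the package derives from :class:`DocEEGError`
so callers (and the CLI) can distinguish data problems from genuine bugs.
"""


class DocEEGError(Exception):
    """Base class for all doc-eeg errors."""


class FormatError(DocEEGError):
    """Unreadable or structurally invalid input file."""


class SchemaError(DocEEGError):
    """A table is missing required columns or has values of the wrong kind."""


class ParameterError(DocEEGError, ValueError):
    """An analysis parameter is outside its valid range."""


class LengthError(DocEEGError, ValueError):
    """A series is too short for the requested analysis."""


class DataQualityError(DocEEGError):
    """Recording quality too poor to analyse (e.g. almost everything rejected)."""


class DegenerateDataError(DocEEGError, ValueError):
    """A statistical test received data it cannot operate on (all ties, constant y...)."""


class ValidationError(DocEEGError, ValueError):
    """A clinical score is outside its defined range."""


class ConvergenceError(DocEEGError):
    """An iterative fit failed to converge."""
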