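"""Exception hierarchy.

Every error raised by this package derives from :class:`AnkleAdlError`, so
callers (and the CLI) can catch one type and turn it into a diagnostic.
"""


class AnkleAdlError(Exception):
    """Base class for all package errors."""


class FormatError(AnkleAdlError):
    """A file does not follow the expected dialect (e.g. missing column)."""


class EmptyInputError(FormatError):
    """A file contains no data rows."""


class SamplingError(AnkleAdlError):
    """Timestamps are not a uniform grid at the declared sample rate."""


class ValidationError(AnkleAdlError):
    """A domain-type invariant is violated."""


class FilterSpecError(AnkleAdlError):
    """A filter specification is unusable (e.g. cutoff at/above Nyquist)."""


class LengthError(AnkleAdlError):
    """A signal or recording is too short for the requested operation."""


class WindowingError(AnkleAdlError):
    """A segment is too short to be split into the configured RMS windows."""


class ScriptError(AnkleAdlError):
    """An activity script is infeasible or breaks posture ordering rules."""
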