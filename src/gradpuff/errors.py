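"""Exception hierarchy.

Every error raised by gradpuff derives from :class:`GradpuffError`, so callers
(in particular the study pipeline, which runs in continue-on-error mode) can
catch package failures without swallowing programming errors.
"""


class GradpuffError(Exception):
    """Base class for all gradpuff errors."""


class ConfigurationError(GradpuffError):
    """A configuration object violates one of its invariants."""


class FormatError(GradpuffError):
    """A file could not be parsed in the expected text format."""


class ValidationError(GradpuffError):
    """Data failed a consistency check (e.g. overlapping annotations)."""


class ParameterError(GradpuffError):
    """An operation was called with inadmissible parameters."""


class DegenerateInputError(GradpuffError):
    """The input is degenerate for the requested operation (e.g. constant
    signal for z-scoring, zero-mass spectrum for a divergence)."""


class LengthError(GradpuffError):
    """A signal or segment is too short for the requested analysis window."""
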