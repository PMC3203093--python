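"""Exception hierarchy for the screening pipeline.

Input/configuration problems are distinguished from scales that are
merely *unscreenable* (degenerate data, too few converged items): the
former are caller mistakes, the latter are legitimate outcomes that the
pipeline reports and moves on from.
"""


class AwarescreenError(Exception):
    """Base class for all package errors."""


class InputError(AwarescreenError):
    """Malformed input data (missing id column, duplicate ids, ...)."""


class ConfigError(AwarescreenError):
    """Invalid configuration (unknown item label, bad scale spec, ...)."""


class DegenerateDataError(AwarescreenError):
    """Data admit no meaningful analysis (e.g. all respondent rows identical)."""


class UnscreenableError(AwarescreenError):
    """The scale cannot be screened (fewer than 3 converged items, ...)."""
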