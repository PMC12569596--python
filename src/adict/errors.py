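"""Exception hierarchy mapped to CLI exit codes."""


class AdictError(Exception):
    """Base class for all pipeline errors."""

    exit_code = 1


class ConfigurationError(AdictError):
    """A parameter, config key, or column mapping is invalid or missing."""

    exit_code = 2


class InputError(AdictError):
    """An input file is unreadable, empty, or malformed."""

    exit_code = 3


class AnalysisError(AdictError):
    """The data do not support the requested computation."""

    exit_code = 4
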