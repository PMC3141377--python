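"""Exception hierarchy shared across the package."""


class StromaSigError(Exception):
    """Base class for all package errors."""


class FormatError(StromaSigError, ValueError):
    """A file does not conform to the expected text dialect."""


class ConfigError(StromaSigError, ValueError):
    """A configuration object carries invalid or non-finite values."""


class AnalysisError(StromaSigError, ValueError):
    """An analysis precondition is violated (degenerate input, empty set, ...)."""
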