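"""Exception hierarchy; the CLI maps these to distinct exit codes."""


class TopoepiError(Exception):
    """Base class for all package errors."""


class ConfigError(TopoepiError):
    """Invalid configuration or parameter value."""


class DataError(TopoepiError):
    """Inconsistent or malformed input data."""


class NumericalError(TopoepiError):
    """A statistic is undefined or a fit failed numerically."""
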