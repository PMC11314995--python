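"""Exception hierarchy shared across the package."""


class TremorKitError(Exception):
    """Base class for all tremorkit errors."""


class ConfigError(TremorKitError):
    """Invalid configuration or parameter value."""


class DataError(TremorKitError):
    """Malformed, missing, or unusable input data."""


class ParseError(DataError):
    """A file could not be parsed in the expected dialect."""
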