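"""Exception types shared across the package."""


class BsascanError(Exception):
    """Base class for all package-specific errors."""


class ParseError(BsascanError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(BsascanError, ValueError):
    """Data violated a table invariant (counts, coordinates, sorting)."""


class ConfigError(BsascanError, ValueError):
    """A configuration value is inconsistent or refers to missing data."""
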