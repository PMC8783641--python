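"""Exception hierarchy shared across the package."""


class HippolfpError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(HippolfpError, ValueError):
    """A configuration value violates an invariant; names the offending field."""


class ParameterError(HippolfpError, ValueError):
    """An operation parameter is out of its valid domain (e.g. band above Nyquist)."""


class FormatError(HippolfpError, ValueError):
    """A file or container does not conform to the expected layout."""


class InsufficientDataError(HippolfpError, ValueError):
    """Not enough data to compute the requested quantity (e.g. <3 events)."""
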