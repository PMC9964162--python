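"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` (and its
subclasses) to exit code 3.
"""


class Gh51Error(Exception):
    """Base class for all package errors."""


class ConfigError(Gh51Error):
    """Invalid configuration (missing paths, out-of-range thresholds)."""


class DataError(Gh51Error):
    """Invalid or inconsistent input data."""


class ParseError(DataError):
    """Malformed file content; message names the offending line when known."""
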