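"""Exception hierarchy.

``ConfigError`` covers malformed configuration (CLI exit code 2);
``DataError`` covers malformed or inconsistent input data (CLI exit code 3).
"""


class PrewellError(Exception):
    """Base class for all package errors."""


class ConfigError(PrewellError):
    """Invalid configuration: bad schema, missing keys, out-of-range values."""


class DataError(PrewellError):
    """Invalid input data: malformed files, inconsistent records."""


class WhitelistError(DataError):
    """Malformed barcode whitelist."""


class MatrixFormatError(DataError):
    """Malformed sparse-matrix directory or MatrixMarket file."""
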