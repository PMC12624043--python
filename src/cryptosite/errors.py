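"""Exception hierarchy shared across the package."""


class CryptositeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CryptositeError, ValueError):
    """Malformed input file (PDB, TSV, FASTA)."""


class ConfigError(CryptositeError, ValueError):
    """Invalid or incomplete configuration (missing radii, bad thresholds...)."""


class DataError(CryptositeError, ValueError):
    """Input data is well-formed but scientifically inconsistent."""


class StateError(CryptositeError, RuntimeError):
    """An operation was called before its prerequisites were established."""


class DialectWarning(UserWarning):
    """Tolerable deviation from the expected file dialect."""
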