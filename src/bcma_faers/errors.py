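"""Exception hierarchy.

``ConfigurationError`` covers bad user-supplied configuration (missing table
files, empty lexicons, invalid simulation parameters) and maps to CLI exit
code 1.  ``DataError`` covers malformed data that cannot be skipped (e.g. a
value containing the field delimiter at write time) and maps to exit code 2.
"""


class BcmaFaersError(Exception):
    """Base class for package errors."""


class ConfigurationError(BcmaFaersError):
    """Invalid configuration: missing files, bad lexicon/dictionary/sim config."""


class DataError(BcmaFaersError):
    """Unrecoverable problem with the data being read or written."""
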