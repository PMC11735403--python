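"""Exception hierarchy shared across the pipeline.

Exit-code mapping in the CLI: ConfigurationError -> 2, DataError/FormatError -> 3.
"""


class AllelichromError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AllelichromError):
    """A config value, column mapping or sample name is wrong or missing."""


class FormatError(AllelichromError):
    """An input file violates its format contract (named record / line)."""


class DataError(AllelichromError):
    """Inputs parse but are inconsistent with each other."""


class UsageError(AllelichromError):
    """An operation was called with arguments outside its contract."""
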