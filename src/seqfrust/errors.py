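"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation failures exit 2, I/O
failures exit 3, statistical-precondition failures exit 4.
"""


class SeqFrustError(Exception):
    """Base class for all package errors."""


class ValidationError(SeqFrustError, ValueError):
    """Invalid input data: bad residue codes, malformed records, shape mismatches."""


class FileFormatError(ValidationError):
    """A file could not be parsed under any supported dialect."""


class StatisticsError(SeqFrustError, ValueError):
    """A statistical precondition is not met (too few pairs, zero variance, single class)."""
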