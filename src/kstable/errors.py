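"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`KStableError`, so callers (and the CLI) can separate usage and
data problems from genuine bugs.
"""


class KStableError(Exception):
    """Base class for all errors raised by kstable."""


class DatasetError(KStableError):
    """Invalid mutation record or dataset-level operation failure."""


class MutationTableError(DatasetError):
    """Malformed mutation table.

    Parameters
    ----------
    message:
        Human-readable description.
    row_errors:
        Optional list of ``(line_number, message)`` pairs, 1-based and
        counting the header as line 1.
    """

    def __init__(self, message, row_errors=None):
        self.row_errors = list(row_errors or [])
        if self.row_errors:
            detail = "; ".join(f"line {ln}: {msg}" for ln, msg in self.row_errors)
            message = f"{message} ({detail})"
        super().__init__(message)


class AAindexFormatError(KStableError):
    """Malformed AAindex1 flat file."""


class EncodingError(KStableError):
    """Feature encoding failure (unknown residue, incomplete attribute...)."""


class KStarError(KStableError):
    """K* classifier failure (schema mismatch, scale solver divergence...)."""
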