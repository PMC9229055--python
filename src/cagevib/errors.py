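"""Exception hierarchy shared by all cagevib modules.

The CLI maps these onto exit codes: :class:`FormatError` (and subclasses)
exit with 2, :class:`ContractError`/:class:`ConfigError` with 3.
"""


class CageVibError(Exception):
    """Base class for all cagevib errors."""


class FormatError(CageVibError):
    """A file does not have the expected structure (missing column, bad header)."""


class ParseError(FormatError):
    """A cell could not be parsed; carries the offending row index where known."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"{message} (row {row})")
        self.row = row


class ConfigError(CageVibError):
    """A configuration value violates its invariants."""


class ContractError(CageVibError):
    """An operation was called outside its precondition."""
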