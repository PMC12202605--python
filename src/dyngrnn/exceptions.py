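"""Exception types shared across the package."""


class DynGRNNError(Exception):
    """Base class for package errors."""


class FormatError(DynGRNNError, ValueError):
    """Malformed input file (ragged rows, empty table, ...)."""


class ParseError(DynGRNNError, ValueError):
    """A cell could not be parsed as a number; carries 1-based (row, col)."""

    def __init__(self, row: int, col: int, token: str):
        self.row = row
        self.col = col
        self.token = token
        super().__init__(f"non-numeric token {token!r} at row {row}, col {col}")


class DimensionError(DynGRNNError, ValueError):
    """Array dimensions violate a precondition."""


class ConfigError(DynGRNNError, ValueError):
    """Invalid configuration value."""


class SpecError(DynGRNNError, ValueError):
    """A synthetic-cohort specification is internally inconsistent."""
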