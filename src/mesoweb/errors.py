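"""Exception types shared across the package."""


class MesowebError(Exception):
    """Base class for package errors."""


class ConfigurationError(MesowebError, ValueError):
    """Raised when a generator or pipeline configuration is invalid."""


class SchemaError(MesowebError, ValueError):
    """Raised when an input table violates its declared schema.

    Carries enough context (file, row, column) to locate the offending cell.
    """

    def __init__(self, message: str, *, table: str | None = None,
                 row: int | None = None, column: str | None = None):
        self.table = table
        self.row = row
        self.column = column
        parts = [message]
        if table is not None:
            parts.append(f"table={table}")
        if row is not None:
            parts.append(f"row={row}")
        if column is not None:
            parts.append(f"column={column}")
        super().__init__("; ".join(parts))


class SpeciesLookupError(MesowebError, KeyError):
    """Raised when a record references a species missing a required attribute."""
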