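"""Exception hierarchy shared by all tcgabed modules."""

from __future__ import annotations


class TcgaBedError(Exception):
    """Base class for every error raised by tcgabed."""


class MalformedBarcodeError(TcgaBedError, ValueError):
    """An aliquot barcode does not match the TCGA barcode grammar."""


class EmptyIntervalError(TcgaBedError, ValueError):
    """A zero-based half-open interval is empty and has no one-based closed image."""


class ChromosomeError(TcgaBedError, ValueError):
    """A chromosome token cannot be normalized to chr1..chr22/chrX/chrY/chrM."""


class MalformedInputError(TcgaBedError):
    """A source data row cannot be interpreted; carries file/line/column context."""

    def __init__(self, message: str, *, path: str | None = None,
                 line: int | None = None, column: str | None = None):
        self.path = path
        self.line = line
        self.column = column
        where = []
        if path is not None:
            where.append(str(path))
        if line is not None:
            where.append(f"line {line}")
        if column is not None:
            where.append(f"column {column!r}")
        prefix = " ".join(where)
        super().__init__(f"{prefix}: {message}" if prefix else message)


class TableFormatError(MalformedInputError):
    """An annotation lookup table is malformed."""


class DocumentParseError(TcgaBedError):
    """A clinical/biospecimen document could not be parsed."""


class LinkageError(TcgaBedError):
    """Clinical or biospecimen data do not belong to the aliquot being assembled."""


class SchemaError(TcgaBedError, ValueError):
    """A BED column schema violates its structural invariants."""


class ConfigError(TcgaBedError):
    """A conversion job or configuration file is invalid; nothing has been written."""
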