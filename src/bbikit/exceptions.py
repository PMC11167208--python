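"""Typed error hierarchy.

Corrupt or invalid input fails fast with one of these; there is no
best-effort recovery mode.
"""


class BBIError(Exception):
    """Base class for every error raised by this package."""


# --- codec-level -----------------------------------------------------------

class UnknownMagic(BBIError):
    """First four bytes match neither BigWig nor BigBed in either byte order."""


class TruncatedFile(BBIError):
    """Byte source is shorter than a structure it must contain."""


class UnsupportedVersion(BBIError):
    """Header version older than 3 (zoom/summary layout differs)."""


class BadTreeMagic(BBIError):
    """Chromosome B+-tree signature mismatch."""


class CorruptNode(BBIError):
    """Tree node declares more items than its block size allows."""


class BadSectionKind(BBIError):
    """Wig section type byte is not bedgraph/varstep/fixedstep."""


class ItemOutOfBounds(BBIError):
    """A section item lies outside its declared base range."""


class UnterminatedString(BBIError):
    """BigBed rest-string runs past the end of its block."""


class BadIndexMagic(BBIError):
    """R-tree index signature mismatch."""


class UnsortedLeafItems(BBIError):
    """R-tree bulk load requires leaf items sorted by (chrom, start)."""


class BufferOverrun(BBIError):
    """Decompressed block exceeds the header's uncompressBufSize."""


# --- reader ----------------------------------------------------------------

class WrongFileType(BBIError):
    """BigWig-only API called on a BigBed handle, or vice versa."""


class ChromNotFound(BBIError):
    """Queried chromosome name is absent from the file."""


class InvertedRange(BBIError):
    """Query start greater than query end."""


class NoSuchZoomLevel(BBIError):
    """Requested reduction level is not in the file."""


# --- writer ----------------------------------------------------------------

class OverlapError(BBIError):
    """Overlapping intervals in a bedGraph/BigWig input stream."""


class UnsortedError(BBIError):
    """Input stream not sorted by (chromosome order, start)."""


class UnknownChrom(BBIError):
    """Stream references a chromosome missing from chrom.sizes."""


class ValueNotFinite(BBIError):
    """NaN or infinite data value in the input stream."""


class ChromLengthExceeded(BBIError):
    """Item end beyond the declared chromosome length."""


class RaggedFields(BBIError):
    """BED entries with inconsistent column counts."""


class SinkNotSeekable(BBIError):
    """Output sink cannot be patched and no temp-file fallback allowed."""


# --- autoSql ---------------------------------------------------------------

class AutoSqlSyntaxError(BBIError):
    """Schema text violates the autoSql table grammar."""

    def __init__(self, message: str, line: int = 0, column: int = 0):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


class DuplicateField(BBIError):
    """Two schema fields share a name."""


class FieldCountMismatch(BBIError):
    """Entry rest-string column count disagrees with the schema."""


class FieldParseError(BBIError):
    """A rest-string column failed conversion to its declared type."""

    def __init__(self, field_name: str, message: str):
        super().__init__(f"field {field_name!r}: {message}")
        self.field_name = field_name


class BadBedType(BBIError):
    """bedN[+M] specifier outside 3 <= N <= 12 or malformed."""
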