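"""autoSql schema parsing and BED rest-string typing.

autoSql is the small declaration language UCSC uses to describe the
columns of a BED-like record; BigBed files embed one ``table``
declaration as plain text. This module parses that dialect (``table``
declarations only — ``object``/``simple`` never appear inside BigBed
files), renders tables back to text, and converts the tab-separated
"rest" columns of an entry to typed Python values.

Supported field types: the integer family (byte/ubyte/short/ushort/
int/uint, plus ``bigint``), float/double, ``char[N]``, string/lstring,
fixed and field-sized arrays (``int[4]``, ``uint[blockCount]``), and
``enum(...)``/``set(...)``. ``index``/``primary``/``auto`` annotations
after a field are tolerated and ignored.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .exceptions import (
    AutoSqlSyntaxError,
    BadBedType,
    DuplicateField,
    FieldCountMismatch,
    FieldParseError,
)

_INT_TYPES = {"byte", "ubyte", "short", "ushort", "int", "uint", "bigint"}
_UNSIGNED = {"ubyte", "ushort", "uint"}
_FLOAT_TYPES = {"float", "double"}
_SIMPLE_TYPES = _INT_TYPES | _FLOAT_TYPES | {"string", "lstring", "char"}


@dataclass(slots=True)
class AutoSqlField:
    name: str
    type: str                      # base type keyword
    comment: str = ""
    array_size: int | str | None = None   # int, field-name reference, or None
    values: tuple[str, ...] = ()   # enum/set members

    def is_array(self) -> bool:
        return self.array_size is not None and self.type != "char"


@dataclass(slots=True)
class AutoSqlTable:
    name: str
    comment: str = ""
    fields: list[AutoSqlField] = field(default_factory=list)

    def field_names(self) -> list[str]:
        return [f.name for f in self.fields]


# ---------------------------------------------------------------------------
# tokenizer

_TOKEN_RE = re.compile(
    r'\s+|(?P<comment>#[^\n]*)|(?P<string>"(?:[^"\\]|\\.)*")'
    r'|(?P<word>[A-Za-z_][A-Za-z0-9_]*)|(?P<num>\d+)'
    r'|(?P<sym>[()\[\];,])')


def _tokenize(text: str):
    pos = 0
    line, col = 1, 1
    tokens = []
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m or m.end() == pos:
            raise AutoSqlSyntaxError(
                f"unexpected character {text[pos]!r}", line, col)
        chunk = text[pos:m.end()]
        if m.lastgroup and m.lastgroup != "comment":
            tokens.append((m.lastgroup, m.group(m.lastgroup), line, col))
        nl = chunk.count("\n")
        if nl:
            line += nl
            col = len(chunk) - chunk.rfind("\n")
        else:
            col += len(chunk)
        pos = m.end()
    tokens.append(("eof", "", line, col))
    return tokens


class _Parser:
    def __init__(self, text: str):
        self.toks = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.toks[self.i]

    def next(self):
        t = self.toks[self.i]
        if t[0] != "eof":
            self.i += 1
        return t

    def expect(self, kind: str, value: str | None = None):
        t = self.next()
        if t[0] != kind or (value is not None and t[1] != value):
            want = value or kind
            raise AutoSqlSyntaxError(
                f"expected {want!r}, got {t[1]!r}", t[2], t[3])
        return t

    def quoted(self) -> str:
        t = self.expect("string")
        body = t[1][1:-1]
        return body.replace('\\"', '"').replace("\\\\", "\\")


def parse_autosql(text: str) -> AutoSqlTable:
    """Parse one ``table`` declaration.

    Raises :class:`AutoSqlSyntaxError` with line/column on malformed
    input and :class:`DuplicateField` on repeated field names.
    """
    if not text or not text.strip():
        raise AutoSqlSyntaxError("empty schema text", 1, 1)
    p = _Parser(text)
    p.expect("word", "table")
    name = p.expect("word")[1]
    comment = p.quoted()
    p.expect("sym", "(")
    fields: list[AutoSqlField] = []
    seen: set[str] = set()
    while True:
        t = p.peek()
        if t[0] == "sym" and t[1] == ")":
            p.next()
            break
        if t[0] == "eof":
            raise AutoSqlSyntaxError("unterminated field list", t[2], t[3])
        fields.append(_parse_field(p, seen))
    tok = p.peek()
    if tok[0] != "eof":
        raise AutoSqlSyntaxError(
            f"trailing content {tok[1]!r} after table", tok[2], tok[3])
    return AutoSqlTable(name, comment, fields)


def _parse_field(p: _Parser, seen: set[str]) -> AutoSqlField:
    t = p.expect("word")
    type_kw = t[1]
    values: tuple[str, ...] = ()
    array_size: int | str | None = None
    if type_kw in ("enum", "set"):
        p.expect("sym", "(")
        vals = []
        while True:
            vals.append(p.expect("word")[1])
            nxt = p.next()
            if nxt[1] == ")":
                break
            if nxt[1] != ",":
                raise AutoSqlSyntaxError(
                    f"expected ',' or ')' in {type_kw} values",
                    nxt[2], nxt[3])
        values = tuple(vals)
    elif type_kw not in _SIMPLE_TYPES:
        raise AutoSqlSyntaxError(
            f"unknown type keyword {type_kw!r}", t[2], t[3])
    if p.peek()[1] == "[":
        p.next()
        st = p.next()
        if st[0] == "num":
            array_size = int(st[1])
            if array_size <= 0:
                raise AutoSqlSyntaxError(
                    "array size must be positive", st[2], st[3])
        elif st[0] == "word":
            array_size = st[1]
        else:
            raise AutoSqlSyntaxError(
                f"bad array size {st[1]!r}", st[2], st[3])
        p.expect("sym", "]")
    name_tok = p.expect("word")
    fname = name_tok[1]
    if fname in seen:
        raise DuplicateField(f"field {fname!r} declared twice")
    seen.add(fname)
    # tolerated annotations: `index`, `index[N]`, `primary`, `auto`
    while p.peek()[0] == "word" and p.peek()[1] in ("index", "primary", "auto"):
        ann = p.next()[1]
        if ann == "index" and p.peek()[1] == "[":
            p.next()
            p.expect("num")
            p.expect("sym", "]")
    p.expect("sym", ";")
    comment = p.quoted() if p.peek()[0] == "string" else ""
    return AutoSqlField(fname, type_kw, comment, array_size, values)


def render_autosql(table: AutoSqlTable) -> str:
    """Render a table back to autoSql text (inverse of parse_autosql)."""
    def esc(s: str) -> str:
        return s.replace("\\", "\\\\").replace('"', '\\"')

    lines = [f'table {table.name}', f'"{esc(table.comment)}"', "("]
    for f in table.fields:
        t = f.type
        if f.values:
            t = f"{f.type}({', '.join(f.values)})"
        if f.array_size is not None:
            t = f"{t}[{f.array_size}]"
        lines.append(f'    {t} {f.name};  "{esc(f.comment)}"')
    lines.append(")")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# typing entries

_INT_BOUNDS = {
    "byte": (-(1 << 7), (1 << 7) - 1),
    "ubyte": (0, (1 << 8) - 1),
    "short": (-(1 << 15), (1 << 15) - 1),
    "ushort": (0, (1 << 16) - 1),
    "int": (-(1 << 31), (1 << 31) - 1),
    "uint": (0, (1 << 32) - 1),
    "bigint": (-(1 << 63), (1 << 63) - 1),
}


def _convert_scalar(f: AutoSqlField, text: str):
    if f.type in _INT_TYPES:
        try:
            v = int(text)
        except ValueError:
            raise FieldParseError(f.name, f"{text!r} is not an integer")
        lo, hi = _INT_BOUNDS[f.type]
        if not lo <= v <= hi:
            raise FieldParseError(
                f.name, f"{v} out of range for {f.type}")
        return v
    if f.type in _FLOAT_TYPES:
        try:
            return float(text)
        except ValueError:
            raise FieldParseError(f.name, f"{text!r} is not a number")
    if f.type == "char":
        n = f.array_size if isinstance(f.array_size, int) else 1
        if len(text) > n:
            raise FieldParseError(
                f.name, f"{text!r} longer than char[{n}]")
        return text
    if f.type in ("string", "lstring"):
        return text
    if f.type == "enum":
        if text not in f.values:
            raise FieldParseError(
                f.name, f"{text!r} not one of {f.values}")
        return text
    if f.type == "set":
        members = tuple(x for x in text.split(",") if x)
        for m in members:
            if m not in f.values:
                raise FieldParseError(
                    f.name, f"{m!r} not one of {f.values}")
        return members
    raise FieldParseError(f.name, f"unsupported type {f.type!r}")


def type_entry(table: AutoSqlTable, rest: str) -> tuple:
    """Convert a rest-string's columns per the schema.

    The schema's first three fields are the chrom/start/end roles and are
    not part of the rest-string. Comma-separated arrays tolerate a
    trailing comma (the BED12 blockSizes convention); arrays sized by
    another field are validated against that field's parsed value.
    """
    fields = table.fields[3:]
    cols = rest.split("\t") if rest else []
    if len(cols) != len(fields):
        raise FieldCountMismatch(
            f"entry has {len(cols)} extra columns, schema declares "
            f"{len(fields)}")
    out: list = []
    by_name: dict[str, object] = {}
    for f, text in zip(fields, cols):
        if f.is_array():
            parts = [x for x in text.split(",") if x != ""]
            elem = AutoSqlField(f.name, f.type, values=f.values)
            vals = tuple(_convert_scalar(elem, x) for x in parts)
            expect = f.array_size
            if isinstance(expect, int) and len(vals) != expect:
                raise FieldParseError(
                    f.name, f"expected {expect} elements, got {len(vals)}")
            if isinstance(expect, str):
                ref = by_name.get(expect)
                if isinstance(ref, int) and len(vals) != ref:
                    raise FieldParseError(
                        f.name,
                        f"expected {ref} elements per {expect!r}, "
                        f"got {len(vals)}")
            value: object = vals
        else:
            value = _convert_scalar(f, text)
        out.append(value)
        by_name[f.name] = value
    return tuple(out)


def render_typed(table: AutoSqlTable, values: tuple) -> str:
    """Inverse of type_entry: typed values back to a rest-string."""
    fields = table.fields[3:]
    cols = []
    for f, v in zip(fields, values):
        if f.is_array():
            cols.append(",".join(str(x) for x in v) + ("," if v else ""))
        elif f.type == "set":
            cols.append(",".join(v))
        else:
            cols.append(str(v))
    return "\t".join(cols)


# ---------------------------------------------------------------------------
# canonical BED schema

_BED_FIELDS = [
    ("string", "chrom", "Reference sequence chromosome or scaffold"),
    ("uint", "chromStart", "Start position in chromosome"),
    ("uint", "chromEnd", "End position in chromosome"),
    ("string", "name", "Name of item"),
    ("uint", "score", "Score from 0-1000"),
    ("char[1]", "strand", "+ or - for strand"),
    ("uint", "thickStart", "Start of where display should be thick"),
    ("uint", "thickEnd", "End of where display should be thick"),
    ("uint", "itemRgb", "Color value R,G,B as a packed integer"),
    ("uint", "blockCount", "Number of blocks"),
    ("int[blockCount]", "blockSizes", "Comma separated list of block sizes"),
    ("int[blockCount]", "blockStarts",
     "Start positions relative to chromStart"),
]


def parse_bed_type(spec: str) -> tuple[int, int | None]:
    """Parse a ``bedN``/``bedN+``/``bedN+M`` specifier to (N, M)."""
    m = re.fullmatch(r"bed(\d+)(\+(\d*))?", spec.strip())
    if not m:
        raise BadBedType(f"bad BED type {spec!r} (want bedN[+[M]])")
    n = int(m.group(1))
    if not 3 <= n <= 12:
        raise BadBedType(f"bed{n}: N must be between 3 and 12")
    if m.group(2) is None:
        return n, 0
    return n, int(m.group(3)) if m.group(3) else None


def default_autosql(bed_n: int, extra_m: int = 0) -> AutoSqlTable:
    """Canonical schema for bedN+M: the first N standard BED fields plus
    M opaque string columns named field{N+1}.."""
    if not 3 <= bed_n <= 12:
        raise BadBedType(f"bed{bed_n}: N must be between 3 and 12")
    if extra_m < 0:
        raise BadBedType("extra field count must be >= 0")
    fields = []
    for t, name, comment in _BED_FIELDS[:bed_n]:
        size: int | str | None = None
        base = t
        m = re.fullmatch(r"(\w+)\[(\w+)\]", t)
        if m:
            base = m.group(1)
            size = int(m.group(2)) if m.group(2).isdigit() else m.group(2)
        fields.append(AutoSqlField(name, base, comment, size))
    for i in range(extra_m):
        fields.append(AutoSqlField(f"field{bed_n + i + 1}", "string",
                                   "Additional column"))
    return AutoSqlTable(f"bed{bed_n}", "Browser Extensible Data", fields)
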