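"""Bit-exact encoders/decoders for the BBI container structures.

Covers the fixed header, zoom headers, total summary, data-block
compression, BigWig data sections (bedgraph / variable-step / fixed-step
encodings), BigBed data blocks and zoom records. The chromosome B+-tree
and the R-tree index live in :mod:`bbikit.btree` and :mod:`bbikit.rtree`.

All coordinates are 0-based, half-open, both in memory and on disk. Files
are written little-endian; both byte orders are read, dispatched on the
magic number.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import NamedTuple


from .exceptions import (
    BadSectionKind,
    BufferOverrun,
    ItemOutOfBounds,
    OverlapError,
    TruncatedFile,
    UnknownMagic,
    UnsupportedVersion,
    UnsortedError,
    UnterminatedString,
)
from .source import ByteSource, read_exact
from .summary import Summary

BIGWIG_MAGIC = 0x888FFC26
BIGBED_MAGIC = 0x8789F2EB
CHROM_TREE_MAGIC = 0x78CA8C91
RTREE_MAGIC = 0x2468ACE0

BBI_HEADER_SIZE = 64
ZOOM_HEADER_SIZE = 24
TOTAL_SUMMARY_SIZE = 40
ZOOM_RECORD_SIZE = 32

#: wig section encodings (type byte on disk)
BEDGRAPH = 1
VARSTEP = 2
FIXEDSTEP = 3


class Interval(NamedTuple):
    """One BigWig datum on a single chromosome."""

    start: int
    end: int
    value: float


class BedEntry(NamedTuple):
    """One BigBed datum; ``rest`` is the tab-joined optional columns."""

    start: int
    end: int
    rest: str


class ChromInfo(NamedTuple):
    name: str
    id: int
    length: int


@dataclass(slots=True)
class BBIHeader:
    magic: int
    version: int = 4
    zoom_level_count: int = 0
    chrom_tree_offset: int = 0
    full_data_offset: int = 0
    full_index_offset: int = 0
    field_count: int = 0
    defined_field_count: int = 0
    auto_sql_offset: int = 0
    total_summary_offset: int = 0
    uncompress_buf_size: int = 0
    byte_order: str = "little"  # "little" | "big"

    @property
    def is_bigwig(self) -> bool:
        return self.magic == BIGWIG_MAGIC

    @property
    def is_bigbed(self) -> bool:
        return self.magic == BIGBED_MAGIC

    @property
    def endian(self) -> str:
        return "<" if self.byte_order == "little" else ">"

    @property
    def compressed(self) -> bool:
        return self.uncompress_buf_size > 0


@dataclass(slots=True)
class ZoomHeader:
    reduction_level: int
    data_offset: int
    index_offset: int


@dataclass(slots=True)
class ZoomRecord:
    chrom_id: int
    start: int
    end: int
    summary: Summary


@dataclass(slots=True)
class SectionHeader:
    chrom_id: int
    start: int
    end: int
    item_step: int
    item_span: int
    kind: int
    item_count: int


# ---------------------------------------------------------------------------
# fixed header

_HEADER_FMT = "IHHQQQHHQQIQ"


def read_header(source: ByteSource) -> BBIHeader:
    """Read and validate the 64-byte fixed header.

    The byte order is inferred from which orientation of the magic
    matches; versions older than 3 are rejected because their zoom and
    summary layout differs.
    """
    raw = source.read_at(0, BBI_HEADER_SIZE)
    if len(raw) < BBI_HEADER_SIZE:
        raise TruncatedFile(
            f"file has {len(raw)} bytes, fixed header needs {BBI_HEADER_SIZE}")
    for endian, order in (("<", "little"), (">", "big")):
        (magic,) = struct.unpack_from(endian + "I", raw, 0)
        if magic in (BIGWIG_MAGIC, BIGBED_MAGIC):
            break
    else:
        raise UnknownMagic(f"not a BigWig/BigBed file (magic {raw[:4]!r})")
    (magic, version, zoom_count, chrom_tree_off, full_data_off,
     full_index_off, field_count, defined_field_count, auto_sql_off,
     total_summary_off, uncompress_buf, _reserved) = struct.unpack_from(
        endian + _HEADER_FMT, raw, 0)
    if version < 3:
        raise UnsupportedVersion(
            f"BBI version {version} not supported (need 3 or 4)")
    return BBIHeader(
        magic=magic,
        version=version,
        zoom_level_count=zoom_count,
        chrom_tree_offset=chrom_tree_off,
        full_data_offset=full_data_off,
        full_index_offset=full_index_off,
        field_count=field_count,
        defined_field_count=defined_field_count,
        auto_sql_offset=auto_sql_off,
        total_summary_offset=total_summary_off,
        uncompress_buf_size=uncompress_buf,
        byte_order=order,
    )


def pack_header(h: BBIHeader) -> bytes:
    return struct.pack(
        h.endian + _HEADER_FMT,
        h.magic, h.version, h.zoom_level_count, h.chrom_tree_offset,
        h.full_data_offset, h.full_index_offset, h.field_count,
        h.defined_field_count, h.auto_sql_offset, h.total_summary_offset,
        h.uncompress_buf_size, 0)


# ---------------------------------------------------------------------------
# zoom headers and total summary

def read_zoom_headers(source: ByteSource, header: BBIHeader) -> list[ZoomHeader]:
    n = header.zoom_level_count
    if n == 0:
        return []
    raw = read_exact(source, BBI_HEADER_SIZE, n * ZOOM_HEADER_SIZE)
    out = []
    for i in range(n):
        level, _res, doff, ioff = struct.unpack_from(
            header.endian + "IIQQ", raw, i * ZOOM_HEADER_SIZE)
        out.append(ZoomHeader(level, doff, ioff))
    return out


def pack_zoom_header(z: ZoomHeader, endian: str = "<") -> bytes:
    return struct.pack(endian + "IIQQ", z.reduction_level, 0,
                       z.data_offset, z.index_offset)


def read_total_summary(source: ByteSource, header: BBIHeader) -> Summary:
    if header.total_summary_offset == 0:
        return Summary()
    raw = read_exact(source, header.total_summary_offset, TOTAL_SUMMARY_SIZE)
    valid, mn, mx, sd, ss = struct.unpack(header.endian + "Qdddd", raw)
    if valid == 0:
        return Summary()
    return Summary(valid, mn, mx, sd, ss)


def pack_total_summary(s: Summary, endian: str = "<") -> bytes:
    if s.valid_count == 0:
        return struct.pack(endian + "Qdddd", 0, 0.0, 0.0, 0.0, 0.0)
    return struct.pack(endian + "Qdddd", s.valid_count, s.min_val,
                       s.max_val, s.sum_data, s.sum_squares)


# ---------------------------------------------------------------------------
# block compression (RFC-1950 zlib-wrapped deflate)

def compress_block(raw: bytes, level: int = 6) -> bytes:
    return zlib.compress(raw, level)


def decompress_block(data: bytes, uncompress_buf_size: int) -> bytes:
    """Inflate one block; ``uncompress_buf_size == 0`` means stored raw."""
    if uncompress_buf_size == 0:
        return bytes(data)
    d = zlib.decompressobj()
    try:
        out = d.decompress(data, uncompress_buf_size)
    except zlib.error as e:
        raise BufferOverrun(f"bad deflate stream: {e}") from e
    if d.unconsumed_tail:
        raise BufferOverrun(
            f"decompressed block exceeds declared uncompressBufSize "
            f"{uncompress_buf_size}")
    return out


# ---------------------------------------------------------------------------
# BigWig data sections

_SECTION_HEADER_FMT = "IIIIIBBH"
SECTION_HEADER_SIZE = 24


def decode_wig_section(block: bytes, endian: str = "<") -> tuple[int, list[Interval]]:
    """Expand one decompressed data section to explicit intervals.

    Returns ``(chrom_id, intervals)``; all three encodings come back as
    sorted, non-overlapping (start, end, value) triples within the
    section's declared range.
    """
    if len(block) < SECTION_HEADER_SIZE:
        raise TruncatedFile("data section shorter than its header")
    (chrom_id, start, end, step, span, kind, _res, count) = struct.unpack_from(
        endian + _SECTION_HEADER_FMT, block, 0)
    out: list[Interval] = []
    off = SECTION_HEADER_SIZE
    if kind == BEDGRAPH:
        for _ in range(count):
            s, e, v = struct.unpack_from(endian + "IIf", block, off)
            off += 12
            out.append(Interval(s, e, v))
    elif kind == VARSTEP:
        for _ in range(count):
            s, v = struct.unpack_from(endian + "If", block, off)
            off += 8
            out.append(Interval(s, s + span, v))
    elif kind == FIXEDSTEP:
        for i in range(count):
            (v,) = struct.unpack_from(endian + "f", block, off)
            off += 4
            s = start + i * step
            out.append(Interval(s, s + span, v))
    else:
        raise BadSectionKind(f"unknown section type {kind}")
    for iv in out:
        if iv.start < start or iv.end > end:
            raise ItemOutOfBounds(
                f"item {iv} outside section range [{start},{end})")
    return chrom_id, out


def _detect_kind(intervals: list[Interval]) -> int:
    spans = {iv.end - iv.start for iv in intervals}
    if len(spans) == 1:
        span = next(iter(spans))
        if len(intervals) == 1:
            return FIXEDSTEP
        steps = {b.start - a.start for a, b in zip(intervals, intervals[1:])}
        if len(steps) == 1 and next(iter(steps)) >= span:
            return FIXEDSTEP
        return VARSTEP
    return BEDGRAPH


def encode_wig_section(chrom_id: int, intervals: list[Interval],
                       kind: str | int = "auto") -> bytes:
    """Encode one section (single chromosome, sorted, non-overlapping).

    ``kind='auto'`` picks the most compact lossless encoding: fixed-step
    when every item shares one span and starts form an arithmetic
    progression, else variable-step when spans are uniform, else bedgraph.
    """
    if not intervals:
        raise ValueError("cannot encode an empty section")
    for a, b in zip(intervals, intervals[1:]):
        if b.start < a.start:
            raise UnsortedError(f"items out of order at {a} -> {b}")
        if b.start < a.end:
            raise OverlapError(f"overlapping items {a} and {b}")
    if kind == "auto":
        k = _detect_kind(intervals)
    elif kind in ("bedgraph", BEDGRAPH):
        k = BEDGRAPH
    elif kind in ("varstep", VARSTEP):
        k = VARSTEP
    elif kind in ("fixedstep", FIXEDSTEP):
        k = FIXEDSTEP
    else:
        raise BadSectionKind(f"unknown section kind {kind!r}")

    start = intervals[0].start
    end = intervals[-1].end
    span = intervals[0].end - intervals[0].start
    if k == FIXEDSTEP:
        step = (intervals[1].start - intervals[0].start
                if len(intervals) > 1 else span)
        body = b"".join(struct.pack("<f", iv.value) for iv in intervals)
    elif k == VARSTEP:
        step = 0
        body = b"".join(struct.pack("<If", iv.start, iv.value)
                        for iv in intervals)
    else:
        step = span = 0
        body = b"".join(struct.pack("<IIf", iv.start, iv.end, iv.value)
                        for iv in intervals)
    head = struct.pack("<" + _SECTION_HEADER_FMT, chrom_id, start, end,
                       step, span, k, 0, len(intervals))
    return head + body


def encode_wig_sections(chrom_id: int, intervals: list[Interval],
                        items_per_slot: int,
                        kind: str | int = "auto") -> list[bytes]:
    """Chunk intervals into sections of at most ``items_per_slot`` items."""
    return [
        encode_wig_section(chrom_id, intervals[i:i + items_per_slot], kind)
        for i in range(0, len(intervals), items_per_slot)
    ]


# ---------------------------------------------------------------------------
# BigBed data blocks

def encode_bed_block(chrom_id: int, entries: list[BedEntry]) -> bytes:
    parts = []
    for e in entries:
        parts.append(struct.pack("<III", chrom_id, e.start, e.end))
        parts.append(e.rest.encode())
        parts.append(b"\0")
    return b"".join(parts)


def decode_bed_block(block: bytes, query: tuple[int, int, int] | None = None,
                     endian: str = "<") -> list[tuple[int, BedEntry]]:
    """Decode a BigBed block, optionally filtering to a query range.

    ``query`` is (chrom_id, start, end) half-open; ``None`` returns every
    entry. On-disk order is preserved; returns (chrom_id, entry) pairs.
    """
    out: list[tuple[int, BedEntry]] = []
    off = 0
    n = len(block)
    while off < n:
        if off + 12 > n:
            raise TruncatedFile("bed entry header past end of block")
        cid, s, e = struct.unpack_from(endian + "III", block, off)
        off += 12
        nul = block.find(b"\0", off)
        if nul < 0:
            raise UnterminatedString(
                f"rest-string at offset {off} has no terminator")
        rest = block[off:nul].decode()
        off = nul + 1
        if query is not None:
            qc, qs, qe = query
            if cid != qc or s >= qe or e <= qs:
                continue
        out.append((cid, BedEntry(s, e, rest)))
    return out


# ---------------------------------------------------------------------------
# zoom records (disk layout: uint32 counts, float32 summary fields)

def pack_zoom_record(r: ZoomRecord, endian: str = "<") -> bytes:
    s = r.summary
    return struct.pack(endian + "IIIIffff", r.chrom_id, r.start, r.end,
                       s.valid_count, s.min_val, s.max_val, s.sum_data,
                       s.sum_squares)


def unpack_zoom_records(block: bytes, endian: str = "<") -> list[ZoomRecord]:
    out = []
    for off in range(0, len(block), ZOOM_RECORD_SIZE):
        cid, s, e, valid, mn, mx, sd, ss = struct.unpack_from(
            endian + "IIIIffff", block, off)
        out.append(ZoomRecord(cid, s, e, Summary(valid, mn, mx, sd, ss)))
    return out
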