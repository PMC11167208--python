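"""Create BigWig/BigBed files from sorted streams.

The writer consumes the input exactly once. Completed data sections are
compressed and appended to a spool (a temporary file by default, an
in-memory buffer when ``use_temp_files=False``), R-tree leaf bookkeeping
is kept as fixed-width records in its own spool, and one summary
accumulator per zoom level runs alongside the stream. Because every part
is staged before assembly, the finished file is emitted front-to-back in
one sequential write — no seeking, so pipes work as sinks.

Peak buffered input is bounded by ``items_per_slot`` items per active
structure (the open section plus one window per zoom level).
"""

from __future__ import annotations

import heapq
import io
import itertools
import math
import struct
import tempfile
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from . import autosql as _autosql
from .btree import write_chrom_tree
from .codec import (
    BBI_HEADER_SIZE,
    BIGBED_MAGIC,
    BIGWIG_MAGIC,
    TOTAL_SUMMARY_SIZE,
    ZOOM_HEADER_SIZE,
    BBIHeader,
    BedEntry,
    ChromInfo,
    Interval,
    ZoomHeader,
    ZoomRecord,
    compress_block,
    encode_bed_block,
    encode_wig_section,
    pack_header,
    pack_total_summary,
    pack_zoom_header,
    pack_zoom_record,
)
from .exceptions import (
    ChromLengthExceeded,
    FieldCountMismatch,
    OverlapError,
    RaggedFields,
    UnknownChrom,
    UnsortedError,
    ValueNotFinite,
)
from .rtree import LeafItem, build_rtree
from .summary import Summary, merge_summary

DEFAULT_ITEMS_PER_SLOT_WIG = 1024
DEFAULT_ITEMS_PER_SLOT_BED = 512
_SPAN_SAMPLE = 10_000  # items used to estimate mean span in single-pass mode


@dataclass(slots=True)
class WriteOptions:
    """Knobs for file creation.

    ``block_size`` is the R-tree/B+-tree fanout; ``items_per_slot`` the
    number of items per compressed block (1024 for wig, 512 for bed when
    left as ``None``). The zoom schedule starts at
    ``initial_zoom_factor``x the mean item span and multiplies by
    ``zoom_multiplier`` up to ``max_zoom_levels`` levels.
    """

    block_size: int = 256
    items_per_slot: int | None = None
    compress: bool = True
    compress_level: int = 6
    initial_zoom_factor: int = 10
    zoom_multiplier: int = 4
    max_zoom_levels: int = 10
    single_pass: bool = False
    use_temp_files: bool = True
    threads: int = 1

    def __post_init__(self):
        if self.block_size < 2:
            raise ValueError("block_size must be >= 2")
        if self.items_per_slot is not None and self.items_per_slot < 1:
            raise ValueError("items_per_slot must be >= 1")
        if self.zoom_multiplier < 2:
            raise ValueError("zoom_multiplier must be >= 2")
        if self.max_zoom_levels < 0:
            raise ValueError("max_zoom_levels must be >= 0")


@dataclass(slots=True)
class FileReport:
    """What got written: returned by write_bigwig/write_bigbed."""

    total_summary: Summary
    section_count: int
    data_count: int
    zoom_levels: list[int]
    chrom_count: int


def plan_zoom_levels(mean_span: float, longest_chrom: int,
                     opts: WriteOptions | None = None) -> list[int]:
    """Geometric zoom schedule.

    The first level is ``max(2, ceil(initial_zoom_factor * mean_span))``;
    each next multiplies by ``zoom_multiplier``; planning stops after
    ``max_zoom_levels`` or once a level exceeds half the longest
    chromosome.
    """
    opts = opts or WriteOptions()
    if mean_span <= 0:
        return []
    levels: list[int] = []
    level = max(2, math.ceil(opts.initial_zoom_factor * mean_span))
    while len(levels) < opts.max_zoom_levels and level <= longest_chrom / 2:
        levels.append(level)
        level *= opts.zoom_multiplier
    return levels


class ZoomAccumulator:
    """Streaming fixed-window reduction at one level.

    Windows of ``level`` bases are anchored at base 0 of each chromosome;
    a run of equal-valued bases is split across windows per-base exactly.
    Finished records go to ``emit``.
    """

    def __init__(self, level: int, emit, chrom_lengths: list[int] | None = None):
        self.level = level
        self.emit = emit
        self.chrom_lengths = chrom_lengths
        self._chrom = -1
        self._win = -1
        self._summary = Summary()

    def _flush_window(self) -> None:
        if self._summary.valid_count:
            start = self._win * self.level
            end = start + self.level
            if self.chrom_lengths is not None:
                end = min(end, self.chrom_lengths[self._chrom])
            self.emit(ZoomRecord(self._chrom, start, end, self._summary))
        self._summary = Summary()

    def add(self, chrom_id: int, start: int, end: int, value: float) -> None:
        if chrom_id != self._chrom:
            self._flush_window()
            self._chrom = chrom_id
            self._win = start // self.level
        pos = start
        while pos < end:
            win = pos // self.level
            if win != self._win:
                self._flush_window()
                self._win = win
            win_end = (win + 1) * self.level
            seg = min(end, win_end) - pos
            self._summary.add_run(seg, value)
            pos += seg

    def finish(self) -> None:
        self._flush_window()
        self._chrom = -1
        self._win = -1


def reduce_stream(runs: Iterable[tuple[int, int, int, float]],
                  level: int,
                  chrom_lengths: list[int] | None = None) -> Iterator[ZoomRecord]:
    """Reduce sorted (chrom_id, start, end, value) runs to zoom records.

    Input must be sorted by (chrom_id, start) and non-overlapping (BigBed
    entries are first converted to per-base coverage runs). Windows with
    no data are omitted; summaries are float64-exact.
    """
    out: list[ZoomRecord] = []
    acc = ZoomAccumulator(level, out.append, chrom_lengths)
    last = (-1, -1)
    for chrom_id, start, end, value in runs:
        if (chrom_id, start) < last:
            raise UnsortedError(
                f"run ({chrom_id},{start}) before {last}")
        last = (chrom_id, start)
        acc.add(chrom_id, start, end, value)
        while out:
            yield out.pop(0)
    acc.finish()
    yield from out


# ---------------------------------------------------------------------------
# staging

class _Spool:
    """Append-only byte store: temp file or in-memory buffer."""

    def __init__(self, use_temp: bool):
        self._f = tempfile.TemporaryFile() if use_temp else io.BytesIO()
        self.size = 0

    def append(self, data: bytes) -> int:
        off = self.size
        self._f.write(data)
        self.size += len(data)
        return off

    def copy_to(self, sink, chunk: int = 1 << 20) -> None:
        self._f.seek(0)
        while True:
            buf = self._f.read(chunk)
            if not buf:
                break
            sink.write(buf)

    def close(self) -> None:
        self._f.close()


_LEAF_FMT = "<IIIIQQ"  # startChrom, startBase, endChrom, endBase, relOffset, size


class _LeafSpool:
    """Fixed-width R-tree leaf bookkeeping, spillable to a temp file."""

    def __init__(self, use_temp: bool):
        self._spool = _Spool(use_temp)
        self.count = 0

    def add(self, sc: int, sb: int, ec: int, eb: int,
            rel_offset: int, size: int) -> None:
        self._spool.append(struct.pack(_LEAF_FMT, sc, sb, ec, eb,
                                       rel_offset, size))
        self.count += 1

    def items(self, base_offset: int) -> list[LeafItem]:
        self._spool._f.seek(0)
        raw = self._spool._f.read()
        out = []
        for off in range(0, len(raw), 32):
            sc, sb, ec, eb, rel, size = struct.unpack_from(_LEAF_FMT, raw, off)
            out.append(LeafItem(sc, sb, ec, eb, base_offset + rel, size))
        return out

    def close(self) -> None:
        self._spool.close()


class _BlockStage:
    """Compresses finished blocks and records their leaf bounds.

    With ``threads > 1`` raw blocks are queued and deflated in order by a
    thread pool (zlib releases the GIL), so output bytes are identical to
    the serial path.
    """

    def __init__(self, opts: WriteOptions, executor: ThreadPoolExecutor | None):
        self.opts = opts
        self.spool = _Spool(opts.use_temp_files)
        self.leaves = _LeafSpool(opts.use_temp_files)
        self.max_raw = 0
        self.block_count = 0
        self._executor = executor
        self._pending: list[tuple[bytes, tuple[int, int, int, int]]] = []
        self._batch = max(8, 4 * opts.threads)

    def put(self, raw: bytes, bounds: tuple[int, int, int, int]) -> None:
        self.max_raw = max(self.max_raw, len(raw))
        self.block_count += 1
        self._pending.append((raw, bounds))
        if len(self._pending) >= self._batch:
            self.drain()

    def drain(self) -> None:
        if not self._pending:
            return
        raws = [p[0] for p in self._pending]
        if self.opts.compress:
            if self._executor is not None:
                level = self.opts.compress_level
                blobs = list(self._executor.map(
                    lambda r: compress_block(r, level), raws))
            else:
                blobs = [compress_block(r, self.opts.compress_level)
                         for r in raws]
        else:
            blobs = raws
        for blob, (_, bounds) in zip(blobs, self._pending):
            off = self.spool.append(blob)
            sc, sb, ec, eb = bounds
            self.leaves.add(sc, sb, ec, eb, off, len(blob))
        self._pending.clear()

    def close(self) -> None:
        self.spool.close()
        self.leaves.close()


class _ZoomStage:
    """One zoom level: window reduction plus block staging."""

    def __init__(self, level: int, opts: WriteOptions,
                 chrom_lengths: list[int]):
        self.level = level
        self.opts = opts
        ips = opts.items_per_slot or DEFAULT_ITEMS_PER_SLOT_WIG
        self.records_per_block = max(1, ips)
        self.stage = _BlockStage(opts, None)
        self.record_count = 0
        self._buf: list[ZoomRecord] = []
        self.acc = ZoomAccumulator(level, self._emit, chrom_lengths)

    def _emit(self, rec: ZoomRecord) -> None:
        self.record_count += 1
        self._buf.append(rec)
        if len(self._buf) >= self.records_per_block:
            self._flush_block()

    def _flush_block(self) -> None:
        if not self._buf:
            return
        raw = b"".join(pack_zoom_record(r) for r in self._buf)
        first = self._buf[0]
        ec, eb = max((r.chrom_id, r.end) for r in self._buf)
        self.stage.put(raw, (first.chrom_id, first.start, ec, eb))
        self._buf.clear()

    def finish(self) -> None:
        self.acc.finish()
        self._flush_block()
        self.stage.drain()


# ---------------------------------------------------------------------------
# chromosome bookkeeping shared by both writers

class _ChromDir:
    def __init__(self, chrom_sizes):
        pairs = list(chrom_sizes.items()) if isinstance(chrom_sizes, dict) \
            else list(chrom_sizes)
        if not pairs:
            raise ValueError("chrom_sizes is empty")
        self.tree_bytes, self.infos = write_chrom_tree(pairs)
        self.by_name = {c.name: c for c in self.infos}
        self.lengths = [c.length for c in self.infos]
        self.longest = max(self.lengths)

    def resolve(self, name: str) -> ChromInfo:
        try:
            return self.by_name[name]
        except KeyError:
            raise UnknownChrom(f"chromosome {name!r} not in chrom.sizes") from None


def _validated_wig(stream, chroms: _ChromDir):
    """Yield (chrom_id, start, end, float32 value); enforce stream contract."""
    last = (-1, -1)
    last_end = 0
    for chrom, start, end, value in stream:
        info = chroms.resolve(chrom)
        with np.errstate(over="ignore"):
            v32 = float(np.float32(value))
        if not math.isfinite(v32):
            raise ValueNotFinite(
                f"value {value!r} at {chrom}:{start}-{end} is not finite "
                f"at 32-bit precision")
        if start < 0 or start >= end:
            raise ValueError(f"bad interval {chrom}:{start}-{end}")
        if end > info.length:
            raise ChromLengthExceeded(
                f"{chrom}:{start}-{end} exceeds length {info.length}")
        key = (info.id, start)
        if key < last:
            raise UnsortedError(
                f"interval {chrom}:{start}-{end} out of order "
                f"(sort by lexicographic chromosome name, then start)")
        if info.id == last[0] and start < last_end:
            raise OverlapError(
                f"interval {chrom}:{start}-{end} overlaps previous "
                f"end {last_end}")
        last = key
        last_end = end
        yield info.id, start, end, v32


def _validated_bed(stream, chroms: _ChromDir):
    """Yield (chrom_id, start, end, rest); enforce sortedness and rectangular fields."""
    last = (-1, -1)
    n_fields = None
    for item in stream:
        chrom, start, end = item[0], item[1], item[2]
        rest = item[3] if len(item) > 3 else ""
        info = chroms.resolve(chrom)
        if start < 0 or start >= end:
            raise ValueError(f"bad entry {chrom}:{start}-{end}")
        if end > info.length:
            raise ChromLengthExceeded(
                f"{chrom}:{start}-{end} exceeds length {info.length}")
        nf = 3 + (len(rest.split("\t")) if rest else 0)
        if n_fields is None:
            n_fields = nf
        elif nf != n_fields:
            raise RaggedFields(
                f"entry {chrom}:{start}-{end} has {nf} fields, "
                f"expected {n_fields}")
        key = (info.id, start)
        if key < last:
            raise UnsortedError(
                f"entry {chrom}:{start}-{end} out of order "
                f"(sort by lexicographic chromosome name, then start)")
        last = key
        yield info.id, start, end, rest


def _take_sample(iterator, single_pass: bool):
    """Materialize the whole stream (buffered) or a prefix (single pass)."""
    if single_pass:
        sample = []
        it = iter(iterator)
        for item in it:
            sample.append(item)
            if len(sample) >= _SPAN_SAMPLE:
                break
        return sample, it, False
    items = list(iterator)
    return items, iter(()), True


def _mean_span(sample) -> float:
    if not sample:
        return 0.0
    return sum(it[2] - it[1] for it in sample) / len(sample)


# ---------------------------------------------------------------------------
# assembly

def _assemble(sink_path_or_file, magic: int, chroms: _ChromDir,
              data_stage: _BlockStage, data_count: int,
              zoom_stages: list[_ZoomStage], total: Summary,
              opts: WriteOptions, field_count: int = 0,
              defined_field_count: int = 0,
              autosql_text: str | None = None) -> None:
    zoom_stages = [z for z in zoom_stages if z.record_count > 0]
    n_zoom = len(zoom_stages)

    header_block = BBI_HEADER_SIZE + n_zoom * ZOOM_HEADER_SIZE
    # autoSql sits between the zoom headers and the total summary: some
    # established readers recover its length as totalSummaryOffset -
    # autoSqlOffset, so the text must immediately precede the summary.
    auto_sql_offset = 0
    autosql_blob = b""
    if autosql_text is not None:
        auto_sql_offset = header_block
        autosql_blob = autosql_text.encode() + b"\0"
    total_summary_offset = header_block + len(autosql_blob)
    chrom_tree_offset = total_summary_offset + TOTAL_SUMMARY_SIZE
    full_data_offset = chrom_tree_offset + len(chroms.tree_bytes)
    data_blocks_start = full_data_offset + 4
    full_index_offset = data_blocks_start + data_stage.spool.size

    data_leaves = data_stage.leaves.items(data_blocks_start)
    index_bytes = build_rtree(
        data_leaves, opts.block_size, full_index_offset,
        end_file_offset=full_index_offset,
        items_per_slot=opts.items_per_slot or DEFAULT_ITEMS_PER_SLOT_WIG)

    pos = full_index_offset + len(index_bytes)
    zoom_headers: list[ZoomHeader] = []
    zoom_parts: list[tuple[_ZoomStage, list[LeafItem], bytes]] = []
    for z in zoom_stages:
        zdata = pos
        blocks_start = zdata + 4
        zindex = blocks_start + z.stage.spool.size
        leaves = z.stage.leaves.items(blocks_start)
        zbytes = build_rtree(leaves, opts.block_size, zindex,
                             end_file_offset=zindex,
                             items_per_slot=z.records_per_block)
        zoom_headers.append(ZoomHeader(z.level, zdata, zindex))
        zoom_parts.append((z, leaves, zbytes))
        pos = zindex + len(zbytes)

    max_raw = max([data_stage.max_raw] + [z.stage.max_raw for z in zoom_stages],
                  default=0)
    header = BBIHeader(
        magic=magic,
        version=4,
        zoom_level_count=n_zoom,
        chrom_tree_offset=chrom_tree_offset,
        full_data_offset=full_data_offset,
        full_index_offset=full_index_offset,
        field_count=field_count,
        defined_field_count=defined_field_count,
        auto_sql_offset=auto_sql_offset,
        total_summary_offset=total_summary_offset,
        uncompress_buf_size=max_raw if opts.compress else 0,
    )

    own = isinstance(sink_path_or_file, (str, bytes)) or hasattr(
        sink_path_or_file, "__fspath__")
    sink = open(sink_path_or_file, "wb") if own else sink_path_or_file
    try:
        sink.write(pack_header(header))
        for zh in zoom_headers:
            sink.write(pack_zoom_header(zh))
        if autosql_blob:
            sink.write(autosql_blob)
        sink.write(pack_total_summary(total))
        sink.write(chroms.tree_bytes)
        sink.write(struct.pack("<I", data_count))
        data_stage.spool.copy_to(sink)
        sink.write(index_bytes)
        for z, _leaves, zbytes in zoom_parts:
            sink.write(struct.pack("<I", z.record_count))
            z.stage.spool.copy_to(sink)
            sink.write(zbytes)
        sink.flush()
    finally:
        if own:
            sink.close()
        data_stage.close()
        for z in zoom_stages:
            z.stage.close()


# ---------------------------------------------------------------------------
# public writers

def write_bigwig(intervals, chrom_sizes, sink,
                 opts: WriteOptions | None = None) -> FileReport:
    """Write a BigWig from sorted, non-overlapping intervals.

    ``intervals`` yields (chrom_name, start, end, value), sorted by
    lexicographic chromosome name then start; ``chrom_sizes`` is
    (name, length) pairs or a dict; ``sink`` a path or binary file
    object (need not be seekable).
    """
    opts = opts or WriteOptions()
    ips = opts.items_per_slot or DEFAULT_ITEMS_PER_SLOT_WIG
    chroms = _ChromDir(chrom_sizes)
    stream = _validated_wig(intervals, chroms)
    sample, tail, exhausted = _take_sample(stream, opts.single_pass)

    plan = plan_zoom_levels(_mean_span(sample), chroms.longest, opts)
    executor = (ThreadPoolExecutor(opts.threads)
                if opts.threads > 1 else None)
    data_stage = _BlockStage(opts, executor)
    zoom_stages = [_ZoomStage(lv, opts, chroms.lengths) for lv in plan]
    total = Summary()

    sec_buf: list[Interval] = []
    sec_chrom = -1
    section_count = 0

    def flush_section() -> None:
        nonlocal section_count
        if not sec_buf:
            return
        raw = encode_wig_section(sec_chrom, list(sec_buf))
        data_stage.put(raw, (sec_chrom, sec_buf[0].start,
                             sec_chrom, sec_buf[-1].end))
        section_count += 1
        sec_buf.clear()

    for chrom_id, start, end, value in itertools.chain(sample, tail):
        if chrom_id != sec_chrom or len(sec_buf) >= ips:
            flush_section()
            sec_chrom = chrom_id
        sec_buf.append(Interval(start, end, value))
        total.add_run(end - start, value)
        for z in zoom_stages:
            z.acc.add(chrom_id, start, end, value)
    flush_section()
    data_stage.drain()
    for z in zoom_stages:
        z.finish()
    if executor is not None:
        executor.shutdown()

    _assemble(sink, BIGWIG_MAGIC, chroms, data_stage, section_count,
              zoom_stages, total, opts)
    kept = [z.level for z in zoom_stages if z.record_count > 0]
    return FileReport(total, section_count, section_count, kept,
                      len(chroms.infos))


def _coverage_runs(entries) -> Iterator[tuple[int, int, int, float]]:
    """Per-base coverage depth of possibly overlapping sorted entries,
    as non-overlapping (chrom_id, start, end, depth) runs."""
    heap: list[int] = []
    cur_chrom = -1
    prev = 0

    def drain(upto: int | None):
        nonlocal prev
        while heap and (upto is None or heap[0] <= upto):
            e0 = heap[0]
            if prev < e0:
                yield cur_chrom, prev, e0, float(len(heap))
                prev = e0
            heapq.heappop(heap)

    for chrom_id, start, end, _rest in entries:
        if chrom_id != cur_chrom:
            yield from drain(None)
            cur_chrom = chrom_id
            prev = 0
        yield from drain(start)
        if heap and prev < start:
            yield cur_chrom, prev, start, float(len(heap))
        prev = max(prev, start) if heap else start
        heapq.heappush(heap, end)
    yield from drain(None)


def write_bigbed(entries, chrom_sizes, sink,
                 opts: WriteOptions | None = None,
                 autosql_text: str | None = None,
                 bed_type: str | None = None) -> FileReport:
    """Write a BigBed from sorted entries (overlaps allowed).

    ``entries`` yields (chrom_name, start, end[, rest]); ``rest`` is the
    tab-joined columns beyond the first three. The summary and zoom
    levels aggregate per-base coverage depth. ``autosql_text`` is
    embedded verbatim when given (its field count must match the data);
    otherwise a canonical schema for the declared ``bed_type``
    (``"bedN"`` or ``"bedN+M"``) or the observed field count is
    generated.
    """
    opts = opts or WriteOptions()
    ips = opts.items_per_slot or DEFAULT_ITEMS_PER_SLOT_BED
    chroms = _ChromDir(chrom_sizes)
    stream = _validated_bed(entries, chroms)
    sample, tail, exhausted = _take_sample(stream, opts.single_pass)

    plan = plan_zoom_levels(_mean_span(sample), chroms.longest, opts)
    executor = (ThreadPoolExecutor(opts.threads)
                if opts.threads > 1 else None)
    data_stage = _BlockStage(opts, executor)
    zoom_stages = [_ZoomStage(lv, opts, chroms.lengths) for lv in plan]
    total = Summary()

    field_count = 0
    entry_count = 0
    section_count = 0
    ent_buf: list[BedEntry] = []
    ent_chrom = -1
    ent_max_end = 0

    def flush_block() -> None:
        nonlocal section_count, ent_max_end
        if not ent_buf:
            return
        raw = encode_bed_block(ent_chrom, list(ent_buf))
        data_stage.put(raw, (ent_chrom, ent_buf[0].start,
                             ent_chrom, ent_max_end))
        section_count += 1
        ent_buf.clear()
        ent_max_end = 0

    def entry_stream():
        nonlocal field_count, entry_count, ent_chrom, ent_max_end
        for chrom_id, start, end, rest in itertools.chain(sample, tail):
            if not field_count:
                field_count = 3 + (len(rest.split("\t")) if rest else 0)
            entry_count += 1
            if chrom_id != ent_chrom or len(ent_buf) >= ips:
                flush_block()
                ent_chrom = chrom_id
            ent_buf.append(BedEntry(start, end, rest))
            ent_max_end = max(ent_max_end, end)
            yield chrom_id, start, end, rest

    for chrom_id, start, end, depth in _coverage_runs(entry_stream()):
        total.add_run(end - start, depth)
        for z in zoom_stages:
            z.acc.add(chrom_id, start, end, depth)
    flush_block()
    data_stage.drain()
    for z in zoom_stages:
        z.finish()
    if executor is not None:
        executor.shutdown()

    field_count = field_count or 3
    defined, schema = _resolve_schema(field_count, bed_type, autosql_text)

    _assemble(sink, BIGBED_MAGIC, chroms, data_stage, entry_count,
              zoom_stages, total, opts, field_count=field_count,
              defined_field_count=defined, autosql_text=schema)
    kept = [z.level for z in zoom_stages if z.record_count > 0]
    return FileReport(total, section_count, entry_count, kept,
                      len(chroms.infos))


def _resolve_schema(field_count: int, bed_type: str | None,
                    autosql_text: str | None) -> tuple[int, str]:
    """Decide definedFieldCount and the embedded schema text."""
    if bed_type is not None:
        n, m = _autosql.parse_bed_type(bed_type)
        if m is None:
            m = field_count - n
        if n + m != field_count:
            raise FieldCountMismatch(
                f"{bed_type} does not match the data's {field_count} fields")
        defined = n
    elif autosql_text is not None:
        defined = min(len(_autosql.parse_autosql(autosql_text).fields), 12)
    else:
        defined = min(field_count, 12)
    if autosql_text is not None:
        table = _autosql.parse_autosql(autosql_text)
        if len(table.fields) != field_count:
            raise FieldCountMismatch(
                f"schema declares {len(table.fields)} fields but the data "
                f"has {field_count}")
        return defined, autosql_text
    table = _autosql.default_autosql(defined, field_count - defined)
    return defined, _autosql.render_autosql(table)
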