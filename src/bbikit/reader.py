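"""Random-access queries over opened BBI files.

Metadata (header, chromosome list, zoom headers, total summary, embedded
autoSql) is loaded eagerly at open; data blocks are only touched when a
query runs, and are decompressed one at a time, so a streaming consumer
never holds more than one block of decoded data.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import rtree
from .autosql import AutoSqlTable, parse_autosql, type_entry
from .btree import read_chrom_tree
from .codec import (
    BBIHeader,
    BedEntry,
    ChromInfo,
    Interval,
    ZoomRecord,
    decode_bed_block,
    decode_wig_section,
    decompress_block,
    read_header,
    read_total_summary,
    read_zoom_headers,
    unpack_zoom_records,
)
from .exceptions import (
    ChromNotFound,
    InvertedRange,
    NoSuchZoomLevel,
    WrongFileType,
)
from .source import ByteSource, as_byte_source
from .summary import Summary

STATISTICS = ("mean", "min", "max", "coverage", "sum", "std")


class BBIFile:
    """An opened BigWig or BigBed; use :func:`open_bbi` to construct."""

    def __init__(self, source: ByteSource):
        self.source = source
        self.header: BBIHeader = read_header(source)
        self.chrom_list: list[ChromInfo] = read_chrom_tree(
            source, self.header.chrom_tree_offset)
        self.zooms = read_zoom_headers(source, self.header)
        self.total_summary: Summary = read_total_summary(source, self.header)
        self.autosql: str | None = None
        if self.header.auto_sql_offset:
            self.autosql = self._read_cstring(self.header.auto_sql_offset)
        self._by_name = {c.name: c for c in self.chrom_list}

    # -- metadata ----------------------------------------------------------

    @property
    def chroms(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chrom_list}

    @property
    def zoom_levels(self) -> list[int]:
        return [z.reduction_level for z in self.zooms]

    def _read_cstring(self, offset: int) -> str:
        chunks = []
        while True:
            buf = self.source.read_at(offset, 4096)
            if not buf:
                break
            nul = buf.find(b"\0")
            if nul >= 0:
                chunks.append(buf[:nul])
                break
            chunks.append(buf)
            offset += len(buf)
        return b"".join(chunks).decode()

    def close(self) -> None:
        self.source.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()

    # -- query plumbing ----------------------------------------------------

    def _resolve_range(self, chrom: str, start: int, end: int | None):
        info = self._by_name.get(chrom)
        if info is None:
            raise ChromNotFound(f"no chromosome {chrom!r} in file")
        if end is None:
            end = info.length
        if start > end:
            raise InvertedRange(f"start {start} > end {end}")
        # permissive clamping: past-the-end queries are empty, not errors
        end = min(end, info.length)
        start = max(min(start, end), 0)
        return info, start, end

    def _blocks(self, index_offset: int, chrom_id: int, start: int,
                end: int) -> Iterator[bytes]:
        if start >= end:
            return
        for off, size in rtree.overlapping_blocks(
                self.source, index_offset, chrom_id, start, end,
                self.header.endian):
            raw = self.source.read_at(off, size)
            yield decompress_block(raw, self.header.uncompress_buf_size)

    def zoom_records(self, level: int, chrom: str, start: int = 0,
                     end: int | None = None) -> list[ZoomRecord]:
        """Records of one zoom level overlapping the query range."""
        zh = next((z for z in self.zooms if z.reduction_level == level), None)
        if zh is None:
            raise NoSuchZoomLevel(
                f"no zoom level {level}; file has {self.zoom_levels}")
        info, start, end = self._resolve_range(chrom, start, end)
        out = []
        for block in self._blocks(zh.index_offset, info.id, start, end):
            for rec in unpack_zoom_records(block, self.header.endian):
                if rec.chrom_id == info.id and rec.start < end \
                        and rec.end > start:
                    out.append(rec)
        return out


class BigWigFile(BBIFile):
    """Step-function signal: intervals, per-base values, binned stats."""

    def __init__(self, source: ByteSource):
        super().__init__(source)
        if not self.header.is_bigwig:
            raise WrongFileType("file is a BigBed, not a BigWig")

    def intervals(self, chrom: str, start: int = 0, end: int | None = None,
                  trim: bool = False) -> Iterator[Interval]:
        """Intervals overlapping [start, end), sorted, lazily decoded.

        By default intervals come back untrimmed (their full stored
        extent); ``trim=True`` clips them to the query window.
        """
        info, start, end = self._resolve_range(chrom, start, end)
        for block in self._blocks(self.header.full_index_offset, info.id,
                                  start, end):
            cid, items = decode_wig_section(block, self.header.endian)
            if cid != info.id:
                continue
            for iv in items:
                if iv.start < end and iv.end > start:
                    if trim:
                        yield Interval(max(iv.start, start),
                                       min(iv.end, end), iv.value)
                    else:
                        yield iv

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base float64 array of length end-start; NaN where uncovered."""
        info, qstart, qend = self._resolve_range(chrom, start, end)
        out = np.full(end - start, np.nan)
        for iv in self.intervals(chrom, qstart, qend, trim=True):
            out[iv.start - start:iv.end - start] = iv.value
        return out

    def stats(self, chrom: str, start: int = 0, end: int | None = None,
              statistic: str = "mean", nbins: int = 1,
              mode: str = "exact") -> list[float]:
        """Binned summary statistics over a range.

        The range splits into ``nbins`` equal bins (the last absorbs the
        remainder). ``mode='zoom'`` uses the coarsest zoom level whose
        reduction is at most half the bin length, apportioning partially
        overlapping zoom records proportionally to overlap; it falls
        back to exact data when no level qualifies.
        """
        if statistic not in STATISTICS:
            raise ValueError(f"unknown statistic {statistic!r}")
        if mode not in ("exact", "zoom", "zoom-approximate"):
            raise ValueError(f"unknown mode {mode!r}")
        info, start, end = self._resolve_range(chrom, start, end)
        length = end - start
        if nbins < 1 or nbins > max(length, 1):
            raise ValueError(f"nbins {nbins} outside 1..{length}")
        if length == 0:
            empty = 0.0 if statistic in ("coverage", "sum") else math.nan
            return [empty] * nbins
        # equal-width bins, remainder absorbed by the last one
        width = length // nbins
        edges = [start + i * width for i in range(nbins)] + [end]

        summaries = [Summary() for _ in range(nbins)]

        def bin_of(pos: int) -> int:
            return min((pos - start) // width, nbins - 1) if width else 0

        if mode == "exact" or not self.zooms:
            use_zoom = False
        else:
            bin_len = width or length
            candidates = [z for z in self.zoom_levels if z <= bin_len / 2]
            use_zoom = bool(candidates)
        if not use_zoom:
            for iv in self.intervals(chrom, start, end, trim=True):
                b0, b1 = bin_of(iv.start), bin_of(iv.end - 1)
                for b in range(b0, b1 + 1):
                    lo = max(iv.start, edges[b])
                    hi = min(iv.end, edges[b + 1])
                    summaries[b].add_run(hi - lo, iv.value)
        else:
            level = max(candidates)
            for rec in self.zoom_records(level, chrom, start, end):
                s = rec.summary
                span = rec.end - rec.start
                b0, b1 = bin_of(max(rec.start, start)), \
                    bin_of(min(rec.end, end) - 1)
                for b in range(b0, b1 + 1):
                    lo = max(rec.start, edges[b])
                    hi = min(rec.end, edges[b + 1])
                    frac = (hi - lo) / span
                    if frac <= 0:
                        continue
                    part = summaries[b]
                    part.valid_count += s.valid_count * frac
                    part.min_val = min(part.min_val, s.min_val)
                    part.max_val = max(part.max_val, s.max_val)
                    part.sum_data += s.sum_data * frac
                    part.sum_squares += s.sum_squares * frac

        out = []
        for b, s in enumerate(summaries):
            blen = edges[b + 1] - edges[b]
            n = s.valid_count
            if statistic == "coverage":
                out.append(n / blen if blen else 0.0)
            elif statistic == "sum":
                out.append(s.sum_data if n else 0.0)
            elif n == 0:
                out.append(math.nan)
            elif statistic == "mean":
                out.append(s.sum_data / n)
            elif statistic == "min":
                out.append(s.min_val)
            elif statistic == "max":
                out.append(s.max_val)
            elif statistic == "std":
                if n > 1:
                    var = (s.sum_squares - s.sum_data ** 2 / n) / (n - 1)
                    out.append(math.sqrt(max(var, 0.0)))
                else:
                    out.append(0.0)
        return out


class BigBedFile(BBIFile):
    """Feature records: entries with verbatim rest-strings."""

    def __init__(self, source: ByteSource):
        super().__init__(source)
        if not self.header.is_bigbed:
            raise WrongFileType("file is a BigWig, not a BigBed")

    def entries(self, chrom: str, start: int = 0,
                end: int | None = None) -> Iterator[BedEntry]:
        """Entries overlapping [start, end) in on-disk order."""
        info, start, end = self._resolve_range(chrom, start, end)
        for block in self._blocks(self.header.full_index_offset, info.id,
                                  start, end):
            for _cid, entry in decode_bed_block(
                    block, (info.id, start, end), self.header.endian):
                yield entry

    def schema(self) -> AutoSqlTable | None:
        return parse_autosql(self.autosql) if self.autosql else None

    def typed_entries(self, chrom: str, start: int = 0,
                      end: int | None = None):
        """Entries with rest columns converted per the embedded schema."""
        table = self.schema()
        if table is None:
            raise WrongFileType("file embeds no autoSql schema")
        for e in self.entries(chrom, start, end):
            yield (e.start, e.end) + type_entry(table, e.rest)


def open_bbi(path_or_source) -> BigWigFile | BigBedFile:
    """Open a BBI file of either kind, dispatching on its magic."""
    source = as_byte_source(path_or_source)
    header = read_header(source)
    return BigWigFile(source) if header.is_bigwig else BigBedFile(source)


def open_bigwig(path_or_source) -> BigWigFile:
    return BigWigFile(as_byte_source(path_or_source))


def open_bigbed(path_or_source) -> BigBedFile:
    return BigBedFile(as_byte_source(path_or_source))
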