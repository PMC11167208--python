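"""R-tree interval index over data blocks.

Leaves point at (file offset, byte size) of compressed data blocks, keyed
by bounding (chrom, base) ranges. The tree is bulk-loaded bottom-up from
the already-sorted leaf list and serialized breadth-first, root node
first, so query traversal touches O(depth + hits) nodes.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass

from .codec import RTREE_MAGIC
from .exceptions import BadIndexMagic, UnsortedLeafItems
from .source import ByteSource, read_exact

_HEADER_FMT = "<IIQIIIIQII"
_HEADER_SIZE = 48
_NODE_HEADER_SIZE = 4
_LEAF_ITEM_SIZE = 32
_INT_ITEM_SIZE = 24


@dataclass(slots=True)
class LeafItem:
    """One indexed data block: bounds plus its location in the file."""

    start_chrom: int
    start_base: int
    end_chrom: int
    end_base: int
    data_offset: int
    data_size: int

    def overlaps(self, chrom_id: int, start: int, end: int) -> bool:
        return ((self.start_chrom, self.start_base) < (chrom_id, end)
                and (self.end_chrom, self.end_base) > (chrom_id, start))


def build_rtree(leaf_items: list[LeafItem], block_size: int = 256,
                index_offset: int = 0, end_file_offset: int = 0,
                items_per_slot: int = 1) -> bytes:
    """Serialize a bulk-loaded R-tree.

    ``index_offset`` is the absolute file position where these bytes will
    land (child pointers are absolute); ``end_file_offset`` records where
    the indexed data region ends.
    """
    for a, b in zip(leaf_items, leaf_items[1:]):
        if (b.start_chrom, b.start_base) < (a.start_chrom, a.start_base):
            raise UnsortedLeafItems(
                f"leaf items out of order at ({a.start_chrom},{a.start_base})"
                f" -> ({b.start_chrom},{b.start_base})")

    if leaf_items:
        end_c, end_b = max((i.end_chrom, i.end_base) for i in leaf_items)
        bounds = (leaf_items[0].start_chrom, leaf_items[0].start_base,
                  end_c, end_b)
    else:
        bounds = (0, 0, 0, 0)

    # bottom-up grouping; each entry is (bounds, payload)
    def group(nodes: list) -> list:
        out = []
        for i in range(0, len(nodes), block_size):
            chunk = nodes[i:i + block_size]
            sc = min(c[0][0:2] for c in chunk)
            ec = max(c[0][2:4] for c in chunk)
            out.append(((sc[0], sc[1], ec[0], ec[1]), chunk))
        return out

    leaves = [((it.start_chrom, it.start_base, it.end_chrom, it.end_base), it)
              for it in leaf_items]
    levels = [group(leaves)] if leaves else [[((0, 0, 0, 0), [])]]
    while len(levels[-1]) > 1:
        levels.append(group(levels[-1]))
    levels.reverse()  # root first

    def node_size(is_leaf: bool, count: int) -> int:
        return _NODE_HEADER_SIZE + count * (
            _LEAF_ITEM_SIZE if is_leaf else _INT_ITEM_SIZE)

    offset = index_offset + _HEADER_SIZE
    node_offsets: list[list[int]] = []
    for li, level in enumerate(levels):
        is_leaf = li == len(levels) - 1
        offs = []
        for _, items in level:
            offs.append(offset)
            offset += node_size(is_leaf, len(items))
        node_offsets.append(offs)

    out = bytearray()
    out += struct.pack(_HEADER_FMT, RTREE_MAGIC, block_size, len(leaf_items),
                       bounds[0], bounds[1], bounds[2], bounds[3],
                       end_file_offset, items_per_slot, 0)
    for li, level in enumerate(levels):
        is_leaf = li == len(levels) - 1
        for ni, (_, items) in enumerate(level):
            out += struct.pack("<BBH", 1 if is_leaf else 0, 0, len(items))
            if is_leaf:
                for _, it in items:
                    out += struct.pack("<IIIIQQ", it.start_chrom,
                                       it.start_base, it.end_chrom,
                                       it.end_base, it.data_offset,
                                       it.data_size)
            else:
                child_base = sum(len(nd[1]) for nd in level[:ni])
                for j, (b, _) in enumerate(items):
                    out += struct.pack("<IIIIQ", b[0], b[1], b[2], b[3],
                                       node_offsets[li + 1][child_base + j])
    return bytes(out)


def read_rtree_header(source: ByteSource, index_offset: int,
                      endian: str = "<") -> tuple[int, int]:
    raw = read_exact(source, index_offset, _HEADER_SIZE)
    fields = struct.unpack(endian + _HEADER_FMT[1:], raw)
    if fields[0] != RTREE_MAGIC:
        raise BadIndexMagic(f"bad R-tree magic {fields[0]:#x}")
    return fields[1], fields[2]  # blockSize, itemCount


def overlapping_blocks(source: ByteSource, index_offset: int, chrom_id: int,
                       start: int, end: int,
                       endian: str = "<") -> list[tuple[int, int]]:
    """Exactly the leaf (offset, size) pairs overlapping the query, in
    file order. Subtrees whose bounds miss the query are never read."""
    read_rtree_header(source, index_offset, endian)
    hits: list[tuple[int, int]] = []

    def overlaps(sc, sb, ec, eb) -> bool:
        return (sc, sb) < (chrom_id, end) and (ec, eb) > (chrom_id, start)

    def visit(node_off: int) -> None:
        hdr = read_exact(source, node_off, _NODE_HEADER_SIZE)
        is_leaf, _res, count = struct.unpack(endian + "BBH", hdr)
        if is_leaf:
            body = read_exact(source, node_off + _NODE_HEADER_SIZE,
                              count * _LEAF_ITEM_SIZE)
            for i in range(count):
                sc, sb, ec, eb, doff, dsize = struct.unpack_from(
                    endian + "IIIIQQ", body, i * _LEAF_ITEM_SIZE)
                if overlaps(sc, sb, ec, eb):
                    hits.append((doff, dsize))
        else:
            body = read_exact(source, node_off + _NODE_HEADER_SIZE,
                              count * _INT_ITEM_SIZE)
            for i in range(count):
                sc, sb, ec, eb, child = struct.unpack_from(
                    endian + "IIIIQ", body, i * _INT_ITEM_SIZE)
                if overlaps(sc, sb, ec, eb):
                    visit(child)

    visit(index_offset + _HEADER_SIZE)
    return hits
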