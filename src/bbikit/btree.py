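"""Chromosome B+-tree: fixed-width name keys mapping to (id, length).

Keys are chromosome names null-padded to the length of the longest name;
ids are dense 0..n-1 assigned in key (lexicographic byte) order. The tree
is bulk-loaded bottom-up and serialized root-first so a reader can start
at the header and descend.
"""

from __future__ import annotations

import struct

from .codec import CHROM_TREE_MAGIC, ChromInfo
from .exceptions import BadTreeMagic, CorruptNode
from .source import ByteSource, read_exact

_HEADER_FMT = "<IIIIQQ"   # magic, blockSize, keySize, valSize, itemCount, reserved
_HEADER_SIZE = 32
_NODE_HEADER_SIZE = 4     # isLeaf u8, reserved u8, count u16


def write_chrom_tree(chroms: list[tuple[str, int]], block_size: int = 256) -> tuple[bytes, list[ChromInfo]]:
    """Serialize a chromosome B+-tree.

    ``chroms`` is (name, length) in any order; returns the tree bytes and
    the ChromInfo list in id order (names sorted, ids dense).
    """
    if not chroms:
        raise ValueError("cannot write a chromosome tree with no chromosomes")
    names = [n for n, _ in chroms]
    if len(set(names)) != len(names):
        raise ValueError("duplicate chromosome names")
    ordered = sorted(chroms, key=lambda c: c[0].encode())
    infos = [ChromInfo(name, i, length)
             for i, (name, length) in enumerate(ordered)]
    key_size = max(len(n.encode()) for n in names)
    val_size = 8

    def key(name: str) -> bytes:
        b = name.encode()
        return b + b"\0" * (key_size - len(b))

    # group into leaf nodes, then stack internal levels until one root
    leaf_items = [(key(c.name), c.id, c.length) for c in infos]
    levels: list[list[tuple[bytes, list]]] = []  # (first_key, items) per node
    nodes = [(leaf_items[i][0], leaf_items[i:i + block_size])
             for i in range(0, len(leaf_items), block_size)]
    levels.append(nodes)
    while len(levels[-1]) > 1:
        prev = levels[-1]
        nxt = [(prev[i][0], prev[i:i + block_size])
               for i in range(0, len(prev), block_size)]
        levels.append(nxt)
    levels.reverse()  # root level first

    leaf_item_size = key_size + val_size
    int_item_size = key_size + 8

    def node_size(is_leaf: bool, count: int) -> int:
        return _NODE_HEADER_SIZE + count * (leaf_item_size if is_leaf else int_item_size)

    # assign offsets level by level (root at header end)
    offset = _HEADER_SIZE
    node_offsets: list[list[int]] = []
    for li, level in enumerate(levels):
        is_leaf = li == len(levels) - 1
        offs = []
        for _, items in level:
            offs.append(offset)
            offset += node_size(is_leaf, len(items))
        node_offsets.append(offs)

    out = bytearray()
    out += struct.pack(_HEADER_FMT, CHROM_TREE_MAGIC, block_size, key_size,
                       val_size, len(infos), 0)
    for li, level in enumerate(levels):
        is_leaf = li == len(levels) - 1
        for ni, (_, items) in enumerate(level):
            out += struct.pack("<BBH", 1 if is_leaf else 0, 0, len(items))
            if is_leaf:
                for k, cid, clen in items:
                    out += k + struct.pack("<II", cid, clen)
            else:
                # children are consecutive nodes of the next level
                child_base = sum(len(nd[1]) for nd in level[:ni])
                for j, (first_key, _) in enumerate(items):
                    out += first_key + struct.pack(
                        "<Q", node_offsets[li + 1][child_base + j])
    return bytes(out), infos


def read_chrom_tree(source: ByteSource, offset: int) -> list[ChromInfo]:
    """Read every chromosome by traversing the tree; result in id order."""
    raw = read_exact(source, offset, _HEADER_SIZE)
    magic, block_size, key_size, val_size, item_count, _ = struct.unpack(
        _HEADER_FMT, raw)
    endian = "<"
    if magic != CHROM_TREE_MAGIC:
        magic_be = struct.unpack(">I", raw[:4])[0]
        if magic_be == CHROM_TREE_MAGIC:
            endian = ">"
            _, block_size, key_size, val_size, item_count, _ = struct.unpack(
                _HEADER_FMT.replace("<", ">"), raw)
        else:
            raise BadTreeMagic(f"bad chromosome tree magic {magic:#x}")

    out: list[ChromInfo] = []

    def visit(node_off: int) -> None:
        hdr = read_exact(source, node_off, _NODE_HEADER_SIZE)
        is_leaf, _res, count = struct.unpack(endian + "BBH", hdr)
        if count > block_size:
            raise CorruptNode(
                f"node at {node_off} has {count} items > blockSize {block_size}")
        if is_leaf:
            body = read_exact(source, node_off + _NODE_HEADER_SIZE,
                              count * (key_size + val_size))
            for i in range(count):
                base = i * (key_size + val_size)
                name = body[base:base + key_size].rstrip(b"\0").decode()
                cid, clen = struct.unpack_from(endian + "II", body,
                                               base + key_size)
                out.append(ChromInfo(name, cid, clen))
        else:
            body = read_exact(source, node_off + _NODE_HEADER_SIZE,
                              count * (key_size + 8))
            for i in range(count):
                base = i * (key_size + 8)
                (child,) = struct.unpack_from(endian + "Q", body,
                                              base + key_size)
                visit(child)

    visit(offset + _HEADER_SIZE)
    out.sort(key=lambda c: c.id)
    if len(out) != item_count:
        raise CorruptNode(
            f"tree header declares {item_count} items, found {len(out)}")
    return out
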