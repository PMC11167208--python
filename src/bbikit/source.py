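"""Random-access byte sources.

Everything in the package reads through the tiny ``read_at(offset, n)``
protocol so that local files, in-memory buffers and instrumented test
doubles are interchangeable.
"""

from __future__ import annotations

import io
import os
from typing import Protocol, runtime_checkable

from .exceptions import TruncatedFile


@runtime_checkable
class ByteSource(Protocol):
    def read_at(self, offset: int, n: int) -> bytes: ...

    def __len__(self) -> int: ...


class FileByteSource:
    """Positioned reads over a regular file (uses ``os.pread``)."""

    def __init__(self, path: str | os.PathLike):
        self.path = os.fspath(path)
        self._fd = os.open(self.path, os.O_RDONLY)
        self._size = os.fstat(self._fd).st_size

    def read_at(self, offset: int, n: int) -> bytes:
        return os.pread(self._fd, n, offset)

    def __len__(self) -> int:
        return self._size

    def close(self) -> None:
        if self._fd >= 0:
            os.close(self._fd)
            self._fd = -1

    def __del__(self):  # pragma: no cover - GC timing
        try:
            self.close()
        except OSError:
            pass


class MemoryByteSource:
    def __init__(self, data: bytes):
        self._data = data

    def read_at(self, offset: int, n: int) -> bytes:
        return self._data[offset:offset + n]

    def __len__(self) -> int:
        return len(self._data)

    def close(self) -> None:
        pass


class CountingByteSource:
    """Wrapper that counts positioned reads.

    Used by tests to assert the access contracts: R-tree traversal touches
    O(depth + hits) nodes, and streaming queries hold at most one data
    block at a time.
    """

    def __init__(self, inner: ByteSource):
        self.inner = inner
        self.read_count = 0
        self.bytes_read = 0
        self.reads: list[tuple[int, int]] = []

    def read_at(self, offset: int, n: int) -> bytes:
        self.read_count += 1
        self.bytes_read += n
        self.reads.append((offset, n))
        return self.inner.read_at(offset, n)

    def __len__(self) -> int:
        return len(self.inner)

    def close(self) -> None:
        self.inner.close()

    def reset(self) -> None:
        self.read_count = 0
        self.bytes_read = 0
        self.reads.clear()


def as_byte_source(obj) -> ByteSource:
    """Coerce a path, bytes, file object or ByteSource to a ByteSource."""
    if isinstance(obj, (str, os.PathLike)):
        return FileByteSource(obj)
    if isinstance(obj, (bytes, bytearray, memoryview)):
        return MemoryByteSource(bytes(obj))
    if isinstance(obj, io.BytesIO):
        return MemoryByteSource(obj.getvalue())
    if isinstance(obj, ByteSource):
        return obj
    raise TypeError(f"cannot make a byte source from {type(obj).__name__}")


def read_exact(source: ByteSource, offset: int, n: int) -> bytes:
    data = source.read_at(offset, n)
    if len(data) != n:
        raise TruncatedFile(
            f"wanted {n} bytes at offset {offset}, got {len(data)}"
        )
    return data
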