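"""Aggregation state shared by zoom records and the file-wide total summary.

A ``Summary`` holds (validCount, min, max, sumData, sumSquares) over covered
bases. Merging summaries is associative and commutative with ``NEUTRAL`` as
identity, which is what lets zoom levels be built by streaming reduction and
re-reduced from one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(slots=True)
class Summary:
    valid_count: int = 0
    min_val: float = math.inf
    max_val: float = -math.inf
    sum_data: float = 0.0
    sum_squares: float = 0.0

    @property
    def mean(self) -> float:
        return self.sum_data / self.valid_count if self.valid_count else math.nan

    @property
    def std(self) -> float:
        """Sample standard deviation over covered bases (0 when n <= 1)."""
        n = self.valid_count
        if n <= 1:
            return 0.0
        var = (self.sum_squares - self.sum_data * self.sum_data / n) / (n - 1)
        return math.sqrt(max(var, 0.0))

    def is_neutral(self) -> bool:
        return self.valid_count == 0

    def copy(self) -> "Summary":
        return Summary(self.valid_count, self.min_val, self.max_val,
                       self.sum_data, self.sum_squares)

    def add_run(self, length: int, value: float) -> None:
        """Fold in ``length`` bases all holding ``value`` (in place)."""
        if length <= 0:
            return
        self.valid_count += length
        if value < self.min_val:
            self.min_val = value
        if value > self.max_val:
            self.max_val = value
        self.sum_data += length * value
        self.sum_squares += length * value * value


NEUTRAL = Summary()


def summary_of_run(length: int, value: float) -> Summary:
    if length <= 0:
        return Summary()
    return Summary(length, value, value, length * value, length * value * value)


def merge_summary(a: Summary, b: Summary) -> Summary:
    """Combine two summaries; either may be the neutral element."""
    if a.valid_count == 0:
        return b.copy()
    if b.valid_count == 0:
        return a.copy()
    return Summary(
        a.valid_count + b.valid_count,
        min(a.min_val, b.min_val),
        max(a.max_val, b.max_val),
        a.sum_data + b.sum_data,
        a.sum_squares + b.sum_squares,
    )
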