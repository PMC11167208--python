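"""Deterministic synthetic genomes and brute-force per-base oracles.

Every randomized test in the suite draws its data here: generators are
pure functions of a :class:`GenSpec` (same seed, byte-identical output)
and the oracles are literal per-base array computations — slow,
obviously correct, and authoritative for what the indexed code paths
must return. Values are rounded to float32 at generation time so oracle
and file contents compare bit-equal (BigWig stores 32-bit values).

Nothing here attempts biological realism (no peak shapes, no
autocorrelation); the point is coverage of the format's edge cases, not
of real signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

MISSING = np.nan


@dataclass(slots=True)
class GenSpec:
    """Parameters of one synthetic dataset."""

    seed: int = 0
    n_chroms: int = 3
    chrom_len_range: tuple[int, int] = (10_000, 100_000)
    n_items: int = 1000
    value_dist: tuple = ("uniform", 0.0, 100.0)  # also ("normal",mu,sd), ("constant",c)
    gap_fraction: float = 0.3
    overlap_allowed: bool = False  # BED only
    span_dist: tuple[int, int] = (1, 200)
    bed_fields: int = 6            # BED-N column count for gen_bed

    def __post_init__(self):
        if not 0 <= self.gap_fraction < 1:
            raise ValueError("gap_fraction must be in [0, 1)")
        if self.chrom_len_range[0] > self.chrom_len_range[1]:
            raise ValueError("bad chrom_len_range")
        if self.span_dist[0] < 1 or self.span_dist[0] > self.span_dist[1]:
            raise ValueError("bad span_dist")


def _rng(spec: GenSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng((spec.seed, salt))


def _values(spec: GenSpec, rng: np.random.Generator, n: int) -> np.ndarray:
    kind = spec.value_dist[0]
    if kind == "uniform":
        v = rng.uniform(spec.value_dist[1], spec.value_dist[2], n)
    elif kind == "normal":
        v = rng.normal(spec.value_dist[1], spec.value_dist[2], n)
    elif kind == "constant":
        v = np.full(n, spec.value_dist[1], dtype=float)
    else:
        raise ValueError(f"unknown value_dist {kind!r}")
    return v.astype(np.float32).astype(float)


def gen_chrom_sizes(spec: GenSpec) -> list[tuple[str, int]]:
    """Chromosome names zero-padded so lexicographic order is numeric."""
    rng = _rng(spec, 1)
    width = max(2, len(str(spec.n_chroms)))
    lo, hi = spec.chrom_len_range
    return [(f"chr{i + 1:0{width}d}", int(rng.integers(lo, hi + 1)))
            for i in range(spec.n_chroms)]


def _alloc_items(spec: GenSpec, chrom_sizes) -> list[int]:
    """Split n_items across chromosomes proportionally to length."""
    total = sum(l for _, l in chrom_sizes)
    counts = [int(round(spec.n_items * l / total)) for _, l in chrom_sizes]
    drift = spec.n_items - sum(counts)
    counts[0] += drift
    return [max(c, 0) for c in counts]


def gen_bedgraph(spec: GenSpec, chrom_sizes=None):
    """Sorted, non-overlapping (chrom, start, end, value) records.

    Spans draw from ``span_dist``; gaps are sized so roughly
    ``gap_fraction`` of the traversed axis is uncovered. Items that
    would run off a chromosome are dropped, so the realized count can be
    slightly below ``n_items``.
    """
    chrom_sizes = chrom_sizes or gen_chrom_sizes(spec)
    rng = _rng(spec, 2)
    out: list[tuple[str, int, int, float]] = []
    for (name, length), count in zip(chrom_sizes, _alloc_items(spec, chrom_sizes)):
        if count == 0:
            continue
        spans = rng.integers(spec.span_dist[0], spec.span_dist[1] + 1, count)
        vals = _values(spec, rng, count)
        # mean gap chosen so gaps take gap_fraction of covered+gap length
        g = spec.gap_fraction
        mean_gap = (g / (1 - g)) * spans.mean() if g > 0 else 0.0
        gaps = rng.geometric(1.0 / (1.0 + mean_gap), count) - 1 \
            if mean_gap > 0 else np.zeros(count, dtype=int)
        pos = int(gaps[0])
        for i in range(count):
            if i:
                pos += int(gaps[i])
            end = pos + int(spans[i])
            if end > length:
                break
            out.append((name, pos, end, float(vals[i])))
            pos = end
    return out


_STRANDS = ("+", "-", ".")


def gen_bed(spec: GenSpec, chrom_sizes=None):
    """Sorted BED entries (chrom, start, end, rest) with bed_fields columns.

    Overlaps occur whenever ``overlap_allowed``; otherwise entries are
    disjoint like a bedGraph. Names are unique across the dataset.
    """
    chrom_sizes = chrom_sizes or gen_chrom_sizes(spec)
    rng = _rng(spec, 3)
    out: list[tuple[str, int, int, str]] = []
    serial = 0
    for (name, length), count in zip(chrom_sizes, _alloc_items(spec, chrom_sizes)):
        if count == 0:
            continue
        spans = rng.integers(spec.span_dist[0], spec.span_dist[1] + 1, count)
        if spec.overlap_allowed:
            starts = np.sort(rng.integers(0, max(length - spec.span_dist[1], 1),
                                          count))
            pairs = [(int(s), int(s + sp)) for s, sp in zip(starts, spans)
                     if s + sp <= length]
        else:
            g = spec.gap_fraction
            mean_gap = (g / (1 - g)) * spans.mean() if g > 0 else 0.0
            gaps = rng.geometric(1.0 / (1.0 + mean_gap), count) - 1 \
                if mean_gap > 0 else np.zeros(count, dtype=int)
            pairs = []
            pos = 0
            for i in range(count):
                pos += int(gaps[i])
                end = pos + int(spans[i])
                if end > length:
                    break
                pairs.append((pos, end))
                pos = end
        scores = rng.integers(0, 1001, len(pairs))
        strands = rng.integers(0, 3, len(pairs))
        for (s, e), sc, st in zip(pairs, scores, strands):
            cols = [f"item{serial}", str(int(sc)), _STRANDS[st],
                    str(s), str(e), "0"]
            rest = "\t".join(cols[:max(spec.bed_fields - 3, 0)])
            out.append((name, s, e, rest))
            serial += 1
    return out


# ---------------------------------------------------------------------------
# text renderings (what the CLI consumes)

def render_bedgraph(items) -> str:
    # repr gives the shortest text that reparses to the exact same float
    return "".join(f"{c}\t{s}\t{e}\t{v!r}\n" for c, s, e, v in items)


def render_bed(items) -> str:
    return "".join(
        f"{c}\t{s}\t{e}" + (f"\t{rest}" if rest else "") + "\n"
        for c, s, e, rest in items)


def render_chrom_sizes(chrom_sizes) -> str:
    return "".join(f"{name}\t{length}\n" for name, length in chrom_sizes)


# ---------------------------------------------------------------------------
# oracles

def oracle_track(items, chrom_sizes, kind: str | None = None) -> dict[str, np.ndarray]:
    """Literal per-base expansion.

    bedGraph items (4-tuples with a float value) give a value array with
    NaN at uncovered bases; BED items (3-tuples or 4-tuples whose fourth
    element is a rest-string) give an integer coverage-depth array. Pass
    ``kind`` ("wig"/"bed") explicitly when ``items`` may be empty.
    """
    if kind is None:
        if not items:
            raise ValueError("cannot infer track kind from empty items")
        first = items[0]
        kind = "bed" if len(first) == 3 or isinstance(first[3], str) else "wig"
    sizes = dict(chrom_sizes)
    if kind == "bed":
        tracks = {n: np.zeros(l, dtype=np.int64) for n, l in sizes.items()}
        for item in items:
            c, s, e = item[0], item[1], item[2]
            tracks[c][s:e] += 1
        return tracks
    tracks = {n: np.full(l, MISSING) for n, l in sizes.items()}
    for c, s, e, v in items:
        tracks[c][s:e] = v
    return tracks


def oracle_overlap(items, chrom: str, start: int, end: int) -> list:
    """Brute-force half-open overlap filter, preserving input order."""
    return [it for it in items
            if it[0] == chrom and it[1] < end and it[2] > start]


def oracle_summary(track: np.ndarray, start: int = 0,
                   end: int | None = None):
    """(validCount, min, max, sumData, sumSquares) over covered bases."""
    from .summary import Summary
    seg = track[start:end if end is not None else len(track)]
    seg = np.asarray(seg, dtype=float)
    covered = seg[~np.isnan(seg)]
    if covered.size == 0:
        return Summary()
    return Summary(int(covered.size), float(covered.min()),
                   float(covered.max()), float(covered.sum()),
                   float((covered * covered).sum()))


def oracle_stats(track: np.ndarray, start: int, end: int, statistic: str,
                 nbins: int) -> list[float]:
    """Binned statistics straight off the per-base array."""
    length = end - start
    width = length // nbins
    edges = [start + i * width for i in range(nbins)] + [end]
    out = []
    for b in range(nbins):
        s = oracle_summary(track, edges[b], edges[b + 1])
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
            out.append(s.std)
        else:
            raise ValueError(statistic)
    return out


def oracle_merge(tracks: Sequence[dict[str, np.ndarray]]) -> dict[str, np.ndarray]:
    """Base-wise sum of several per-base value tracks (NaN = uncovered).

    Uncovered bases stay NaN only where no input covers them.
    """
    names: dict[str, int] = {}
    for t in tracks:
        for n, arr in t.items():
            names[n] = max(names.get(n, 0), len(arr))
    out = {}
    for n, length in names.items():
        acc = np.zeros(length)
        covered = np.zeros(length, dtype=bool)
        for t in tracks:
            arr = t.get(n)
            if arr is None:
                continue
            mask = ~np.isnan(arr)
            acc[:len(arr)][mask] += arr[mask]
            covered[:len(arr)][mask] = True
        acc[~covered] = MISSING
        out[n] = acc
    return out


def step_function(track: np.ndarray) -> list[tuple[int, int, float]]:
    """Minimal sorted step function of a per-base array (NaN = absent),
    adjacent equal-valued runs merged."""
    out = []
    cur_val = None
    cur_start = 0
    for i, v in enumerate(track):
        missing = isinstance(v, float) and math.isnan(v)
        v_key = None if missing else float(v)
        if v_key != cur_val:
            if cur_val is not None:
                out.append((cur_start, i, cur_val))
            cur_val = v_key
            cur_start = i
    if cur_val is not None:
        out.append((cur_start, len(track), cur_val))
    return out
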