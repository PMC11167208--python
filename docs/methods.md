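# Methods

## The container in brief

A BBI file is a directory of co-stored parts: a 64-byte fixed header
(magic distinguishes BigWig `0x888FFC26` from BigBed `0x8789F2EB` and
reveals byte order), a list of zoom headers, the embedded autoSql text
(BigBed), a 40-byte total summary, a chromosome B+-tree, the main data
area (a 32-bit record count followed by deflate-compressed blocks), an
R-tree over those blocks, and per zoom level a record count, compressed
zoom-record blocks and another R-tree. `bbikit` writes header version 4,
always little-endian, and reads versions 3–4 in either byte order
(version < 3 is rejected: its zoom/summary layout differs). Compressed
blocks are RFC-1950 zlib streams (level 6 by default; `compress=False`
stores blocks raw and records `uncompressBufSize = 0`).

Coordinates are 0-based half-open everywhere — in the API, in text
formats and on disk — so no shifting happens anywhere.

BigWig data sections carry one of three encodings; the writer
auto-detects the most compact lossless one per section: fixed-step when
all items share one span and starts form an arithmetic progression
(step ≥ span), else variable-step when spans are uniform, else bedgraph.
Sections never span chromosomes and hold at most `items_per_slot` items
(1024 wig / 512 bed by default).

One detail worth knowing when cross-reading with other tools: the
chromosome B+-tree signature in real files (and in this package) is
`0x78CA8C91`, keys are names null-padded to the longest name's length,
and ids are dense 0..n−1 in key order. The autoSql text is placed
between the zoom headers and the total summary because at least one
widely-used reader recovers its length as
`totalSummaryOffset − autoSqlOffset`.

## The summary algebra

Every aggregate in the format is the 5-tuple
S = (validCount, min, max, sumData, sumSquares) over covered bases.
Merging is componentwise (counts and sums add, min/max combine) with the
empty summary (count 0, min = +inf, max = −inf, sums 0) as identity;
the operation is associative and commutative up to floating-point
re-association of the sums, which the tests treat as exact for
counts/min/max and 1e-12-relative for the sums. Derived statistics:

- mean = sumData / validCount (NaN when validCount = 0)
- coverage = validCount / binLength
- std = sqrt((sumSquares − sumData²/validCount)/(validCount − 1)) for
  validCount > 1, else 0.

The two-pass variance form is what the on-disk tuple permits; it cancels
catastrophically when the variance is tiny relative to the mean, so
near-constant windows can report std off by ~sqrt(eps)·|value| in
absolute terms (the implementation clamps negative variances to 0). The
test suite compares std with that allowance and everything else at
1e-9 relative.

Precision: BigWig data values are stored as 32-bit floats (fixed by the
format); inputs are validated finite *after* rounding to float32, and
the synthetic generators round at generation time so files and oracles
compare bit-equal. The total summary is float64 on disk. Zoom records,
however, store their counts as uint32 and their summary fields as
float32 — also format-fixed — so in-memory zoom reduction is float64 and
exact to 1e-9 against per-base oracles, while records read back from
disk agree at float32 precision (~1e-6 relative).

## Zoom levels

The writer plans a geometric schedule: level₀ =
max(2, ceil(initial_zoom_factor × mean item span)) with
initial_zoom_factor 10, each subsequent level ×4 (zoom_multiplier), at
most 10 levels, stopping once a level exceeds half the longest
chromosome. In single-pass mode the mean span is estimated from the
first 10,000 items (the whole stream cannot be seen); buffered mode uses
the exact mean. Reduction partitions each chromosome into windows of
`level` bases anchored at 0; a run crossing a window boundary
contributes to each window proportionally, per-base exactly; empty
windows are omitted; the last window of a chromosome is clipped to its
length. Because the algebra is associative, re-reducing level-k records
into 4k-windows reproduces the direct 4k reduction, which is tested.

For BigBed, zoom levels and the total summary aggregate **per-base
coverage depth** (the number of entries covering a base), the
conventional interpretation. Depth is computed on the fly with a sweep
over entry starts and a min-heap of active ends, so overlapping entries
stream in one pass.

## Single-pass writing

`write_bigwig`/`write_bigbed` consume their input iterator exactly once.
While streaming, the writer keeps one open section buffer
(≤ items_per_slot items) and one window accumulator per zoom level;
completed blocks are compressed and appended to spools, and R-tree leaf
bookkeeping is stored as fixed-width 32-byte records in its own spool.
Spools are unlinked temporary files by default
(`use_temp_files=False` switches them to in-memory buffers — same
bytes, more memory). Assembly then computes every offset up front and
emits the file front-to-back in one sequential write, so the sink never
needs to seek and pipes work directly; buffered and single-pass modes
produce byte-identical files for identical inputs and options.

With `threads > 1`, finished raw blocks are deflated in submission order
by a thread pool (zlib releases the GIL); ordering is preserved, so
output bytes are independent of the thread count — a determinism
contract the tests check, not a performance claim. Reading is pure and
stateless per query, so concurrent readers trivially agree with serial
ones.

Input contracts are enforced, not repaired: streams must be sorted by
lexicographic chromosome name (the B+-tree key order, which is also the
id order) then start; bedGraph intervals must not overlap; values must
be finite in float32; entries must fit their chromosome; BED column
counts must be rectangular. Violations raise typed errors naming the
offending item, and the CLI converts them to exit code 1 with the line
number.

## Queries

The R-tree is bulk-loaded bottom-up from the sorted leaf list (fanout
`block_size`, default 256) and serialized root-first; traversal descends
only subtrees whose bounds overlap the query, reading O(depth + hits)
nodes — an instrumented byte source verifies the bound. Interval/entry
queries decompress one block at a time and yield as they go; intervals
come back untrimmed by default (`trim=True` clips to the window).
`values()` returns a float64 per-base array with NaN at uncovered bases
— NaN, never 0, because 0 is a legal signal value.

`stats()` splits a range into nbins equal integer-width bins, the last
absorbing the remainder (note other implementations use fractional bin
edges; results coincide when the range divides evenly). Exact mode walks
the full-resolution data. Zoom mode picks the largest reduction level
≤ binLength/2 (falling back to exact when none qualifies) and apportions
partially overlapping zoom records proportionally to overlap length —
the standard browser heuristic. Out-of-range queries clamp: an end past
the chromosome is truncated, a start past the end yields an empty
result; only start > end *as given* is an error.

## autoSql

The parser covers the dialect BigBed files embed: a single `table`
declaration with the integer family, float/double, char[N],
string/lstring, fixed- and field-sized arrays (`int[blockCount]`),
enum(...) and set(...); `index`/`primary`/`auto` annotations are
tolerated and ignored; unknown type keywords are a syntax error rather
than an opaque passthrough. Typing never silently coerces — each column
either converts per its declared type (with range checks on the integer
family) or raises an error naming the field. Comma-separated arrays
tolerate a trailing comma, the BED12 blockSizes convention, and arrays
sized by another field are validated against that field's parsed value.
When writing a BigBed without a user schema, a canonical bedN+M schema
is generated; a user schema's field count must match the data (a
mismatch is an error, not a warning). `definedFieldCount` comes from an
explicit `bedN[+[M]]` type if given, else from the schema capped at 12,
else min(fieldCount, 12).

## Synthetic data and what the tests show

The generators are pure functions of a `GenSpec` (seed, chromosome count
and length range, item count, value distribution, gap fraction, span
range, overlap flag): chromosome names are zero-padded so lexicographic
and numeric order coincide; intervals are laid down left to right with
geometric gaps sized to hit the requested uncovered fraction; BED
entries optionally overlap. Defaults (3 chromosomes of 10–100 kb, ~1000
items, spans 1–200 bp, 30% gaps, uniform values) are desk-scale stand-ins
for real signal tracks; the randomized sweeps go up to 5 chromosomes of
1 Mb and 10⁵ items. The oracles are literal per-base arrays — value
arrays for wig, depth arrays for bed — and every indexed code path is
tested against them.

What passing shows: bit-exact round-trips, index correctness, summary
arithmetic and cross-implementation interoperability on data whose
*structure* spans the format's edge cases (empty files, single items,
multi-level trees, overlapping entries, all three wig encodings, both
byte orders). What it does not show: behavior at full mammalian-genome
scale (chromosome lengths here are ~10³× smaller), realistic signal
autocorrelation or peak shapes, and network byte sources.

## Known limitations

- BigBed extra indices (name lookup sections) are not written or read.
- No caching/prefetch layer for remote sources; each query re-reads the
  index nodes it traverses.
- Corrupt files fail fast with typed errors; there is no best-effort
  recovery mode.
- `stats` bins use integer widths (see above) — agreement with
  fractional-edge implementations is exact only when nbins divides the
  range length.
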