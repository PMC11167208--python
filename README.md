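# bbikit

Reading, writing and querying **BigWig** and **BigBed** files in pure
Python, with drop-in command-line tools.

BigWig and BigBed — collectively *BBI* (Big Binary Indexed) files — are
the compressed, indexed binary containers genome browsers and NGS
pipelines use for quantitative signal tracks and interval features. One
file holds the primary data in deflate-compressed blocks, an R-tree
interval index, precomputed "zoom level" summaries at several
resolutions, a chromosome B+-tree and a file-wide total summary, so
arbitrary genomic ranges can be answered with a handful of block reads,
locally or over remote byte ranges. The catch is that the binary layout
is intricate, which makes independent tooling scarce. `bbikit` is a
complete, self-contained codec for that layout:

- **Reader** — open a BigWig/BigBed (path, bytes, or any object with
  `read_at(offset, n)`), query intervals/entries, per-base value arrays,
  zoom records, and exact or zoom-approximated binned statistics
  (mean/min/max/coverage/sum/std). Queries stream block by block; one
  decompressed block is resident at a time.
- **Writer** — build valid files from sorted streams, including a
  **single-pass mode** that consumes the input exactly once (so standard
  input works) and spills sections, zoom records and index bookkeeping
  to temporary files to keep memory flat. Zoom levels follow a geometric
  schedule; summaries aggregate per-base exactly (coverage depth for
  BigBed). Output is byte-deterministic, independent of thread count.
- **autoSql** — parse the schema language embedded in BigBed files,
  render it back, and convert entry rest-strings to typed tuples
  (BED12 comma-list conventions included).
- **CLI** — `bedgraphtobigwig`, `bedtobigbed`, `bigwigmerge`,
  `bigwigaverageoverbed`, `bigwigtobedgraph`, `bigbedtobed`,
  `bigwiginfo`, as subcommands of one `bbikit` binary and as individual
  entry points, accepting UCSC-style `-flag=value` arguments.
- **Fixtures** — deterministic synthetic genome generators and
  brute-force per-base oracles that power the test suite.

The summary algebra at the core of zoom levels is the 5-tuple
*(validCount, min, max, sumData, sumSquares)* per window, merged with an
associative, commutative fold whose neutral element is the empty
summary; from it mean = sumData/validCount and
std = sqrt((sumSquares − sumData²/n)/(n−1)) are recovered per window,
bin or file.

## A worked example

```python
import bbikit

chroms = [("chr1", 1000), ("chr2", 500)]
intervals = [("chr1", 0, 50, 1.5), ("chr1", 100, 200, 2.5),
             ("chr2", 10, 20, 3.0)]
report = bbikit.write_bigwig(iter(intervals), chroms, "example.bw")
print(report.total_summary)

f = bbikit.open_bigwig("example.bw")
print(list(f.intervals("chr1", 40, 120)))
print(f.stats("chr1", 0, 200, "mean", nbins=2))
```

prints

```
Summary(valid_count=160, min_val=1.5, max_val=3.0, sum_data=355.0, sum_squares=827.5)
[Interval(start=0, end=50, value=1.5), Interval(start=100, end=200, value=2.5)]
[1.5, 2.5]
```

160 bases carry data (50 + 100 + 10); their value sum is
50·1.5 + 100·2.5 + 10·3 = 355. The range query returns both overlapping
intervals untrimmed (pass `trim=True` to clip them), and the two-bin
mean shows 1.5 over chr1:0–100 (only the first interval covers it) and
2.5 over chr1:100–200.

The same pipeline from the shell:

```sh
bbikit bedgraphtobigwig signal.bedGraph chrom.sizes signal.bw
bbikit bigwigmerge a.bw b.bw merged.bedGraph
bbikit bigwigaverageoverbed signal.bw regions.bed out.tab
```

`bigwigmerge` emits the base-wise sum of its inputs as a minimal step
function; `bigwigaverageoverbed` writes one row per region:
`name  size  covered  sum  mean0  mean` (mean0 averages over all bases,
mean over covered bases only).

## Layout

```
src/bbikit/
  codec.py     on-disk structures: header, sections, bed blocks, zoom records
  btree.py     chromosome B+-tree (fixed-width keys, dense ids)
  rtree.py     R-tree interval index: bulk load + bounded traversal
  summary.py   the (validCount, min, max, sumData, sumSquares) algebra
  reader.py    BBIFile / BigWigFile / BigBedFile query API
  writer.py    streaming single-pass / buffered file creation
  autosql.py   schema parser, renderer, entry typing
  cli.py       the drop-in tool suite
  fixtures.py  synthetic data generators and per-base oracles
```

See `docs/methods.md` for the format details, numerical conventions and
design decisions.
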