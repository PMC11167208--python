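"""Writing: summary algebra, zoom planning/reduction, file creation,
stream validation, single-pass/buffered equivalence and determinism."""

import io
import math
import random
import struct

import numpy as np
import pytest

from bbikit import (
    Summary,
    WriteOptions,
    merge_summary,
    open_bigbed,
    open_bigwig,
    plan_zoom_levels,
    reduce_stream,
    write_bigbed,
    write_bigwig,
)
from bbikit.exceptions import (
    ChromLengthExceeded,
    FieldCountMismatch,
    OverlapError,
    RaggedFields,
    UnknownChrom,
    UnsortedError,
    ValueNotFinite,
)
from bbikit.fixtures import GenSpec, gen_bed, gen_bedgraph, gen_chrom_sizes, oracle_track
from bbikit.summary import summary_of_run

from conftest import bigwig_bytes, make_bigwig


class TestSummaryAlgebra:
    def test_componentwise_merge(self):
        a = Summary(10, 1, 3, 20, 50)
        b = Summary(5, 0, 2, 5, 7)
        assert merge_summary(a, b) == Summary(15, 0, 3, 25, 57)

    def test_neutral_element_is_identity(self):
        s = Summary(10, 1, 3, 20, 50)
        assert merge_summary(s, Summary()) == s
        assert merge_summary(Summary(), s) == s
        assert merge_summary(Summary(), Summary()).is_neutral()

    def test_fold_order_irrelevant(self):
        rng = np.random.default_rng(1)
        sums = [summary_of_run(int(rng.integers(1, 50)),
                               float(np.float32(rng.normal())))
                for _ in range(100)]
        ref = None
        for perm_seed in range(5):
            order = list(range(100))
            random.Random(perm_seed).shuffle(order)
            folded = Summary()
            for i in order:
                folded = merge_summary(folded, sums[i])
            # min/max/count exact; sums compared to fp tolerance since
            # float addition is only approximately commutative
            key = (folded.valid_count, folded.min_val, folded.max_val,
                   round(folded.sum_data, 6), round(folded.sum_squares, 6))
            ref = ref or key
            assert key == ref


class TestZoomPlanning:
    def test_default_schedule_from_unit_span(self):
        assert plan_zoom_levels(1.0, 10 ** 9) == [
            10, 40, 160, 640, 2560, 10240, 40960, 163840, 655360, 2621440]

    def test_stops_at_half_longest_chrom(self):
        assert plan_zoom_levels(1.0, 50) == [10]

    def test_plan_is_increasing_and_bounded(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            span = float(rng.uniform(0.5, 500))
            longest = int(rng.integers(100, 10 ** 8))
            opts = WriteOptions(zoom_multiplier=int(rng.integers(2, 8)),
                                max_zoom_levels=int(rng.integers(0, 12)))
            plan = plan_zoom_levels(span, longest, opts)
            assert len(plan) <= opts.max_zoom_levels
            assert all(a < b for a, b in zip(plan, plan[1:]))
            assert all(lv <= longest / 2 for lv in plan)


class TestReduceStream:
    def test_single_run_split_across_windows(self):
        recs = list(reduce_stream([(0, 0, 10, 2.0)], level=4))
        assert [(r.start, r.end) for r in recs] == [(0, 4), (4, 8), (8, 12)]
        assert [r.summary for r in recs] == [
            Summary(4, 2, 2, 8, 16), Summary(4, 2, 2, 8, 16),
            Summary(2, 2, 2, 4, 8)]

    def test_empty_stream(self):
        assert list(reduce_stream([], level=8)) == []

    def test_unsorted_rejected(self):
        with pytest.raises(UnsortedError):
            list(reduce_stream([(0, 100, 110, 1.0), (0, 0, 10, 1.0)], 16))

    def test_rereduction_equals_direct_reduction(self):
        spec = GenSpec(seed=9, n_chroms=2, chrom_len_range=(5000, 9000),
                       n_items=400)
        cs = gen_chrom_sizes(spec)
        name_to_id = {n: i for i, (n, _) in enumerate(sorted(cs))}
        runs = [(name_to_id[c], s, e, v) for c, s, e, v in gen_bedgraph(spec, cs)]
        k = 16
        direct = list(reduce_stream(runs, 4 * k))
        # aggregate level-k records into 4k windows by summary merge
        agg: dict[tuple[int, int], Summary] = {}
        for r in reduce_stream(runs, k):
            key = (r.chrom_id, r.start // (4 * k))
            agg[key] = merge_summary(agg.get(key, Summary()), r.summary)
        assert len(direct) == len(agg)
        for r in direct:
            s = agg[(r.chrom_id, r.start // (4 * k))]
            assert s.valid_count == r.summary.valid_count
            assert s.min_val == r.summary.min_val
            assert s.max_val == r.summary.max_val
            assert s.sum_data == pytest.approx(r.summary.sum_data, rel=1e-12)
            assert s.sum_squares == pytest.approx(r.summary.sum_squares,
                                                  rel=1e-12)


class TestWriteBigWig:
    def test_empty_stream_yields_valid_empty_file(self, tmp_path):
        p = tmp_path / "empty.bw"
        report = write_bigwig(iter([]), [("chr1", 1000)], str(p))
        assert report.section_count == 0
        assert report.total_summary.is_neutral()
        f = open_bigwig(str(p))
        assert f.chroms == {"chr1": 1000}
        assert list(f.intervals("chr1")) == []
        assert f.total_summary.is_neutral()

    def test_single_interval_total_summary(self, tmp_path):
        p = tmp_path / "one.bw"
        report = write_bigwig([("chr1", 0, 10, 2.0)], [("chr1", 100)], str(p))
        assert report.total_summary == Summary(10, 2, 2, 20, 40)
        assert open_bigwig(str(p)).total_summary == Summary(10, 2, 2, 20, 40)

    def test_round_trip_random(self, small_wig):
        f = open_bigwig(str(small_wig["path"]))
        got = [(n, iv.start, iv.end, iv.value)
               for n, _ in small_wig["chrom_sizes"]
               for iv in f.intervals(n)]
        assert got == small_wig["items"]

    def test_total_summary_equals_per_base_fold(self, small_wig):
        tracks = oracle_track(small_wig["items"], small_wig["chrom_sizes"])
        valid = sum(int((~np.isnan(t)).sum()) for t in tracks.values())
        cat = np.concatenate([t[~np.isnan(t)] for t in tracks.values()])
        s = open_bigwig(str(small_wig["path"])).total_summary
        assert s.valid_count == valid
        assert s.min_val == cat.min() and s.max_val == cat.max()
        assert s.sum_data == pytest.approx(cat.sum(), rel=1e-12)
        assert s.sum_squares == pytest.approx((cat * cat).sum(), rel=1e-12)

    @pytest.mark.parametrize("bad,exc", [
        ([("chrX", 0, 10, 1.0)], UnknownChrom),
        ([("chr1", 0, 10, 1.0), ("chr1", 5, 15, 2.0)], OverlapError),
        ([("chr1", 50, 60, 1.0), ("chr1", 0, 10, 2.0)], UnsortedError),
        ([("chr1", 0, 10, float("nan"))], ValueNotFinite),
        ([("chr1", 0, 10, 1e39)], ValueNotFinite),  # overflows float32
        ([("chr1", 90, 150, 1.0)], ChromLengthExceeded),
    ])
    def test_stream_contract_violations(self, tmp_path, bad, exc):
        with pytest.raises(exc):
            write_bigwig(iter(bad), [("chr1", 100)], str(tmp_path / "x.bw"))

    def test_chromosome_order_is_lexicographic(self, tmp_path):
        # chr10 < chr2 lexicographically; the writer demands that order
        items = [("chr10", 0, 5, 1.0), ("chr2", 0, 5, 1.0)]
        write_bigwig(iter(items), [("chr2", 50), ("chr10", 50)],
                     str(tmp_path / "ok.bw"))
        with pytest.raises(UnsortedError):
            write_bigwig(iter(items[::-1]), [("chr2", 50), ("chr10", 50)],
                         str(tmp_path / "bad.bw"))

    def test_deterministic_bytes(self, small_wig):
        items, cs = small_wig["items"], small_wig["chrom_sizes"]
        assert bigwig_bytes(items, cs) == bigwig_bytes(items, cs)

    def test_threads_do_not_change_bytes(self, small_wig):
        items, cs = small_wig["items"], small_wig["chrom_sizes"]
        serial = bigwig_bytes(items, cs, WriteOptions(threads=1))
        threaded = bigwig_bytes(items, cs, WriteOptions(threads=3))
        assert serial == threaded

    def test_single_pass_equals_buffered(self, small_wig):
        items, cs = small_wig["items"], small_wig["chrom_sizes"]
        buffered = bigwig_bytes(items, cs, WriteOptions(single_pass=False))
        streamed = bigwig_bytes(items, cs, WriteOptions(single_pass=True))
        in_memory = bigwig_bytes(items, cs, WriteOptions(
            single_pass=True, use_temp_files=False))
        assert buffered == streamed == in_memory

    def test_single_pass_consumes_iterator_once(self, tmp_path):
        pulls = []

        def stream():
            for i in range(100):
                pulls.append(i)
                yield ("chr1", i * 10, i * 10 + 5, 1.0)

        write_bigwig(stream(), [("chr1", 2000)], str(tmp_path / "sp.bw"),
                     WriteOptions(single_pass=True))
        assert pulls == list(range(100))

    def test_block_item_counts_bounded_by_items_per_slot(self, tmp_path):
        spec = GenSpec(seed=77, n_chroms=1, chrom_len_range=(50_000, 50_000),
                       n_items=700)
        opts = WriteOptions(items_per_slot=64)
        path, cs, items, report = make_bigwig(tmp_path, spec, opts=opts)
        f = open_bigwig(str(path))
        from bbikit.rtree import overlapping_blocks
        from bbikit.codec import decompress_block
        h = f.header
        blocks = overlapping_blocks(f.source, h.full_index_offset, 0, 0,
                                    cs[0][1])
        assert len(blocks) == math.ceil(len(items) / 64) == report.section_count
        for off, size in blocks:
            raw = decompress_block(f.source.read_at(off, size),
                                   h.uncompress_buf_size)
            (count,) = struct.unpack_from("<H", raw, 22)
            assert count <= 64

    def test_uncompressed_mode(self, tmp_path):
        spec = GenSpec(seed=5, n_chroms=2, chrom_len_range=(3000, 6000),
                       n_items=100)
        path, cs, items, _ = make_bigwig(
            tmp_path, spec, opts=WriteOptions(compress=False))
        f = open_bigwig(str(path))
        assert f.header.uncompress_buf_size == 0
        got = [(n, iv.start, iv.end, iv.value) for n, _ in cs
               for iv in f.intervals(n)]
        assert got == items


class TestWriteBigBed:
    def test_minimal_entry_round_trip(self, tmp_path):
        p = tmp_path / "m.bb"
        report = write_bigbed([("chr1", 0, 10, "x")], [("chr1", 100)], str(p))
        f = open_bigbed(str(p))
        assert f.header.field_count == 4
        assert f.header.defined_field_count == 4
        assert list(f.entries("chr1")) == [(0, 10, "x")]
        assert report.data_count == 1

    def test_coverage_summary_of_overlapping_entries(self, tmp_path):
        # depth is 1 on [0,25) and [50,75), 2 on [25,50)
        p = tmp_path / "cov.bb"
        report = write_bigbed([("chr1", 0, 50, ""), ("chr1", 25, 75, "")],
                              [("chr1", 100)], str(p))
        assert report.total_summary == Summary(75, 1, 2, 100, 150)

    def test_round_trip_random_bed6(self, small_bed):
        f = open_bigbed(str(small_bed["path"]))
        got = [(n, e.start, e.end, e.rest)
               for n, _ in small_bed["chrom_sizes"] for e in f.entries(n)]
        assert got == small_bed["items"]

    def test_total_summary_equals_depth_oracle(self, small_bed):
        tracks = oracle_track(small_bed["items"], small_bed["chrom_sizes"],
                              kind="bed")
        depth = np.concatenate([t[t > 0] for t in tracks.values()])
        s = open_bigbed(str(small_bed["path"])).total_summary
        assert s.valid_count == depth.size
        assert (s.min_val, s.max_val) == (depth.min(), depth.max())
        assert s.sum_data == pytest.approx(depth.sum(), rel=1e-12)

    def test_ragged_fields_rejected(self, tmp_path):
        with pytest.raises(RaggedFields):
            write_bigbed([("chr1", 0, 10, "a\t1"), ("chr1", 20, 30, "b")],
                         [("chr1", 100)], str(tmp_path / "r.bb"))

    def test_autosql_field_count_validated(self, tmp_path):
        schema = 'table t "c" (string chrom; "c" uint chromStart; "s" uint chromEnd; "e")'
        with pytest.raises(FieldCountMismatch):
            write_bigbed([("chr1", 0, 10, "x")], [("chr1", 100)],
                         str(tmp_path / "x.bb"), autosql_text=schema)

    def test_custom_autosql_embedded_verbatim(self, tmp_path):
        schema = ('table t "c"\n(\n  string chrom; "c"\n  uint chromStart; "s"\n'
                  '  uint chromEnd; "e"\n  string label; "l"\n)\n')
        p = tmp_path / "as.bb"
        write_bigbed([("chr1", 0, 10, "x")], [("chr1", 100)], str(p),
                     autosql_text=schema)
        assert open_bigbed(str(p)).autosql == schema

    def test_single_pass_equals_buffered(self, small_bed):
        items, cs = small_bed["items"], small_bed["chrom_sizes"]
        outs = []
        for opts in (WriteOptions(single_pass=False),
                     WriteOptions(single_pass=True),
                     WriteOptions(single_pass=True, use_temp_files=False)):
            buf = io.BytesIO()
            write_bigbed(iter(items), cs, buf, opts, bed_type="bed6")
            outs.append(buf.getvalue())
        assert outs[0] == outs[1] == outs[2]
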