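"""Random-access queries: metadata, intervals/entries/values against
per-base oracles, zoom queries, binned statistics, laziness."""

import math

import numpy as np
import pytest

from bbikit import open_bbi, open_bigbed, open_bigwig, write_bigwig
from bbikit.exceptions import (
    ChromNotFound,
    InvertedRange,
    NoSuchZoomLevel,
    WrongFileType,
)
from bbikit.fixtures import (
    GenSpec,
    oracle_stats,
    oracle_track,
)
from bbikit.source import CountingByteSource, FileByteSource

from conftest import make_bigwig


@pytest.fixture(scope="module")
def wig(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("reader")
    spec = GenSpec(seed=17, n_chroms=3, chrom_len_range=(30_000, 80_000),
                   n_items=3000, gap_fraction=0.4)
    path, cs, items, report = make_bigwig(tmp, spec)
    return {"path": path, "cs": cs, "items": items,
            "tracks": oracle_track(items, cs), "report": report}


class TestOpen:
    def test_metadata_loaded_eagerly(self, wig):
        f = open_bigwig(str(wig["path"]))
        assert f.chroms == dict(wig["cs"])
        assert f.zoom_levels == wig["report"].zoom_levels
        assert f.total_summary == wig["report"].total_summary

    def test_wrong_file_type(self, wig, small_bed):
        with pytest.raises(WrongFileType):
            open_bigbed(str(wig["path"]))
        with pytest.raises(WrongFileType):
            open_bigwig(str(small_bed["path"]))
        assert open_bbi(str(wig["path"])).header.is_bigwig
        assert open_bbi(str(small_bed["path"])).header.is_bigbed

    def test_unknown_chrom_and_inverted_range(self, wig):
        f = open_bigwig(str(wig["path"]))
        with pytest.raises(ChromNotFound):
            list(f.intervals("chrNope", 0, 10))
        with pytest.raises(InvertedRange):
            list(f.intervals(wig["cs"][0][0], 100, 50))

    def test_out_of_range_queries_clamp_to_empty(self, wig):
        f = open_bigwig(str(wig["path"]))
        name, length = wig["cs"][0]
        assert list(f.intervals(name, length + 10, length + 20)) == []
        assert f.stats(name, length + 10, length + 20) == [math.nan] or \
            math.isnan(f.stats(name, length + 10, length + 20)[0])


class TestIntervalQueries:
    def test_untrimmed_overlap_semantics(self, tmp_path):
        p = tmp_path / "two.bw"
        write_bigwig([("chr1", 0, 10, 1.0), ("chr1", 10, 20, 3.0)],
                     [("chr1", 100)], str(p))
        f = open_bigwig(str(p))
        assert [tuple(iv) for iv in f.intervals("chr1", 5, 15)] == [
            (0, 10, 1.0), (10, 20, 3.0)]
        assert [tuple(iv) for iv in f.intervals("chr1", 5, 15, trim=True)] == [
            (5, 10, 1.0), (10, 15, 3.0)]
        assert list(f.intervals("chr1", 20, 30)) == []

    def test_random_queries_match_brute_force(self, wig):
        f = open_bigwig(str(wig["path"]))
        rng = np.random.default_rng(23)
        by_chrom = {n: [(s, e, v) for c, s, e, v in wig["items"] if c == n]
                    for n, _ in wig["cs"]}
        for _ in range(400):
            name, length = wig["cs"][int(rng.integers(0, len(wig["cs"])))]
            q0 = int(rng.integers(0, length))
            q1 = q0 + int(rng.integers(1, length // 3))
            brute = [iv for iv in by_chrom[name]
                     if iv[0] < q1 and iv[1] > q0]
            got = [tuple(iv) for iv in f.intervals(name, q0, q1)]
            assert got == brute

    def test_reading_is_pure(self, wig):
        f = open_bigwig(str(wig["path"]))
        name = wig["cs"][1][0]
        a = list(f.intervals(name, 100, 20_000))
        b = list(f.intervals(name, 100, 20_000))
        assert a == b

    def test_streaming_decompresses_lazily(self, tmp_path):
        from bbikit import WriteOptions
        spec = GenSpec(seed=13, n_chroms=1, chrom_len_range=(60_000, 60_000),
                       n_items=2000)
        path, cs, items, _ = make_bigwig(
            tmp_path, spec, opts=WriteOptions(items_per_slot=64))
        src = CountingByteSource(FileByteSource(str(path)))
        f = open_bigwig(src)
        name, length = cs[0]
        src.reset()
        it = f.intervals(name, 0, length)
        next(it)
        reads_after_first = src.read_count
        rest = list(it)
        assert len(rest) > 100
        # pulling one interval must not have read the whole chromosome
        assert reads_after_first < src.read_count / 2


class TestValues:
    def test_per_base_expansion_with_nan_gaps(self, tmp_path):
        p = tmp_path / "v.bw"
        write_bigwig([("chr1", 0, 10, 2.0)], [("chr1", 100)], str(p))
        f = open_bigwig(str(p))
        got = f.values("chr1", 5, 15)
        assert got[:5].tolist() == [2.0] * 5
        assert np.isnan(got[5:]).all()
        assert np.isnan(f.values("chr1", 50, 60)).all()

    def test_matches_oracle_track(self, wig):
        f = open_bigwig(str(wig["path"]))
        rng = np.random.default_rng(31)
        for _ in range(50):
            name, length = wig["cs"][int(rng.integers(0, len(wig["cs"])))]
            q0 = int(rng.integers(0, length - 1))
            q1 = q0 + int(rng.integers(1, min(5000, length - q0)))
            exp = wig["tracks"][name][q0:q1]
            got = f.values(name, q0, q1)
            np.testing.assert_array_equal(got, exp)


class TestZoomQueries:
    def test_records_tile_covered_data(self, wig):
        f = open_bigwig(str(wig["path"]))
        level = f.zoom_levels[0]
        for name, length in wig["cs"]:
            recs = f.zoom_records(level, name)
            covered = {i for r in recs for i in range(r.start // level,
                                                      -(-r.end // level))}
            track = wig["tracks"][name]
            data_windows = {i for i in range(length // level + 1)
                            if not np.isnan(
                                track[i * level:(i + 1) * level]).all()}
            assert data_windows <= covered
            for r in recs:
                assert r.end - r.start <= level
                assert r.summary.valid_count <= r.end - r.start

    def test_missing_level_raises(self, wig):
        f = open_bigwig(str(wig["path"]))
        with pytest.raises(NoSuchZoomLevel):
            f.zoom_records(12345, wig["cs"][0][0])

    def test_zoom_mean_matches_exact_mean_on_aligned_range(self, wig):
        f = open_bigwig(str(wig["path"]))
        level = f.zoom_levels[0]
        name, length = wig["cs"][0]
        q0, q1 = 0, (length // level) * level
        recs = f.zoom_records(level, name, q0, q1)
        valid = sum(r.summary.valid_count for r in recs)
        total = sum(r.summary.sum_data for r in recs)
        track = wig["tracks"][name][q0:q1]
        covered = track[~np.isnan(track)]
        assert valid == covered.size
        # zoom summaries are float32 on disk
        assert total == pytest.approx(covered.sum(), rel=1e-6)


class TestStats:
    def test_single_bin_mean(self, tmp_path):
        p = tmp_path / "s.bw"
        write_bigwig([("chr1", 0, 10, 1.0), ("chr1", 10, 20, 3.0)],
                     [("chr1", 100)], str(p))
        f = open_bigwig(str(p))
        assert f.stats("chr1", 0, 20, "mean", 1) == [2.0]
        assert f.stats("chr1", 0, 20, "sum", 2) == [10.0, 30.0]
        assert f.stats("chr1", 0, 20, "coverage", 1) == [1.0]
        assert f.stats("chr1", 20, 40, "coverage", 1) == [0.0]
        assert math.isnan(f.stats("chr1", 20, 40, "mean", 1)[0])

    def test_whole_chrom_mean_equals_total_summary_on_single_chrom(
            self, tmp_path):
        spec = GenSpec(seed=71, n_chroms=1, chrom_len_range=(40_000, 40_000),
                       n_items=900)
        path, cs, items, report = make_bigwig(tmp_path, spec)
        f = open_bigwig(str(path))
        [mean] = f.stats(cs[0][0], 0, cs[0][1], "mean", 1)
        assert mean == report.total_summary.mean

    @pytest.mark.parametrize("statistic",
                             ["mean", "min", "max", "coverage", "sum", "std"])
    def test_exact_stats_match_oracle(self, wig, statistic):
        f = open_bigwig(str(wig["path"]))
        rng = np.random.default_rng(hash(statistic) % 2 ** 31)
        for _ in range(30):
            name, length = wig["cs"][int(rng.integers(0, len(wig["cs"])))]
            q0 = int(rng.integers(0, length // 2))
            q1 = q0 + int(rng.integers(100, length - q0))
            nbins = int(rng.integers(1, 20))
            exp = oracle_stats(wig["tracks"][name], q0, q1, statistic, nbins)
            got = f.stats(name, q0, q1, statistic, nbins)
            for e, g in zip(exp, got):
                if math.isnan(e):
                    assert math.isnan(g)
                elif statistic == "std":
                    # the sumSq - sum^2/n form cancels catastrophically
                    # near zero variance; sqrt(eps)*|v| absolute slack
                    assert g == pytest.approx(e, rel=1e-6, abs=2e-6)
                else:
                    assert g == pytest.approx(e, rel=1e-9, abs=1e-12)

    def test_zoom_approximate_mean_close_to_exact(self, wig):
        f = open_bigwig(str(wig["path"]))
        level = f.zoom_levels[0]
        name, length = wig["cs"][0]
        # bin length exactly 2x the level: the selection rule (largest
        # reduction <= binLength/2) picks this level, and bins align
        # with its windows
        nbins = min(8, length // (2 * level))
        span = nbins * 2 * level
        exact = f.stats(name, 0, span, "mean", nbins, mode="exact")
        approx = f.stats(name, 0, span, "mean", nbins, mode="zoom")
        for e, a in zip(exact, approx):
            # bin edges align with zoom windows: agreement to f32 rounding
            assert a == pytest.approx(e, rel=1e-6)
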