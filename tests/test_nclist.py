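"""Nested containment list construction, queries, lazy chunks, statistics."""

import gzip
import json

import pytest
from intervaltree import IntervalTree

from conftest import brute_force_overlap, random_features
from trackkit.core import Feature, GenomicInterval
from trackkit.nclist import (
    MemoryTrack,
    build_nclist,
    load_track,
    serialize_track,
    track_stats,
)


def _features(pairs, seq="ctg01"):
    return [
        Feature(interval=GenomicInterval(seq, a, b), id=f"f{i}")
        for i, (a, b) in enumerate(pairs)
    ]


def _shape(nodes):
    return [
        ((n.interval.start, n.interval.end), _shape(n.sublist)) for n in nodes
    ]


class TestBuildNclist:
    def test_containment_nesting(self):
        feats = _features([(0, 10), (2, 5), (3, 4), (6, 9), (12, 20)])
        top = build_nclist(feats)["ctg01"]
        assert _shape(top) == [
            ((0, 10), [((2, 5), [((3, 4), [])]), ((6, 9), [])]),
            ((12, 20), []),
        ]

    def test_identical_intervals_nest_first_under_second(self):
        feats = _features([(5, 8), (5, 8)])
        top = build_nclist(feats)["ctg01"]
        assert len(top) == 1
        assert top[0].feature.id == "f0"
        assert top[0].sublist[0].feature.id == "f1"

    def test_cotangent_starts_longer_is_parent(self):
        feats = _features([(3, 5), (3, 12)])
        top = build_nclist(feats)["ctg01"]
        assert (top[0].interval.start, top[0].interval.end) == (3, 12)
        assert top[0].sublist[0].interval.end == 5

    def test_traversal_conserves_input_multiset(self, rng):
        feats = random_features(rng, 1_000)
        top = build_nclist(feats)["ctg01"]

        def collect(nodes):
            for n in nodes:
                yield (n.interval.start, n.interval.end)
                yield from collect(n.sublist)

        assert sorted(collect(top)) == sorted((f.start, f.end) for f in feats)

    def test_sibling_invariants_hold(self, rng):
        feats = random_features(rng, 500)

        def check(nodes):
            for prev, cur in zip(nodes, nodes[1:]):
                assert (prev.interval.start, -prev.interval.end) <= (
                    cur.interval.start, -cur.interval.end,
                )
                # no sibling contains another, so ends ascend too
                assert prev.interval.end <= cur.interval.end
            for n in nodes:
                for child in n.sublist:
                    assert n.interval.start <= child.interval.start
                    assert child.interval.end <= n.interval.end
                check(n.sublist)

        check(build_nclist(feats)["ctg01"])


class TestQuery:
    def test_spec_example(self):
        feats = _features([(0, 10), (2, 5), (3, 4), (6, 9), (12, 20)])
        track = MemoryTrack("t", feats, {"ctg01": 100})
        assert sorted((f.start, f.end) for f in track.query("ctg01", 4, 7)) == [
            (0, 10), (2, 5), (6, 9),
        ]

    def test_half_open_adjacency_excludes(self):
        feats = _features([(0, 10), (2, 5), (3, 4), (6, 9), (12, 20)])
        track = MemoryTrack("t", feats, {"ctg01": 100})
        assert track.query("ctg01", 10, 12) == []

    def test_unknown_refseq_is_empty_not_error(self):
        track = MemoryTrack("t", _features([(0, 5)]), {"ctg01": 100})
        assert track.query("chrUn", 0, 10) == []

    def test_results_in_start_order(self, rng):
        feats = random_features(rng, 300)
        track = MemoryTrack("t", feats, {"ctg01": 10_000})
        hits = track.query("ctg01", 2_000, 8_000)
        assert [f.start for f in hits] == sorted(f.start for f in hits)

    def test_oracle_equivalence_against_interval_tree(self, rng):
        feats = random_features(rng, 1_000)
        tree = IntervalTree.from_tuples((f.start, f.end) for f in feats)
        track = MemoryTrack("t", feats, {"ctg01": 10_000})
        for _ in range(200):
            s = rng.randrange(0, 9_999)
            e = rng.randrange(s + 1, 10_001)
            got = sorted((f.start, f.end) for f in track.query("ctg01", s, e))
            # intervaltree stores a *set* of intervals, so compare distinct
            # hits against it and the full multiset against a linear scan
            assert set(got) == {(iv.begin, iv.end) for iv in tree.overlap(s, e)}
            assert got == brute_force_overlap(feats, s, e)


class TestSerialization:
    def test_small_track_has_no_lazy_chunks(self, tmp_path, rng):
        feats = random_features(rng, 10)
        serialize_track(MemoryTrack("t", feats, {"ctg01": 10_000}), tmp_path,
                        chunk_feature_limit=1_000)
        files = list((tmp_path / "tracks" / "t" / "ctg01").iterdir())
        assert [f.name for f in files] == ["trackData.json"]

    def test_chunk_files_respect_feature_limit(self, tmp_path, rng):
        feats = random_features(rng, 2_000)
        serialize_track(MemoryTrack("t", feats, {"ctg01": 10_000}), tmp_path,
                        chunk_feature_limit=100)
        refdir = tmp_path / "tracks" / "t" / "ctg01"

        def count(items):
            return sum(
                1 + count(it[2]) for it in items if it[0] == "node"
            )

        total = 0
        for chunk in refdir.glob("lf-*.json"):
            n = count(json.loads(chunk.read_text()))
            assert n <= 100
            total += n
        assert total == 2_000

    def test_lazy_queries_equal_memory_queries(self, tmp_path, rng):
        feats = random_features(rng, 1_000)
        track = MemoryTrack("t", feats, {"ctg01": 10_000})
        serialize_track(track, tmp_path, chunk_feature_limit=50)
        lazy = load_track(tmp_path / "tracks" / "t")
        for _ in range(200):
            s = rng.randrange(0, 9_999)
            e = rng.randrange(s + 1, 10_001)
            assert sorted((f.start, f.end) for f in lazy.query("ctg01", s, e)) == \
                brute_force_overlap(feats, s, e)

    def test_round_trip_preserves_feature_content(self, tmp_path):
        gene = Feature(
            interval=GenomicInterval("ctg01", 10, 90, -1),
            type="gene", id="g1", name="geneA", score=3.5,
            attributes={"Alias": ["a1", "a2"]},
            subfeatures=[Feature(interval=GenomicInterval("ctg01", 20, 40, -1), type="exon")],
        )
        serialize_track(MemoryTrack("t", [gene], {"ctg01": 100}), tmp_path)
        (back,) = load_track(tmp_path / "tracks" / "t").query("ctg01", 0, 100)
        assert back.id == "g1" and back.name == "geneA" and back.score == 3.5
        assert back.attributes["Alias"] == ["a1", "a2"]
        assert back.subfeatures[0].type == "exon"
        assert back.strand == -1

    def test_laziness_opens_exactly_overlapping_chunks(self, tmp_path, rng):
        feats = random_features(rng, 1_000)
        serialize_track(MemoryTrack("t", feats, {"ctg01": 10_000}), tmp_path,
                        chunk_feature_limit=50)
        refdir = tmp_path / "tracks" / "t" / "ctg01"
        root = json.loads((refdir / "trackData.json").read_text())
        spans = {it[1]: (it[2], it[3]) for it in root["nclist"] if it[0] == "chunk"}
        assert spans, "expected the track to be chunked"
        lazy = load_track(tmp_path / "tracks" / "t")
        for s, e in [(0, 500), (4_000, 4_100), (9_000, 10_000)]:
            lazy_fresh = load_track(tmp_path / "tracks" / "t")
            lazy_fresh.query("ctg01", s, e)
            touching = sum(1 for a, b in spans.values() if a < e and s < b)
            assert lazy_fresh.chunks_opened == touching

    def test_compression_is_transparent(self, tmp_path, rng):
        feats = random_features(rng, 400)
        plain_track = MemoryTrack("t", feats, {"ctg01": 10_000})
        serialize_track(plain_track, tmp_path / "plain", chunk_feature_limit=50)
        serialize_track(plain_track, tmp_path / "gz", chunk_feature_limit=50,
                        compress=True)
        plain_dir = tmp_path / "plain" / "tracks" / "t" / "ctg01"
        gz_dir = tmp_path / "gz" / "tracks" / "t" / "ctg01"
        for plain_file in sorted(plain_dir.glob("lf-*.json")):
            gz_file = gz_dir / (plain_file.name + ".gz")
            assert gzip.decompress(gz_file.read_bytes()) == plain_file.read_bytes()
        lazy = load_track(tmp_path / "gz" / "tracks" / "t")
        assert sorted((f.start, f.end) for f in lazy.query("ctg01", 0, 10_000)) == \
            sorted((f.start, f.end) for f in feats)


class TestTrackStats:
    def test_count_and_density(self, rng):
        feats = random_features(rng, 50)
        track = MemoryTrack("t", feats, {"ctg01": 10_000})
        stats = track_stats(track, "ctg01")
        assert stats["feature_count"] == 50
        assert stats["feature_density"] == pytest.approx(0.005)

    def test_bins_sum_to_feature_count(self, rng):
        feats = random_features(rng, 50)
        track = MemoryTrack("t", feats, {"ctg01": 10_000})
        stats = track_stats(track, "ctg01", bin_size=1_000)
        assert len(stats["bins"]) == 10
        assert sum(stats["bins"]) == 50

    def test_region_count_equals_query_length(self, rng):
        feats = random_features(rng, 200)
        track = MemoryTrack("t", feats, {"ctg01": 10_000})
        for _ in range(50):
            s = rng.randrange(0, 9_999)
            e = rng.randrange(s + 1, 10_001)
            stats = track_stats(track, "ctg01", region=(s, e))
            assert stats["region_count"] == len(track.query("ctg01", s, e))

    def test_score_range(self):
        feats = [
            Feature(interval=GenomicInterval("c", 0, 5), score=2.0),
            Feature(interval=GenomicInterval("c", 5, 9), score=7.0),
        ]
        track = MemoryTrack("t", feats, {"c": 100})
        assert track_stats(track, "c")["score_range"] == (2.0, 7.0)

    def test_lazy_stats_match_memory_stats(self, tmp_path, rng):
        feats = random_features(rng, 300)
        track = MemoryTrack("t", feats, {"ctg01": 10_000})
        serialize_track(track, tmp_path, chunk_feature_limit=50)
        lazy = load_track(tmp_path / "tracks" / "t")
        mem = track_stats(track, "ctg01", bin_size=1_000)
        laz = track_stats(lazy, "ctg01", bin_size=1_000)
        assert laz["feature_count"] == mem["feature_count"]
        assert laz["feature_density"] == pytest.approx(mem["feature_density"])
        assert laz["bins"] == mem["bins"]
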