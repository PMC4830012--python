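"""Nested containment lists: construction, lazy chunked serialization, range
queries and track statistics.

An NCList stores any interval contained in another inside the container's
*sublist*. Siblings are sorted by start ascending (ties: end descending), and
because no sibling contains another, sibling ends are ascending too — so an
overlap query binary-searches each sibling run and descends only into nodes
whose intervals overlap the query. Sublists whose feature count would
overflow a chunk are externalized to numbered JSON files and loaded only when
a query's range overlaps their span, which is what lets a plain file server
host an index over millions of features.

On-disk layout for one track::

    <data_dir>/tracks/<label>/<refseq>/trackData.json
    <data_dir>/tracks/<label>/<refseq>/lf-<k>.json[.gz]

The root file holds global statistics (feature count, density, score range,
a histogram ladder) and the top level of the NCList with inline nodes and
lazy-chunk references. Node attributes are column-compressed: a per-track
table of attribute layouts ("classes") plus per-node value arrays.
"""

from __future__ import annotations

import bisect
import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path

from .core import Feature, GenomicInterval, contains

__all__ = [
    "NCListNode",
    "build_nclist",
    "query_nclist",
    "MemoryTrack",
    "LazyTrack",
    "serialize_track",
    "load_track",
    "query_track",
    "track_stats",
    "DEFAULT_CHUNK_FEATURE_LIMIT",
]

DEFAULT_CHUNK_FEATURE_LIMIT = 2_000

# Histogram ladder: powers-of-ten multiples of 1 kb.
_HISTOGRAM_BASE = 1_000


@dataclass
class NCListNode:
    feature: Feature
    sublist: list["NCListNode"] = field(default_factory=list)

    @property
    def interval(self) -> GenomicInterval:
        return self.feature.interval

    def count(self) -> int:
        """Number of features in this node's subtree (itself included)."""
        return 1 + sum(child.count() for child in self.sublist)


def build_nclist(features: list[Feature]) -> dict[str, list[NCListNode]]:
    """Build per-refseq nested containment lists in O(n log n).

    Features are sorted by (start asc, end desc); a single pass with a
    containment stack then places each feature either at the top level or in
    the sublist of the innermost feature containing it. With the tie-break,
    the longer of two co-started intervals becomes the parent, and equal
    intervals nest first-under-second.
    """
    per_seq: dict[str, list[Feature]] = {}
    for f in features:
        per_seq.setdefault(f.seq_id, []).append(f)
    result: dict[str, list[NCListNode]] = {}
    for seq_id, feats in per_seq.items():
        feats = sorted(feats, key=lambda f: (f.start, -f.end))
        top: list[NCListNode] = []
        stack: list[NCListNode] = []
        for f in feats:
            node = NCListNode(f)
            while stack and not contains(stack[-1].interval, node.interval):
                stack.pop()
            if stack:
                stack[-1].sublist.append(node)
            else:
                top.append(node)
            stack.append(node)
        result[seq_id] = top
    return result


def query_nclist(
    siblings: list[NCListNode], start: int, end: int
) -> list[Feature]:
    """All features overlapping [start, end), in start order."""
    hits: list[Feature] = []
    _collect(siblings, start, end, hits)
    hits.sort(key=lambda f: (f.start, f.end))
    return hits


def _collect(siblings, start, end, hits) -> None:
    # sibling ends are ascending: skip everything ending at or before `start`
    ends = [node.interval.end for node in siblings]
    i = bisect.bisect_right(ends, start)
    while i < len(siblings) and siblings[i].interval.start < end:
        node = siblings[i]
        if node.interval.start < end and start < node.interval.end:
            hits.append(node.feature)
        if node.sublist:
            _collect(node.sublist, start, end, hits)
        i += 1


# ---------------------------------------------------------------------------
# Feature (de)serialization: column-compressed node layout


_FIXED_FIELDS = ("type", "id", "name", "score", "phase", "source")


def _layout_of(feature: Feature) -> tuple:
    fixed = tuple(
        name for name in _FIXED_FIELDS if getattr(feature, name) is not None
    )
    return fixed + tuple(sorted(feature.attributes))


def _encode_feature(feature: Feature, classes: dict[tuple, int]) -> list:
    layout = _layout_of(feature)
    cls = classes.setdefault(layout, len(classes))
    iv = feature.interval
    row = [cls, iv.start, iv.end, iv.strand]
    for name in layout:
        if name in _FIXED_FIELDS:
            row.append(getattr(feature, name))
        else:
            row.append(feature.attributes[name])
    row.append([_encode_feature(s, classes) for s in feature.subfeatures])
    return row


def _decode_feature(row: list, classes: list[tuple], seq_id: str) -> Feature:
    cls, start, end, strand = row[0], row[1], row[2], row[3]
    layout = classes[cls]
    feature = Feature(interval=GenomicInterval(seq_id, start, end, strand))
    for name, value in zip(layout, row[4 : 4 + len(layout)]):
        if name in _FIXED_FIELDS:
            setattr(feature, name, value)
        else:
            feature.attributes[name] = list(value)
    feature.subfeatures = [
        _decode_feature(sub, classes, seq_id) for sub in row[-1]
    ]
    return feature


# ---------------------------------------------------------------------------
# Serialization with lazy chunking


class _ChunkWriter:
    def __init__(self, refseq_dir: Path, compress: bool):
        self.refseq_dir = refseq_dir
        self.compress = compress
        self.next_id = 0

    def write(self, payload) -> int:
        chunk_id = self.next_id
        self.next_id += 1
        data = json.dumps(payload, sort_keys=True).encode()
        if self.compress:
            path = self.refseq_dir / f"lf-{chunk_id}.json.gz"
            with open(path, "wb") as raw, gzip.GzipFile(
                fileobj=raw, mode="wb", mtime=0
            ) as fh:
                fh.write(data)
        else:
            (self.refseq_dir / f"lf-{chunk_id}.json").write_text(data.decode())
        return chunk_id


def _encode_nodes(nodes, classes, writer, limit):
    """Encode a sibling run; externalize runs that would overflow a chunk.

    Returns (encoded_items, inline_count). Each encoded item is either
    ["node", feature_row, sub_items] or ["chunk", id, span_start, span_end].
    """
    items = []
    counts = []
    for node in nodes:
        sub_items, sub_count = _encode_nodes(node.sublist, classes, writer, limit)
        if 1 + sub_count > limit:
            sub_items, sub_count = _externalize(sub_items, _node_counts(node.sublist, sub_items), writer, limit)
        row = _encode_feature_shallow(node.feature, classes)
        items.append(["node", row, sub_items])
        counts.append(1 + sub_count)
    return items, sum(counts)


def _node_counts(nodes, items):
    # recompute per-item inline counts after any nested externalization
    return [_item_count(item) for item in items]


def _item_count(item) -> int:
    if item[0] == "chunk":
        return 0
    return 1 + sum(_item_count(sub) for sub in item[2])


def _externalize(items, counts, writer, limit):
    """Greedily pack consecutive sibling items into chunk files of <= limit."""
    out = []
    group: list = []
    group_count = 0

    def flush():
        nonlocal group, group_count
        if not group:
            return
        span_start = min(it[1][1] for it in group if it[0] == "node")
        span_end = max(_item_span_end(it) for it in group)
        chunk_id = writer.write(group)
        out.append(["chunk", chunk_id, span_start, span_end])
        group, group_count = [], 0

    for item, count in zip(items, counts):
        if group and group_count + count > limit:
            flush()
        group.append(item)
        group_count += count
    flush()
    return out, 0


def _item_span_end(item) -> int:
    if item[0] == "chunk":
        return item[3]
    end = item[1][2]
    for sub in item[2]:
        end = max(end, _item_span_end(sub))
    return end


def _encode_feature_shallow(feature: Feature, classes) -> list:
    # NCList nesting is containment between top-level features; each
    # feature's own subfeature tree stays embedded in its row.
    return _encode_feature(feature, classes)


class MemoryTrack:
    """An in-memory feature track: NCList index plus per-refseq statistics."""

    def __init__(
        self,
        label: str,
        features: list[Feature],
        refseq_lengths: dict[str, int],
    ):
        self.label = label
        self.refseq_lengths = dict(refseq_lengths)
        self.nclists = build_nclist(features)
        self.features_by_seq: dict[str, list[Feature]] = {}
        for f in features:
            self.features_by_seq.setdefault(f.seq_id, []).append(f)

    def query(self, seq_name: str, start: int, end: int) -> list[Feature]:
        siblings = self.nclists.get(seq_name)
        if siblings is None:
            return []
        return query_nclist(siblings, start, end)

    def stats(self, seq_name: str, region=None, bin_size=None) -> dict:
        feats = self.features_by_seq.get(seq_name, [])
        length = self.refseq_lengths.get(seq_name, 0)
        return _stats_record(
            feats, length, region, bin_size, query=self.query, seq_name=seq_name
        )


def _stats_record(feats, length, region, bin_size, *, query, seq_name) -> dict:
    record: dict = {
        "feature_count": len(feats),
        "feature_density": (len(feats) / length) if length else 0.0,
    }
    scores = [f.score for f in feats if f.score is not None]
    record["score_range"] = (min(scores), max(scores)) if scores else None
    if region is not None:
        start, end = region
        record["region"] = [start, end]
        record["region_count"] = len(query(seq_name, start, end))
    if bin_size is not None:
        if bin_size < 1:
            raise ValueError("bin_size must be >= 1")
        span = length if length else max((f.end for f in feats), default=0)
        n_bins = max(1, -(-span // bin_size))
        bins = [0] * n_bins
        for f in feats:
            bins[min(f.start // bin_size, n_bins - 1)] += 1
        record["bin_size"] = bin_size
        record["bins"] = bins
    return record


def _histogram_ladder(length: int) -> list[int]:
    sizes = []
    size = _HISTOGRAM_BASE
    while size < max(length, _HISTOGRAM_BASE + 1):
        sizes.append(size)
        size *= 10
    return sizes or [_HISTOGRAM_BASE]


def serialize_track(
    track: MemoryTrack,
    data_dir: str | Path,
    chunk_feature_limit: int = DEFAULT_CHUNK_FEATURE_LIMIT,
    compress: bool = False,
) -> Path:
    """Write a track as lazily-loadable chunked JSON under ``data_dir``.

    A root ``trackData.json`` per refseq holds statistics, the attribute
    class table, and the top of the NCList; sibling runs that would overflow
    ``chunk_feature_limit`` features are split into ``lf-<k>.json`` chunk
    files referenced by their covered span.
    """
    track_dir = Path(data_dir) / "tracks" / track.label
    for seq_name in sorted(set(track.nclists) | set(track.refseq_lengths)):
        refseq_dir = track_dir / seq_name
        refseq_dir.mkdir(parents=True, exist_ok=True)
        writer = _ChunkWriter(refseq_dir, compress)
        classes: dict[tuple, int] = {}
        nodes = track.nclists.get(seq_name, [])
        items, count = _encode_nodes(nodes, classes, writer, chunk_feature_limit)
        if count > chunk_feature_limit:
            items, _ = _externalize(
                items, [_item_count(it) for it in items], writer, chunk_feature_limit
            )
        feats = track.features_by_seq.get(seq_name, [])
        length = track.refseq_lengths.get(seq_name, 0)
        histograms = {}
        for size in _histogram_ladder(length):
            histograms[str(size)] = _stats_record(
                feats, length, None, size, query=track.query, seq_name=seq_name
            )["bins"]
        root = {
            "label": track.label,
            "refseq": seq_name,
            "length": length,
            "feature_count": len(feats),
            "feature_density": (len(feats) / length) if length else 0.0,
            "score_range": _stats_record(
                feats, length, None, None, query=track.query, seq_name=seq_name
            )["score_range"],
            "histograms": histograms,
            "chunk_feature_limit": chunk_feature_limit,
            "compress": compress,
            "classes": [list(layout) for layout, _ in sorted(classes.items(), key=lambda kv: kv[1])],
            "nclist": items,
        }
        (refseq_dir / "trackData.json").write_text(
            json.dumps(root, sort_keys=True)
        )
    return track_dir


class LazyTrack:
    """A serialized track queried straight from its JSON files.

    Chunk files are opened only when a query's range overlaps their span;
    ``chunks_opened`` counts the files actually read (loaded chunks are
    cached, so the counter reflects distinct files).
    """

    def __init__(self, track_dir: str | Path):
        self.track_dir = Path(track_dir)
        self.label = self.track_dir.name
        self._roots: dict[str, dict] = {}
        self._chunk_cache: dict[tuple[str, int], list] = {}
        self.chunks_opened = 0
        for refseq_dir in sorted(self.track_dir.iterdir()):
            root_file = refseq_dir / "trackData.json"
            if root_file.exists():
                self._roots[refseq_dir.name] = json.loads(root_file.read_text())

    def refseqs(self) -> list[str]:
        return sorted(self._roots)

    def _load_chunk(self, seq_name: str, chunk_id: int) -> list:
        key = (seq_name, chunk_id)
        if key not in self._chunk_cache:
            root = self._roots[seq_name]
            base = self.track_dir / seq_name / f"lf-{chunk_id}.json"
            if root.get("compress"):
                with gzip.open(base.with_suffix(".json.gz"), "rt") as fh:
                    self._chunk_cache[key] = json.load(fh)
            else:
                self._chunk_cache[key] = json.loads(base.read_text())
            self.chunks_opened += 1
        return self._chunk_cache[key]

    def query(self, seq_name: str, start: int, end: int) -> list[Feature]:
        root = self._roots.get(seq_name)
        if root is None:
            return []
        classes = [tuple(c) for c in root["classes"]]
        hits: list[Feature] = []
        self._collect_items(root["nclist"], seq_name, classes, start, end, hits)
        hits.sort(key=lambda f: (f.start, f.end))
        return hits

    def _collect_items(self, items, seq_name, classes, start, end, hits):
        # A sibling run is homogeneous: either inline nodes or chunk refs
        # (externalization replaces a whole run with refs).
        if items and items[0][0] == "chunk":
            for item in items:
                _, chunk_id, span_start, span_end = item
                if span_start < end and start < span_end:
                    chunk = self._load_chunk(seq_name, chunk_id)
                    self._collect_items(chunk, seq_name, classes, start, end, hits)
            return
        for item in items:
            _, row, sub_items = item
            node_start, node_end = row[1], row[2]
            if node_start >= end:
                break  # siblings sorted by start: nothing further overlaps
            if start < node_end:
                hits.append(_decode_feature(row, classes, seq_name))
            if sub_items and start < node_end:
                self._collect_items(sub_items, seq_name, classes, start, end, hits)

    def _all_features(self, seq_name: str) -> list[Feature]:
        root = self._roots.get(seq_name)
        if root is None:
            return []
        return self.query(seq_name, 0, max(root.get("length", 0), _max_end(root["nclist"])) + 1)

    def stats(self, seq_name: str, region=None, bin_size=None) -> dict:
        root = self._roots.get(seq_name)
        if root is None:
            return {"feature_count": 0, "feature_density": 0.0, "score_range": None}
        record: dict = {
            "feature_count": root["feature_count"],
            "feature_density": root["feature_density"],
            "score_range": tuple(root["score_range"]) if root["score_range"] else None,
        }
        if region is not None:
            start, end = region
            record["region"] = [start, end]
            record["region_count"] = len(self.query(seq_name, start, end))
        if bin_size is not None:
            precomputed = root["histograms"].get(str(bin_size))
            if precomputed is not None:
                record["bins"] = precomputed
            else:
                feats = self._all_features(seq_name)
                record["bins"] = _stats_record(
                    feats, root.get("length", 0), None, bin_size,
                    query=self.query, seq_name=seq_name,
                )["bins"]
            record["bin_size"] = bin_size
        return record


def _max_end(items) -> int:
    best = 0
    for item in items:
        if item[0] == "chunk":
            best = max(best, item[3])
        else:
            best = max(best, _item_span_end(item))
    return best


def load_track(track_dir: str | Path) -> LazyTrack:
    return LazyTrack(track_dir)


def query_track(index, seq_name: str, start: int, end: int) -> list[Feature]:
    """Range query against either a MemoryTrack or a LazyTrack."""
    return index.query(seq_name, start, end)


def track_stats(index, seq_name: str, region=None, bin_size=None) -> dict:
    """Feature count/density, score range, optional region and bin counts."""
    return index.stats(seq_name, region=region, bin_size=bin_size)
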