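"""Reading and writing annotation features: GFF3, BED and BedGraph.

GFF3 is 1-based inclusive; BED and BedGraph are already interbase. Both
readers produce :class:`~trackkit.core.Feature` trees in the toolkit's
interbase convention, and the exporters convert back, so a read→write→read
round trip is a fixpoint of the feature forest.
"""

from __future__ import annotations

import urllib.parse
from pathlib import Path

from .core import Feature, GenomicInterval, SignalInterval

__all__ = [
    "read_gff3",
    "write_gff3",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph",
    "export_track",
]

_STRAND_FROM_TEXT = {"+": 1, "-": -1, ".": 0, "?": 0}
_STRAND_TO_TEXT = {1: "+", -1: "-", 0: "."}

# GFF3 reserved attribute keys, recognized case-insensitively on read but
# emitted in canonical capitalization.
_RESERVED = {"id": "ID", "name": "Name", "parent": "Parent", "alias": "Alias"}

# Characters that must be percent-escaped in GFF3 column 9 values.
_ATTR_SAFE = "".join(
    c for c in map(chr, range(33, 127)) if c not in "%;=&,"
)


def _text_of(source) -> str:
    if isinstance(source, Path):
        return source.read_text()
    if isinstance(source, str):
        if "\n" in source or "\t" in source:
            return source
        return Path(source).read_text()
    return source.read()


def _parse_attributes(col9: str):
    attrs: dict[str, list[str]] = {}
    for pair in col9.split(";"):
        pair = pair.strip()
        if not pair:
            continue
        if "=" not in pair:
            raise ValueError(f"malformed attribute {pair!r}")
        key, _, raw = pair.partition("=")
        key = _RESERVED.get(key.lower(), key)
        values = [urllib.parse.unquote(v) for v in raw.split(",")]
        attrs.setdefault(key, []).extend(values)
    return attrs


def read_gff3(source) -> list[Feature]:
    """Parse GFF3 into a forest of Feature trees.

    Features are assembled via ID/Parent; coordinates convert from 1-based
    inclusive to interbase; percent-escapes are decoded and multi-valued
    attributes split on commas. Multiple lines sharing one ID and type
    (discontinuous features, e.g. a spliced CDS) merge into a single Feature
    spanning all parts, with the parts as its subfeatures. An embedded
    ``##FASTA`` section terminates parsing.
    """
    text = _text_of(source)
    roots: list[Feature] = []
    by_id: dict[str, Feature] = {}
    pending: list[tuple[Feature, list[str], int]] = []  # (feature, parents, lineno)
    for lineno, line in enumerate(text.splitlines(), 1):
        if line.startswith("##FASTA"):
            break
        if not line.strip() or line.startswith("#"):
            continue
        cols = line.rstrip("\n").split("\t")
        if len(cols) != 9:
            raise ValueError(
                f"GFF3 line {lineno}: expected 9 tab-separated columns, got {len(cols)}"
            )
        seq_id, source_col, ftype, start_s, end_s, score_s, strand_s, phase_s, col9 = cols
        try:
            start, end = int(start_s) - 1, int(end_s)
        except ValueError:
            raise ValueError(f"GFF3 line {lineno}: non-numeric coordinates") from None
        attrs = _parse_attributes(col9)
        fid = attrs.pop("ID", [None])[0]
        name = attrs.pop("Name", [None])[0]
        parents = attrs.pop("Parent", [])
        feature = Feature(
            interval=GenomicInterval(
                seq_id, start, end, _STRAND_FROM_TEXT.get(strand_s, 0)
            ),
            type=ftype,
            id=fid,
            name=name,
            score=None if score_s == "." else float(score_s),
            phase=None if phase_s == "." else int(phase_s),
            source=None if source_col == "." else source_col,
            attributes=attrs,
        )
        if fid is not None and fid in by_id:
            _merge_discontinuous(by_id[fid], feature, lineno)
            continue
        if fid is not None:
            by_id[fid] = feature
        pending.append((feature, parents, lineno))

    orphans: list[str] = []
    for feature, parents, lineno in pending:
        if not parents:
            roots.append(feature)
            continue
        placed = False
        for pid in parents:
            parent = by_id.get(pid)
            if parent is None:
                orphans.append(pid)
            else:
                parent.subfeatures.append(feature)
                placed = True
        if not placed and all(p not in by_id for p in parents):
            pass  # reported below
    if orphans:
        raise ValueError(
            "GFF3 Parent references unknown IDs: " + ", ".join(sorted(set(orphans)))
        )
    return roots


def _merge_discontinuous(container: Feature, part: Feature, lineno: int) -> None:
    if part.type != container.type:
        raise ValueError(
            f"GFF3 line {lineno}: ID {container.id!r} reused with different type "
            f"({container.type!r} vs {part.type!r})"
        )
    if not container.subfeatures or any(
        s.id != container.id for s in container.subfeatures
    ):
        # First merge: turn the container into a span with the original line
        # as its first part.
        first_part = Feature(
            interval=container.interval,
            type=container.type,
            id=container.id,
            name=container.name,
            score=container.score,
            phase=container.phase,
            source=container.source,
            attributes=dict(container.attributes),
        )
        container.subfeatures = [first_part]
        container.phase = None
        container.score = None
    container.subfeatures.append(part)
    container.subfeatures.sort(key=lambda f: (f.start, f.end))
    iv = container.interval
    container.interval = GenomicInterval(
        iv.seq_id,
        min(iv.start, part.start),
        max(iv.end, part.end),
        iv.strand,
    )


def _is_discontinuous(feature: Feature) -> bool:
    return bool(feature.subfeatures) and all(
        s.id == feature.id and s.type == feature.type for s in feature.subfeatures
    ) and feature.id is not None


def _escape_attr(value: str) -> str:
    return urllib.parse.quote(value, safe=_ATTR_SAFE)


def _format_attributes(feature: Feature, parent_id: str | None) -> str:
    pairs: list[str] = []
    if feature.id is not None:
        pairs.append(f"ID={_escape_attr(feature.id)}")
    if feature.name is not None:
        pairs.append(f"Name={_escape_attr(feature.name)}")
    if parent_id is not None:
        pairs.append(f"Parent={_escape_attr(parent_id)}")
    for key in sorted(feature.attributes):
        values = ",".join(_escape_attr(v) for v in feature.attributes[key])
        pairs.append(f"{_escape_attr(key)}={values}")
    return ";".join(pairs) if pairs else "."


class _IdAllocator:
    def __init__(self, taken: set[str]):
        self.taken = taken
        self.n = 0

    def fresh(self) -> str:
        while True:
            self.n += 1
            candidate = f"f{self.n}"
            if candidate not in self.taken:
                self.taken.add(candidate)
                return candidate


def write_gff3(features: list[Feature]) -> str:
    """Emit a feature forest as GFF3, reconstructing ID/Parent links.

    Coordinates convert back to 1-based inclusive. Parents that lack an ID
    but have children receive a generated one. Discontinuous features (parts
    sharing the parent's ID and type) are emitted as multiple lines with the
    same ID.
    """
    taken = {f.id for root in features for f in root.walk() if f.id is not None}
    alloc = _IdAllocator(taken)
    lines = ["##gff-version 3"]

    def emit(feature: Feature, parent_id: str | None) -> None:
        if _is_discontinuous(feature):
            for part in feature.subfeatures:
                lines.append(_gff3_line(part, parent_id))
            return
        if feature.subfeatures and feature.id is None:
            feature = _with_id(feature, alloc.fresh())
        lines.append(_gff3_line(feature, parent_id))
        for sub in feature.subfeatures:
            emit(sub, feature.id)

    for root in features:
        emit(root, None)
    return "\n".join(lines) + "\n"


def _with_id(feature: Feature, fid: str) -> Feature:
    feature.id = fid
    return feature


def _gff3_line(feature: Feature, parent_id: str | None) -> str:
    iv = feature.interval
    return "\t".join(
        [
            iv.seq_id,
            feature.source if feature.source is not None else ".",
            feature.type,
            str(iv.start + 1),
            str(iv.end),
            "." if feature.score is None else _format_score(feature.score),
            _STRAND_TO_TEXT[iv.strand],
            "." if feature.phase is None else str(feature.phase),
            _format_attributes(feature, parent_id),
        ]
    )


def _format_score(score: float) -> str:
    return str(int(score)) if float(score).is_integer() else repr(float(score))


def read_bed(source) -> list[Feature]:
    """Parse BED3–BED12 into Features (BED is already interbase).

    BED12 blocks become child features of type ``block``; track/browser lines
    and comments are skipped. thickStart/thickEnd and itemRgb, when present,
    are preserved in attributes.
    """
    text = _text_of(source)
    features: list[Feature] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        stripped = line.strip()
        if (
            not stripped
            or stripped.startswith("#")
            or stripped.startswith("track")
            or stripped.startswith("browser")
        ):
            continue
        cols = stripped.split()
        if len(cols) < 3:
            raise ValueError(f"BED line {lineno}: fewer than 3 columns")
        seq_id = cols[0]
        start, end = int(cols[1]), int(cols[2])
        name = cols[3] if len(cols) > 3 and cols[3] != "." else None
        score = (
            float(cols[4]) if len(cols) > 4 and cols[4] != "." else None
        )
        strand = _STRAND_FROM_TEXT.get(cols[5], 0) if len(cols) > 5 else 0
        feature = Feature(
            interval=GenomicInterval(seq_id, start, end, strand),
            type="region",
            name=name,
            score=score,
        )
        if len(cols) > 7:
            feature.attributes["thickStart"] = [cols[6]]
            feature.attributes["thickEnd"] = [cols[7]]
        if len(cols) > 8 and cols[8] not in (".", "0"):
            feature.attributes["itemRgb"] = [cols[8]]
        if len(cols) >= 12:
            block_count = int(cols[9])
            sizes = [int(x) for x in cols[10].rstrip(",").split(",") if x]
            starts = [int(x) for x in cols[11].rstrip(",").split(",") if x]
            if len(sizes) != block_count or len(starts) != block_count:
                raise ValueError(
                    f"BED line {lineno}: blockCount {block_count} does not match "
                    f"blockSizes/blockStarts arity ({len(sizes)}/{len(starts)})"
                )
            for bs, sz in zip(starts, sizes):
                feature.subfeatures.append(
                    Feature(
                        interval=GenomicInterval(
                            seq_id, start + bs, start + bs + sz, strand
                        ),
                        type="block",
                    )
                )
        features.append(feature)
    return features


def write_bed(features: list[Feature]) -> str:
    """Emit Features as BED: BED12 when subfeatures exist, else BED6."""
    lines = []
    for f in features:
        iv = f.interval
        base = [
            iv.seq_id,
            str(iv.start),
            str(iv.end),
            f.name if f.name is not None else ".",
            _format_score(f.score) if f.score is not None else "0",
            _STRAND_TO_TEXT[iv.strand],
        ]
        if f.subfeatures:
            blocks = sorted(_leaf_blocks(f), key=lambda b: b.start)
            thick_start = f.attributes.get("thickStart", [str(iv.start)])[0]
            thick_end = f.attributes.get("thickEnd", [str(iv.end)])[0]
            base += [
                thick_start,
                thick_end,
                f.attributes.get("itemRgb", ["0"])[0],
                str(len(blocks)),
                ",".join(str(b.length) for b in blocks) + ",",
                ",".join(str(b.start - iv.start) for b in blocks) + ",",
            ]
        lines.append("\t".join(base))
    return "\n".join(lines) + "\n"


def _leaf_blocks(feature: Feature):
    if not feature.subfeatures:
        return [feature.interval]
    blocks = []
    for sub in feature.subfeatures:
        blocks.extend(_leaf_blocks(sub))
    return blocks


def write_bedgraph(items) -> str:
    """Emit scored features or SignalIntervals in BedGraph (wiggle dialect).

    Every item must carry a score; a scoreless feature is a capability error
    since BedGraph has no missing-value representation.
    """
    lines = []
    for item in items:
        if isinstance(item, SignalInterval):
            iv, value = item.interval, item.value
        else:
            iv = item.interval
            if item.score is None:
                raise ValueError(
                    f"Wiggle export requires scores; feature at {iv.seq_id}:"
                    f"{iv.start}-{iv.end} has none"
                )
            value = item.score
        lines.append(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{_format_score(value)}")
    return "\n".join(lines) + "\n"


def read_bedgraph(source) -> list[SignalInterval]:
    text = _text_of(source)
    out = []
    for line in text.splitlines():
        stripped = line.strip()
        if not stripped or stripped.startswith(("#", "track", "browser")):
            continue
        seq_id, start, end, value = stripped.split()[:4]
        out.append(
            SignalInterval(GenomicInterval(seq_id, int(start), int(end)), float(value))
        )
    return out


def export_track(features: list[Feature], format: str) -> str:
    """Export a feature list in BED, GFF3 or Wiggle (BedGraph) format."""
    fmt = format.lower()
    if fmt == "gff3":
        return write_gff3(features)
    if fmt == "bed":
        return write_bed(features)
    if fmt in ("wiggle", "bedgraph", "wig"):
        return write_bedgraph(features)
    raise ValueError(f"unknown export format {format!r}")
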