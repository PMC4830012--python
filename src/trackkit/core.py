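"""Shared genomic data types and elementary interval algebra.

All coordinates throughout the toolkit are interbase: 0-based, half-open
``[start, end)``. Format readers and writers convert at the boundary (GFF3's
1-based inclusive convention is handled only there), so adjacent intervals
never share a base and zero-length intervals denote insertion points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "Feature",
    "RefSeqInfo",
    "SignalInterval",
    "overlaps",
    "contains",
    "normalize",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open interval on a named reference sequence.

    ``strand`` is +1 (forward), -1 (reverse) or 0 (unstranded); both '.' and
    '?' from annotation formats map to 0.
    """

    seq_id: str
    start: int
    end: int
    strand: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.seq_id}: "
                "need 0 <= start <= end"
            )
        if self.strand not in (-1, 0, 1):
            raise ValueError(f"strand must be -1, 0 or +1, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Feature:
    """A located, typed annotation with recursive subfeatures.

    Gene models arrive as gene -> mRNA -> exon trees; ``attributes`` holds
    multi-valued annotation key/values (GFF3 column 9 style). ``id`` must be
    unique within one track. ``source`` carries the GFF3 source column so
    round trips are faithful; formats without one leave it None.
    """

    interval: GenomicInterval
    type: str = "region"
    id: str | None = None
    name: str | None = None
    score: float | None = None
    phase: int | None = None
    source: str | None = None
    attributes: dict[str, list[str]] = field(default_factory=dict)
    subfeatures: list["Feature"] = field(default_factory=list)

    @property
    def seq_id(self) -> str:
        return self.interval.seq_id

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def strand(self) -> int:
        return self.interval.strand

    def walk(self):
        """Yield this feature and every descendant, depth first."""
        yield self
        for sub in self.subfeatures:
            yield from sub.walk()


@dataclass
class RefSeqInfo:
    """Name, length and aliases of one reference sequence."""

    name: str
    length: int
    aliases: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("reference sequence name must be nonempty")
        if self.length < 0:
            raise ValueError(f"negative length for {self.name}: {self.length}")


@dataclass(frozen=True)
class SignalInterval:
    """A constant numeric value over a genomic interval."""

    interval: GenomicInterval
    value: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError(f"signal value must be finite, got {self.value!r}")


def _check_same_seq(a: GenomicInterval, b: GenomicInterval) -> None:
    if a.seq_id != b.seq_id:
        raise ValueError(
            f"cannot compare intervals on different sequences: {a.seq_id!r} vs {b.seq_id!r}"
        )


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base.

    Adjacent intervals ([0,10) and [10,20)) do not overlap.
    """
    _check_same_seq(a, b)
    return a.start < b.end and b.start < a.end


def contains(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff ``b`` lies entirely within ``a`` (identity counts)."""
    _check_same_seq(a, b)
    return a.start <= b.start and b.end <= a.end


def normalize(intervals: list[GenomicInterval]) -> list[GenomicInterval]:
    """Merge a set of intervals into sorted, disjoint coverage.

    The result covers exactly the union of the input base positions;
    zero-length intervals contribute nothing and are dropped. Strand is not
    preserved (the footprint is strandless). All inputs must share a seq_id.
    """
    nonempty = [iv for iv in intervals if iv.length > 0]
    if not nonempty:
        return []
    seq_ids = {iv.seq_id for iv in nonempty}
    if len(seq_ids) > 1:
        raise ValueError(f"normalize requires a single seq_id, got {sorted(seq_ids)}")
    seq_id = nonempty[0].seq_id
    nonempty.sort(key=lambda iv: (iv.start, iv.end))
    merged: list[GenomicInterval] = []
    cur_start, cur_end = nonempty[0].start, nonempty[0].end
    for iv in nonempty[1:]:
        if iv.start <= cur_end:
            cur_end = max(cur_end, iv.end)
        else:
            merged.append(GenomicInterval(seq_id, cur_start, cur_end))
            cur_start, cur_end = iv.start, iv.end
    merged.append(GenomicInterval(seq_id, cur_start, cur_end))
    return merged
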