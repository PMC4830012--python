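"""Combination-track computations.

Set operations on feature-track *footprints* (the flattened, merged base
positions a track covers), arithmetic on piecewise-constant quantitative
signals, and coverage depth derived from a set of intervals. All operations
have per-base semantics: a base is in ``union(a, b)`` iff it is in ``a`` or
``b``, a signal operation evaluates ``op(a(x), b(x))`` at every base, and
coverage at ``x`` counts the intervals containing ``x``. Feature identity is
deliberately not preserved through set operations — flattening is the only
well-defined reading when gene models overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable

from .core import Feature, GenomicInterval, SignalInterval, normalize

__all__ = [
    "Footprint",
    "SignalTrack",
    "combine_features",
    "combine_signals",
    "feature_coverage",
    "TREAT_AS_ZERO",
    "PROPAGATE_MISSING",
]

TREAT_AS_ZERO = "treat-as-zero"
PROPAGATE_MISSING = "propagate-missing"

_SET_OPS = {
    "union": lambda a, b: a or b,
    "intersection": lambda a, b: a and b,
    "difference": lambda a, b: a and not b,
    "xor": lambda a, b: a != b,
}

_ARITH_OPS: dict[str, Callable[[float, float], float]] = {
    "add": lambda a, b: a + b,
    "subtract": lambda a, b: a - b,
    "multiply": lambda a, b: a * b,
    "divide": lambda a, b: a / b,
}

_DEFAULT_POLICY = {
    "add": TREAT_AS_ZERO,
    "subtract": TREAT_AS_ZERO,
    "multiply": PROPAGATE_MISSING,
    "divide": PROPAGATE_MISSING,
}


@dataclass
class Footprint:
    """Per-refseq normalized (sorted, disjoint, merged) interval lists."""

    intervals: dict[str, list[GenomicInterval]] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "Footprint":
        per_seq: dict[str, list[GenomicInterval]] = {}
        for iv in intervals:
            per_seq.setdefault(iv.seq_id, []).append(iv)
        return cls({seq: normalize(ivs) for seq, ivs in per_seq.items()})

    @classmethod
    def from_features(cls, features: Iterable[Feature]) -> "Footprint":
        return cls.from_intervals(f.interval for f in features)

    def seq_ids(self) -> list[str]:
        return sorted(self.intervals)

    def get(self, seq_id: str) -> list[GenomicInterval]:
        return self.intervals.get(seq_id, [])

    def to_features(self) -> list[Feature]:
        """Flattened intervals as unnamed Features of type 'region'."""
        return [
            Feature(interval=iv, type="region")
            for seq in self.seq_ids()
            for iv in self.intervals[seq]
        ]

    def __eq__(self, other) -> bool:
        if not isinstance(other, Footprint):
            return NotImplemented
        keys = {s for s, ivs in self.intervals.items() if ivs}
        other_keys = {s for s, ivs in other.intervals.items() if ivs}
        if keys != other_keys:
            return False
        return all(self.intervals[s] == other.intervals[s] for s in keys)


def combine_features(a: Footprint, b: Footprint, op: str) -> Footprint:
    """Set operation on two footprints: union, intersection, difference, xor."""
    try:
        predicate = _SET_OPS[op]
    except KeyError:
        raise ValueError(f"unknown set operation {op!r}") from None
    result: dict[str, list[GenomicInterval]] = {}
    for seq in sorted(set(a.intervals) | set(b.intervals)):
        result[seq] = _combine_one_seq(a.get(seq), b.get(seq), predicate, seq)
    return Footprint(result)


def _combine_one_seq(ivs_a, ivs_b, predicate, seq_id) -> list[GenomicInterval]:
    # sweep over the union of breakpoints; both inputs are normalized
    points = sorted(
        {p for iv in ivs_a for p in (iv.start, iv.end)}
        | {p for iv in ivs_b for p in (iv.start, iv.end)}
    )
    if not points:
        return []
    out: list[GenomicInterval] = []
    ia = ib = 0
    for lo, hi in zip(points, points[1:]):
        while ia < len(ivs_a) and ivs_a[ia].end <= lo:
            ia += 1
        while ib < len(ivs_b) and ivs_b[ib].end <= lo:
            ib += 1
        in_a = ia < len(ivs_a) and ivs_a[ia].start <= lo
        in_b = ib < len(ivs_b) and ivs_b[ib].start <= lo
        if predicate(in_a, in_b):
            out.append(GenomicInterval(seq_id, lo, hi))
    return normalize(out)


@dataclass
class SignalTrack:
    """Piecewise-constant signal: sorted, non-overlapping scored intervals.

    ``missing_policy`` controls what a combination does where only one
    operand has data: ``treat-as-zero`` substitutes 0, ``propagate-missing``
    leaves the region missing in the result.
    """

    intervals: dict[str, list[SignalInterval]] = field(default_factory=dict)

    @classmethod
    def from_signal_intervals(cls, items: Iterable[SignalInterval]) -> "SignalTrack":
        per_seq: dict[str, list[SignalInterval]] = {}
        for si in items:
            if si.interval.length > 0:
                per_seq.setdefault(si.interval.seq_id, []).append(si)
        track = cls()
        for seq, sis in per_seq.items():
            sis.sort(key=lambda s: (s.interval.start, s.interval.end))
            for prev, cur in zip(sis, sis[1:]):
                if cur.interval.start < prev.interval.end:
                    raise ValueError(
                        f"overlapping signal intervals on {seq} at {cur.interval.start}"
                    )
            track.intervals[seq] = _merge_runs(sis, seq)
        return track

    def seq_ids(self) -> list[str]:
        return sorted(self.intervals)

    def get(self, seq_id: str) -> list[SignalInterval]:
        return self.intervals.get(seq_id, [])

    def value_at(self, seq_id: str, pos: int) -> float | None:
        for si in self.get(seq_id):
            if si.interval.start <= pos < si.interval.end:
                return si.value
        return None

    def __eq__(self, other) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        keys = {s for s, v in self.intervals.items() if v}
        if keys != {s for s, v in other.intervals.items() if v}:
            return False
        return all(self.intervals[s] == other.intervals[s] for s in keys)


def _merge_runs(sis: list[SignalInterval], seq_id: str) -> list[SignalInterval]:
    """Merge adjacent intervals carrying equal values."""
    out: list[SignalInterval] = []
    for si in sis:
        if (
            out
            and out[-1].interval.end == si.interval.start
            and out[-1].value == si.value
        ):
            out[-1] = SignalInterval(
                GenomicInterval(seq_id, out[-1].interval.start, si.interval.end),
                si.value,
            )
        else:
            out.append(si)
    return out


def combine_signals(
    a: SignalTrack,
    b: SignalTrack,
    op: str,
    missing_policy: str | None = None,
) -> SignalTrack:
    """Pointwise arithmetic on two signals over the union of breakpoints.

    Division by zero yields a missing interval (dropped from the result), as
    does a missing operand under ``propagate-missing``.
    """
    try:
        fn = _ARITH_OPS[op]
    except KeyError:
        raise ValueError(f"unknown arithmetic operation {op!r}") from None
    policy = missing_policy if missing_policy is not None else _DEFAULT_POLICY[op]
    if policy not in (TREAT_AS_ZERO, PROPAGATE_MISSING):
        raise ValueError(f"unknown missing policy {policy!r}")
    result = SignalTrack()
    for seq in sorted(set(a.intervals) | set(b.intervals)):
        pieces: list[SignalInterval] = []
        points = sorted(
            {p for si in a.get(seq) for p in (si.interval.start, si.interval.end)}
            | {p for si in b.get(seq) for p in (si.interval.start, si.interval.end)}
        )
        sis_a, sis_b = a.get(seq), b.get(seq)
        ia = ib = 0
        for lo, hi in zip(points, points[1:]):
            while ia < len(sis_a) and sis_a[ia].interval.end <= lo:
                ia += 1
            while ib < len(sis_b) and sis_b[ib].interval.end <= lo:
                ib += 1
            va = sis_a[ia].value if ia < len(sis_a) and sis_a[ia].interval.start <= lo else None
            vb = sis_b[ib].value if ib < len(sis_b) and sis_b[ib].interval.start <= lo else None
            if va is None and vb is None:
                continue
            if policy == TREAT_AS_ZERO:
                va = 0.0 if va is None else va
                vb = 0.0 if vb is None else vb
            elif va is None or vb is None:
                continue
            if op == "divide" and vb == 0:
                continue
            pieces.append(
                SignalInterval(GenomicInterval(seq, lo, hi), float(fn(va, vb)))
            )
        merged = _merge_runs(pieces, seq)
        if merged:
            result.intervals[seq] = merged
    return result


def feature_coverage(
    items: Iterable[Feature | GenomicInterval],
    region: tuple[str, int, int] | None = None,
) -> SignalTrack:
    """Depth-of-coverage signal: value at base x = intervals containing x.

    Zero-depth runs are omitted; adjacent equal-depth runs are merged. With
    ``region`` = (seq, start, end), only that window is reported.
    """
    intervals = [
        it.interval if isinstance(it, Feature) else it for it in items
    ]
    if region is not None:
        seq, rstart, rend = region
        intervals = [
            GenomicInterval(seq, max(iv.start, rstart), min(iv.end, rend))
            for iv in intervals
            if iv.seq_id == seq and iv.start < rend and rstart < iv.end
        ]
    per_seq: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        if iv.length > 0:
            per_seq.setdefault(iv.seq_id, []).append(iv)
    track = SignalTrack()
    for seq, ivs in per_seq.items():
        events: dict[int, int] = {}
        for iv in ivs:
            events[iv.start] = events.get(iv.start, 0) + 1
            events[iv.end] = events.get(iv.end, 0) - 1
        depth = 0
        pieces: list[SignalInterval] = []
        points = sorted(events)
        for lo, hi in zip(points, points[1:]):
            depth_here = depth = depth + events[lo]
            if depth_here > 0:
                pieces.append(
                    SignalInterval(GenomicInterval(seq, lo, hi), float(depth_here))
                )
        track.intervals[seq] = _merge_runs(pieces, seq)
    return track
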