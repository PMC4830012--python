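"""Pileup and SNP-frequency computation from aligned reads.

Walks each read's CIGAR against the reference to accumulate per-position
base counts, deletions and insertion events; flags positions where a
non-reference base exceeds a configurable frequency threshold as *potential*
single-nucleotide variants. This is a screening summary, not a genotyper:
there are no likelihoods, no indel calls and no base-quality model.

Reads come either from coordinate-sorted SAM/BAM (via pysam) or from a plain
tab-separated format so everything is testable without binary files::

    seq_id  start(0-based)  cigar  bases  flags[, mapq]

``flags`` is the standard SAM flag integer; ``mapq`` defaults to 60.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pysam

from .core import GenomicInterval
from .refseq import RefSeqCatalog
from .trackops import SignalTrack, feature_coverage

__all__ = [
    "AlignedRead",
    "PileupColumn",
    "SnpCall",
    "ReadFilter",
    "read_tabular",
    "read_sam",
    "filter_reads",
    "pileup",
    "call_snps",
    "snp_coverage_track",
    "write_vcf",
    "DEFAULT_MIN_ALT_FREQUENCY",
    "DEFAULT_MIN_DEPTH",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_ALT_FREQUENCY = 0.2
DEFAULT_MIN_DEPTH = 5

_CIGAR_RE = re.compile(r"(\d+)([M=XIDNSHP])")
_QUERY_CONSUMING = set("M=XIS")
_REF_CONSUMING = set("M=XDN")

# SAM flag bits
_FLAG_PAIRED = 0x1
_FLAG_PROPER_PAIR = 0x2
_FLAG_UNMAPPED = 0x4
_FLAG_SECONDARY = 0x100
_FLAG_DUP = 0x400
_FLAG_SUPPLEMENTARY = 0x800


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    ops = [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]
    if not ops or "".join(f"{n}{op}" for op, n in ops) != cigar:
        raise ValueError(f"malformed CIGAR {cigar!r}")
    return ops


@dataclass
class AlignedRead:
    seq_id: str
    start: int  # 0-based leftmost reference position
    cigar: list[tuple[str, int]]
    bases: str
    mapq: int = 60
    flags: int = 0

    @property
    def is_unmapped(self) -> bool:
        return bool(self.flags & _FLAG_UNMAPPED)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & _FLAG_DUP)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flags & _FLAG_SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flags & _FLAG_SUPPLEMENTARY)

    @property
    def is_paired(self) -> bool:
        return bool(self.flags & _FLAG_PAIRED)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flags & _FLAG_PROPER_PAIR)

    def query_length(self) -> int:
        return sum(n for op, n in self.cigar if op in _QUERY_CONSUMING)

    def reference_span(self) -> GenomicInterval:
        ref_len = sum(n for op, n in self.cigar if op in _REF_CONSUMING)
        return GenomicInterval(self.seq_id, self.start, self.start + ref_len)

    def validate(self) -> None:
        if self.query_length() != len(self.bases):
            raise ValueError(
                f"CIGAR consumes {self.query_length()} query bases but read has "
                f"{len(self.bases)}"
            )


@dataclass
class PileupColumn:
    """Per-position tally. Invariant: depth = sum(counts) + deletions."""

    position: int
    ref_base: str | None = None
    counts: dict[str, int] = field(default_factory=dict)
    deletions: int = 0
    insertions_following: int = 0

    @property
    def depth(self) -> int:
        return sum(self.counts.values()) + self.deletions


@dataclass(frozen=True)
class SnpCall:
    position: int
    ref_base: str
    alt_base: str
    alt_frequency: float  # fraction of non-deletion depth
    depth: int


@dataclass(frozen=True)
class ReadFilter:
    """Which reads enter the pileup; unmapped reads are always dropped."""

    drop_duplicates: bool = True
    drop_secondary_and_supplementary: bool = True
    require_proper_pair: bool = False
    min_mapq: int = 0


def read_tabular(source) -> list[AlignedRead]:
    """Parse the documented tab-separated read format."""
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    reads = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 5:
            raise ValueError(f"reads line {lineno}: expected at least 5 columns")
        reads.append(
            AlignedRead(
                seq_id=cols[0],
                start=int(cols[1]),
                cigar=parse_cigar(cols[2]),
                bases=cols[3],
                flags=int(cols[4]),
                mapq=int(cols[5]) if len(cols) > 5 else 60,
            )
        )
    return reads


def write_tabular(reads: list[AlignedRead], header_comment: str | None = None) -> str:
    lines = [f"# {header_comment}"] if header_comment else []
    for r in reads:
        cigar = "".join(f"{n}{op}" for op, n in r.cigar)
        lines.append(
            "\t".join([r.seq_id, str(r.start), cigar, r.bases, str(r.flags), str(r.mapq)])
        )
    return "\n".join(lines) + "\n"


def read_sam(path: str | Path, region: tuple[str, int, int] | None = None) -> list[AlignedRead]:
    """Read alignments from SAM/BAM via pysam (sequential scan for SAM)."""
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.cigartuples is None:
                continue
            seq_id = aln.reference_name
            if region is not None:
                rseq, rstart, rend = region
                if seq_id != rseq or aln.reference_start >= rend or aln.reference_end <= rstart:
                    continue
            cigar = [
                ("MIDNSHP=X"[op], length) for op, length in aln.cigartuples
            ]
            reads.append(
                AlignedRead(
                    seq_id=seq_id,
                    start=aln.reference_start,
                    cigar=cigar,
                    bases=aln.query_sequence or "",
                    mapq=aln.mapping_quality,
                    flags=aln.flag,
                )
            )
    return reads


def filter_reads(reads: list[AlignedRead], policy: ReadFilter | None = None) -> list[AlignedRead]:
    """Drop reads failing any enabled criterion; unmapped always dropped."""
    if policy is None:
        policy = ReadFilter()
    out = []
    for r in reads:
        if r.is_unmapped:
            continue
        if policy.drop_duplicates and r.is_duplicate:
            continue
        if policy.drop_secondary_and_supplementary and (
            r.is_secondary or r.is_supplementary
        ):
            continue
        if policy.require_proper_pair and not r.is_proper_pair:
            continue
        if r.mapq < policy.min_mapq:
            continue
        out.append(r)
    return out


def pileup(
    reads: list[AlignedRead],
    catalog: RefSeqCatalog | None,
    region: tuple[str, int, int],
) -> list[PileupColumn]:
    """One PileupColumn per reference position in ``region`` with depth > 0.

    CIGAR semantics: M/=/X consume read and reference and contribute base
    counts; D consumes reference and increments ``deletions``; N consumes
    reference silently; I increments ``insertions_following`` of the
    preceding column; S/H contribute nothing. Reads whose CIGAR disagrees
    with their base string are skipped with a warning.
    """
    seq_name, rstart, rend = region
    ref = None
    if catalog is not None and catalog.has_sequence:
        ref = catalog.get_sequence(seq_name, rstart, rend)
    columns: dict[int, PileupColumn] = {}

    def col(pos: int) -> PileupColumn:
        c = columns.get(pos)
        if c is None:
            c = PileupColumn(
                position=pos,
                ref_base=ref[pos - rstart] if ref is not None else None,
            )
            columns[pos] = c
        return c

    for read in reads:
        if read.seq_id != seq_name:
            continue
        try:
            read.validate()
        except ValueError as exc:
            logger.warning("skipping read at %s:%d: %s", read.seq_id, read.start, exc)
            continue
        ref_pos = read.start
        query_pos = 0
        for op, n in read.cigar:
            if op in "M=X":
                for i in range(n):
                    p = ref_pos + i
                    if rstart <= p < rend:
                        base = read.bases[query_pos + i].upper()
                        if base not in "ACGTN":
                            base = "N"
                        c = col(p)
                        c.counts[base] = c.counts.get(base, 0) + 1
                ref_pos += n
                query_pos += n
            elif op == "D":
                for i in range(n):
                    p = ref_pos + i
                    if rstart <= p < rend:
                        col(p).deletions += 1
                ref_pos += n
            elif op == "N":
                ref_pos += n
            elif op == "I":
                prev = ref_pos - 1
                if rstart <= prev < rend:
                    col(prev).insertions_following += 1
                query_pos += n
            elif op == "S":
                query_pos += n
            # H and P consume nothing tracked here
    return [columns[p] for p in sorted(columns)]


def call_snps(
    columns: list[PileupColumn],
    min_alt_frequency: float = DEFAULT_MIN_ALT_FREQUENCY,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> list[SnpCall]:
    """Flag non-reference bases exceeding the frequency threshold.

    The frequency denominator is the non-deletion depth, so indel evidence
    does not dilute substitutions; N never calls as an alternate.
    """
    calls: list[SnpCall] = []
    for column in columns:
        if column.ref_base is None:
            raise ValueError("SNP calling requires reference bases in the pileup")
        if column.depth < min_depth:
            continue
        base_depth = sum(column.counts.values())
        if base_depth == 0:
            continue
        ref = column.ref_base.upper()
        for base in sorted(column.counts):
            if base in (ref, "N"):
                continue
            freq = column.counts[base] / base_depth
            if freq >= min_alt_frequency:
                calls.append(
                    SnpCall(
                        position=column.position,
                        ref_base=ref,
                        alt_base=base,
                        alt_frequency=freq,
                        depth=column.depth,
                    )
                )
    calls.sort(key=lambda c: (c.position, c.alt_base))
    return calls


def snp_coverage_track(
    reads: list[AlignedRead],
    catalog: RefSeqCatalog | None,
    region: tuple[str, int, int],
    policy: ReadFilter | None = None,
    min_alt_frequency: float = DEFAULT_MIN_ALT_FREQUENCY,
    min_depth: int = DEFAULT_MIN_DEPTH,
) -> tuple[SignalTrack, list[SnpCall]]:
    """Coverage histogram plus potential SNPs: filter → pileup → summarize.

    The depth component equals ``feature_coverage`` of the filtered reads'
    reference spans restricted to the region.
    """
    kept = filter_reads(reads, policy)
    seq_name, rstart, rend = region
    kept = [
        r
        for r in kept
        if r.seq_id == seq_name and r.start < rend and r.reference_span().end > rstart
    ]
    columns = pileup(kept, catalog, region)
    depth = feature_coverage(
        (r.reference_span() for r in kept), region=region
    )
    if catalog is not None and catalog.has_sequence:
        calls = call_snps(columns, min_alt_frequency, min_depth)
    else:
        calls = []
    return depth, calls


def write_vcf(calls: list[SnpCall], seq_name: str) -> str:
    """Minimal VCF: CHROM, 1-based POS, REF, ALT, INFO DP and AF."""
    lines = [
        "##fileformat=VCFv4.2",
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
        '##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for c in calls:
        lines.append(
            f"{seq_name}\t{c.position + 1}\t.\t{c.ref_base}\t{c.alt_base}\t.\t.\t"
            f"DP={c.depth};AF={c.alt_frequency:.4f}"
        )
    return "\n".join(lines) + "\n"
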