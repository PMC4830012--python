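"""Seeded synthetic-data generators for every input the toolkit consumes.

A :class:`FixtureSpec` pins a single pseudo-random stream, so an identical
spec yields byte-identical artifacts (the seed is written into each file's
header). The generators emulate the shapes that stress this toolkit —
nested gene models for containment lists, shared name prefixes for
autocomplete, reads with spiked variants for the pileup — not realistic
biology: there are no error models, quality strings, or paired-end reads.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass

from .alignments import AlignedRead, write_tabular
from .core import GenomicInterval

__all__ = [
    "FixtureSpec",
    "make_genome",
    "make_annotations",
    "make_signal",
    "make_reads",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset; identical specs are bytewise
    reproducible."""

    seed: int = 0
    n_refseqs: int = 2
    refseq_length: int = 100_000
    n_genes: int = 100
    exons_per_gene: tuple[int, int] = (2, 5)
    read_length: int = 100
    read_depth: int = 20
    # (position, alt frequency) on the first refseq
    variants: tuple[tuple[int, float], ...] = ()
    name_prefixes: tuple[str, ...] = ("gene", "scaf", "orf")

    def refseq_names(self) -> list[str]:
        return [f"ctg{i + 1:02d}" for i in range(self.n_refseqs)]


def _rng(spec: FixtureSpec, stream: str) -> random.Random:
    return random.Random(f"{spec.seed}:{stream}")


def make_genome(spec: FixtureSpec) -> str:
    """FASTA text: uniform-ACGT sequences, 70-column wrapped."""
    rng = _rng(spec, "genome")
    out = []
    for name in spec.refseq_names():
        out.append(f">{name} synthetic seed={spec.seed}")
        seq = "".join(rng.choice(_BASES) for _ in range(spec.refseq_length))
        for i in range(0, len(seq), 70):
            out.append(seq[i : i + 70])
    return "\n".join(out) + "\n"


def genome_sequences(spec: FixtureSpec) -> dict[str, str]:
    """The same sequences make_genome writes, as plain strings."""
    rng = _rng(spec, "genome")
    return {
        name: "".join(rng.choice(_BASES) for _ in range(spec.refseq_length))
        for name in spec.refseq_names()
    }


def make_annotations(spec: FixtureSpec) -> tuple[str, dict]:
    """GFF3 of nested gene models plus a ground-truth manifest.

    Each gene is gene -> mRNA -> exon/UTR (nesting depth >= 2 to stress the
    containment list); names share prefixes (autocomplete stress) and every
    third gene carries an Alias. The manifest lists every top-level feature
    with its span and name.
    """
    rng = _rng(spec, "annot")
    lines = ["##gff-version 3", f"# synthetic fixture seed={spec.seed}"]
    manifest: dict = {"seed": spec.seed, "genes": []}
    names = spec.refseq_names()
    lo, hi = spec.exons_per_gene
    for g in range(spec.n_genes):
        seq = names[g % len(names)]
        prefix = spec.name_prefixes[g % len(spec.name_prefixes)]
        name = f"{prefix}{g + 1:04d}"
        gid = f"g{g + 1}"
        n_exons = rng.randint(lo, hi)
        exon_len = rng.randint(50, 300)
        intron_len = rng.randint(20, 200)
        body = n_exons * exon_len + (n_exons - 1) * intron_len
        utr = rng.randint(10, 100)
        gene_len = body + 2 * utr
        start = rng.randrange(0, max(1, spec.refseq_length - gene_len))
        strand = rng.choice("+-")
        gene_start, gene_end = start, start + gene_len
        lines.append(
            f"{seq}\tfixture\tgene\t{gene_start + 1}\t{gene_end}\t.\t{strand}\t.\t"
            + f"ID={gid};Name={name}"
            + (f";Alias={name}-alias" if g % 3 == 0 else "")
        )
        mid = f"{gid}.t1"
        lines.append(
            f"{seq}\tfixture\tmRNA\t{gene_start + utr + 1}\t{gene_end - utr}\t.\t{strand}\t.\t"
            f"ID={mid};Parent={gid};Name={name}.t1"
        )
        exon_start = gene_start + utr
        for e in range(n_exons):
            exon_end = exon_start + exon_len
            lines.append(
                f"{seq}\tfixture\texon\t{exon_start + 1}\t{exon_end}\t.\t{strand}\t.\t"
                f"ID={mid}.e{e + 1};Parent={mid}"
            )
            exon_start = exon_end + intron_len
        manifest["genes"].append(
            {
                "id": gid,
                "name": name,
                "seq_id": seq,
                "start": gene_start,
                "end": gene_end,
                "strand": 1 if strand == "+" else -1,
                "n_exons": n_exons,
                "alias": f"{name}-alias" if g % 3 == 0 else None,
            }
        )
    return "\n".join(lines) + "\n", manifest


def make_signal(spec: FixtureSpec, n_intervals: int = 200) -> str:
    """BedGraph of random non-overlapping scored runs."""
    rng = _rng(spec, "signal")
    lines = [f"# synthetic fixture seed={spec.seed}"]
    for seq in spec.refseq_names():
        pos = 0
        for _ in range(n_intervals):
            pos += rng.randint(0, 400)
            width = rng.randint(50, 500)
            if pos + width > spec.refseq_length:
                break
            value = round(rng.uniform(0, 100), 2)
            lines.append(f"{seq}\t{pos}\t{pos + width}\t{value}")
            pos += width
    return "\n".join(lines) + "\n"


def make_reads(
    spec: FixtureSpec,
    genome: dict[str, str] | None = None,
    region: tuple[str, int, int] | None = None,
) -> tuple[str, dict]:
    """Tabular reads at the spec's depth with variants spiked in.

    Reads are error-free copies of the reference except at the spec's
    variant positions, where the alternate base is substituted in a
    deterministic fraction of the covering reads (systematic thinning), so
    the realized alternate frequency equals the spiked frequency to within
    1/depth and the ground-truth manifest states the true value rather than
    a sampling target. Returns the tabular text plus that manifest
    (position, ref, alt, frequency).
    """
    if genome is None:
        genome = genome_sequences(spec)
    rng = _rng(spec, "reads")
    if region is None:
        seq_name = spec.refseq_names()[0]
        region = (seq_name, 0, len(genome[seq_name]))
    seq_name, rstart, rend = region
    reference = genome[seq_name]
    n_reads = max(1, (rend - rstart) * spec.read_depth // spec.read_length)
    variant_plan = []
    for pos, freq in spec.variants:
        ref_base = reference[pos]
        alt_base = rng.choice([b for b in _BASES if b != ref_base])
        variant_plan.append({"pos": pos, "ref": ref_base, "alt": alt_base, "freq": freq})
    reads: list[AlignedRead] = []
    spike_acc = {v["pos"]: 0.0 for v in variant_plan}
    for _ in range(n_reads):
        start = rng.randrange(rstart, max(rstart + 1, rend - spec.read_length))
        bases = list(reference[start : start + spec.read_length])
        for v in variant_plan:
            offset = v["pos"] - start
            if 0 <= offset < len(bases):
                spike_acc[v["pos"]] += v["freq"]
                if spike_acc[v["pos"]] >= 1.0:
                    spike_acc[v["pos"]] -= 1.0
                    bases[offset] = v["alt"]
        reads.append(
            AlignedRead(
                seq_id=seq_name,
                start=start,
                cigar=[("M", len(bases))],
                bases="".join(bases),
                mapq=60,
                flags=0,
            )
        )
    reads.sort(key=lambda r: r.start)
    text = write_tabular(reads, header_comment=f"synthetic fixture seed={spec.seed}")
    manifest = {"seed": spec.seed, "region": list(region), "variants": variant_plan}
    return text, manifest


def make_random_intervals(
    rng: random.Random,
    n: int,
    seq_id: str = "ctg01",
    span: int = 10_000,
    max_len: int = 500,
    nested_fraction: float = 0.3,
) -> list[GenomicInterval]:
    """Random, frequently-nested intervals for index stress tests."""
    out: list[GenomicInterval] = []
    for _ in range(n):
        if out and rng.random() < nested_fraction:
            parent = rng.choice(out)
            if parent.length > 2:
                start = rng.randrange(parent.start, parent.end - 1)
                end = rng.randrange(start + 1, parent.end + 1)
                out.append(GenomicInterval(seq_id, start, end))
                continue
        start = rng.randrange(0, span - 1)
        end = min(span, start + rng.randint(1, max_len))
        out.append(GenomicInterval(seq_id, start, end))
    return out


def write_manifest(manifest: dict) -> str:
    return json.dumps(manifest, sort_keys=True, indent=1) + "\n"
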