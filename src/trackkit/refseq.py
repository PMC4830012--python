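"""Chunked reference-sequence store and sequence utilities.

Importing a FASTA file breaks each sequence into fixed-size residue chunks on
disk so that arbitrary subsequences can be served by reading only the chunks
that overlap the request — the store a plain web server could host. A
sizes-only catalog (chromosome name/length table) supports the same metadata
queries without sequence.

Layout under a dataset directory::

    <root>/seq/refs.json          catalog: name, length, aliases, chunk_size
    <root>/seq/<name>/<k>.txt[.gz]  residues of chunk k

Chunk ``k`` covers bases ``[k*chunk_size, min((k+1)*chunk_size, length))``.
Residues are stored exactly as given (soft-masking case is information).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Data import CodonTable as _BioCodonTable

from .core import RefSeqInfo

__all__ = [
    "DEFAULT_CHUNK_SIZE",
    "CodonTable",
    "STANDARD_CODE",
    "RefSeqCatalog",
    "import_fasta",
    "import_sizes",
    "get_sequence",
    "reverse_complement",
    "translate",
    "sort_refseqs",
]

DEFAULT_CHUNK_SIZE = 20_000

_BASES = "ACGT"

# IUPAC nucleotide complements; case preserved, anything else becomes N/n.
_COMPLEMENT = {
    "A": "T", "T": "A", "G": "C", "C": "G", "U": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}
_COMPLEMENT.update({k.lower(): v.lower() for k, v in _COMPLEMENT.items()})


@dataclass
class CodonTable:
    """Total mapping from the 64 {A,C,G,T} codons to amino-acid letters."""

    codons: dict[str, str]
    start_codons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = {a + b + c for a in _BASES for b in _BASES for c in _BASES}
        if set(self.codons) != expected:
            missing = sorted(expected - set(self.codons))[:5]
            raise ValueError(f"codon table must cover all 64 codons; missing e.g. {missing}")


def _standard_code() -> CodonTable:
    bio = _BioCodonTable.unambiguous_dna_by_id[1]
    codons = dict(bio.forward_table)
    for stop in bio.stop_codons:
        codons[stop] = "*"
    return CodonTable(codons=codons, start_codons=list(bio.start_codons))


STANDARD_CODE = _standard_code()


class RefSeqCatalog:
    """Reference-sequence metadata plus (optionally) chunked residues on disk."""

    def __init__(
        self,
        entries: list[RefSeqInfo],
        *,
        root: Path | None = None,
        chunk_size: int = DEFAULT_CHUNK_SIZE,
        has_sequence: bool = False,
        compress: bool = False,
    ):
        self.entries = entries
        self.root = Path(root) if root is not None else None
        self.chunk_size = chunk_size
        self.has_sequence = has_sequence
        self.compress = compress
        self._by_name = {e.name: e for e in entries}
        if len(self._by_name) != len(entries):
            raise ValueError("duplicate reference sequence names in catalog")

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __iter__(self):
        return iter(self.entries)

    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def entry(self, name: str) -> RefSeqInfo:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown reference sequence {name!r}") from None

    def length(self, name: str) -> int:
        return self.entry(name).length

    # -- chunk file access -------------------------------------------------

    def _chunk_path(self, seq_name: str, k: int) -> Path:
        assert self.root is not None
        base = self.root / "seq" / seq_name / f"{k}.txt"
        return base.with_suffix(".txt.gz") if self.compress else base

    def _read_chunk(self, seq_name: str, k: int) -> str:
        path = self._chunk_path(seq_name, k)
        if self.compress:
            with gzip.open(path, "rt") as fh:
                return fh.read()
        return path.read_text()

    def get_sequence(self, seq_name: str, start: int, end: int) -> str:
        """Residues of ``[start, end)``, stitched across chunk boundaries.

        Only chunks overlapping the request are read from disk.
        """
        if not self.has_sequence:
            raise ValueError("catalog was built from a sizes table and holds no sequence")
        length = self.length(seq_name)
        if not (0 <= start <= end <= length):
            raise IndexError(
                f"range [{start}, {end}) out of bounds for {seq_name} (length {length})"
            )
        if start == end:
            return ""
        cs = self.chunk_size
        first, last = start // cs, (end - 1) // cs
        parts = []
        for k in range(first, last + 1):
            chunk = self._read_chunk(seq_name, k)
            lo = max(start - k * cs, 0)
            hi = min(end - k * cs, len(chunk))
            parts.append(chunk[lo:hi])
        return "".join(parts)

    def save_metadata(self) -> Path:
        assert self.root is not None
        seq_dir = self.root / "seq"
        seq_dir.mkdir(parents=True, exist_ok=True)
        meta = {
            "has_sequence": self.has_sequence,
            "chunk_size": self.chunk_size,
            "compress": self.compress,
            "refseqs": [
                {"name": e.name, "length": e.length, "aliases": e.aliases}
                for e in self.entries
            ],
        }
        path = seq_dir / "refs.json"
        path.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
        return path

    @classmethod
    def load(cls, root: str | Path) -> "RefSeqCatalog":
        root = Path(root)
        meta = json.loads((root / "seq" / "refs.json").read_text())
        entries = [
            RefSeqInfo(r["name"], r["length"], list(r.get("aliases", ())))
            for r in meta["refseqs"]
        ]
        return cls(
            entries,
            root=root,
            chunk_size=meta["chunk_size"],
            has_sequence=meta["has_sequence"],
            compress=meta.get("compress", False),
        )


def import_fasta(
    fasta_source,
    out_dir: str | Path,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    compress: bool = False,
) -> RefSeqCatalog:
    """Index a FASTA file into a chunked store under ``out_dir``.

    Sequence names are the first whitespace-delimited token of each header.
    Residues are written verbatim (whitespace stripped, no validation, case
    preserved). Duplicate names and empty inputs are errors.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    out_dir = Path(out_dir)
    entries: list[RefSeqInfo] = []
    seen: set[str] = set()
    catalog = RefSeqCatalog(
        [], root=out_dir, chunk_size=chunk_size, has_sequence=True, compress=compress
    )
    for record in SeqIO.parse(fasta_source, "fasta"):
        name = record.id
        if name in seen:
            raise ValueError(f"duplicate sequence name in FASTA: {name!r}")
        seen.add(name)
        residues = str(record.seq)
        seq_dir = out_dir / "seq" / name
        seq_dir.mkdir(parents=True, exist_ok=True)
        for k in range(0, max(1, -(-len(residues) // chunk_size))):
            piece = residues[k * chunk_size : (k + 1) * chunk_size]
            if not piece and k > 0:
                break
            path = catalog._chunk_path(name, k)
            if compress:
                # mtime=0 for byte-stable output across runs
                with open(path, "wb") as raw, gzip.GzipFile(
                    fileobj=raw, mode="wb", mtime=0
                ) as fh:
                    fh.write(piece.encode())
            else:
                path.write_text(piece)
        entries.append(RefSeqInfo(name, len(residues)))
    if not entries:
        raise ValueError("FASTA input contains no sequences")
    catalog.entries = entries
    catalog._by_name = {e.name: e for e in entries}
    catalog.save_metadata()
    return catalog


def import_sizes(sizes_source, out_dir: str | Path | None = None) -> RefSeqCatalog:
    """Build a sizes-only catalog from a two-column name/length table."""
    if isinstance(sizes_source, (str, Path)):
        text = Path(sizes_source).read_text()
    else:
        text = sizes_source.read()
    entries: list[RefSeqInfo] = []
    seen: set[str] = set()
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 2:
            raise ValueError(f"sizes line {lineno}: expected 'name length', got {line!r}")
        name, length_s = fields[0], fields[1]
        if name in seen:
            raise ValueError(f"sizes line {lineno}: duplicate name {name!r}")
        seen.add(name)
        length = int(length_s)
        if length < 0:
            raise ValueError(f"sizes line {lineno}: negative length for {name!r}")
        entries.append(RefSeqInfo(name, length))
    catalog = RefSeqCatalog(entries, root=out_dir, has_sequence=False)
    if out_dir is not None:
        catalog.save_metadata()
    return catalog


def get_sequence(catalog: RefSeqCatalog, seq_name: str, start: int, end: int) -> str:
    return catalog.get_sequence(seq_name, start, end)


def reverse_complement(residues: str) -> str:
    """Reverse complement with IUPAC ambiguity support and case preserved.

    Characters outside the IUPAC alphabet complement to N (n if lowercase).
    """
    out = []
    for c in reversed(residues):
        comp = _COMPLEMENT.get(c)
        if comp is None:
            comp = "n" if c.islower() else "N"
        out.append(comp)
    return "".join(out)


def translate(
    residues: str,
    frame: int = 0,
    strand: int = 1,
    table: CodonTable | None = None,
) -> str:
    """Conceptual translation of one of the six reading frames.

    ``frame`` is the 0-based offset into the strand-adjusted sequence; a
    trailing partial codon is dropped. Stop codons render ``*``; codons with
    ambiguous or unknown residues render ``X``.
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    if strand not in (1, -1):
        raise ValueError("strand must be +1 or -1")
    if table is None:
        table = STANDARD_CODE
    seq = reverse_complement(residues) if strand == -1 else residues
    seq = seq.upper()
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(table.codons.get(seq[i : i + 3], "X"))
    return "".join(out)


def sort_refseqs(
    catalog: RefSeqCatalog | Iterable[RefSeqInfo],
    mode: str = "name_asc",
    custom_order: list[str] | None = None,
) -> list[RefSeqInfo]:
    """Order reference sequences for display.

    Modes: ``name_asc``, ``name_desc``, ``length_desc``, or ``custom`` with an
    explicit name list; names missing from a custom order are appended in
    alphabetical order. Sorting is stable.
    """
    entries = list(catalog.entries if isinstance(catalog, RefSeqCatalog) else catalog)
    if mode == "name_asc":
        return sorted(entries, key=lambda e: e.name)
    if mode == "name_desc":
        return sorted(entries, key=lambda e: e.name, reverse=True)
    if mode == "length_desc":
        return sorted(entries, key=lambda e: -e.length)
    if mode == "custom":
        if custom_order is None:
            raise ValueError("custom mode requires an explicit name ordering")
        rank = {name: i for i, name in enumerate(custom_order)}
        listed = sorted(
            (e for e in entries if e.name in rank), key=lambda e: rank[e.name]
        )
        rest = sorted((e for e in entries if e.name not in rank), key=lambda e: e.name)
        return listed + rest
    raise ValueError(f"unknown sort mode {mode!r}")
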