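"""Motif and regular-expression search over reference sequences.

Scans both strands of a chunked sequence store and reports every match as a
Feature of type ``match``. The scan is all-offsets: at each start position
the leftmost match beginning there is reported, so overlapping occurrences
are all found. The reverse strand is handled by scanning the reverse
complement and mapping a hit at reverse offset r of length L back to the
forward interval [length - r - L, length - r) with strand -1.

To stay sound over lazily-loaded chunks, matches are bounded by a
configurable maximum length (default 500) and scanning windows overlap by
max_match_length - 1 bases, so a hit spanning a chunk edge is always inside
some window.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .core import Feature, GenomicInterval
from .refseq import RefSeqCatalog, reverse_complement

__all__ = ["SearchQuery", "search", "DEFAULT_MAX_MATCH_LENGTH", "iupac_to_regex"]

DEFAULT_MAX_MATCH_LENGTH = 500

_WINDOW = 20_000

# IUPAC nucleotide codes as character classes for plain-motif queries
_IUPAC_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGTN]",
}


def iupac_to_regex(motif: str) -> str:
    """Expand IUPAC ambiguity letters in a plain motif to character classes."""
    out = []
    for c in motif:
        cls = _IUPAC_CLASS.get(c.upper())
        if cls is None:
            raise ValueError(f"motif contains non-IUPAC character {c!r}")
        out.append(cls)
    return "".join(out)


@dataclass
class SearchQuery:
    """What to search for and where.

    With ``is_regex`` false (the default) the pattern is a plain nucleotide
    motif whose IUPAC ambiguity letters expand to character classes; with it
    true the pattern is compiled verbatim as a Python regular expression.
    """

    pattern: str
    is_regex: bool = False
    case_sensitive: bool = False
    both_strands: bool = True
    refseqs: list[str] | None = None  # None = all
    max_match_length: int = DEFAULT_MAX_MATCH_LENGTH

    def compile(self) -> re.Pattern:
        pattern = self.pattern if self.is_regex else iupac_to_regex(self.pattern)
        flags = 0 if self.case_sensitive else re.IGNORECASE
        try:
            return re.compile(pattern, flags)
        except re.error as exc:
            raise ValueError(f"pattern does not compile: {exc}") from exc


def _scan(fetch, length: int, pattern: re.Pattern, max_len: int):
    """Yield (offset, text) for the leftmost match starting at each offset.

    ``fetch(start, end)`` returns residues; windows overlap by max_len - 1 so
    chunk-spanning matches are found without materializing the sequence.
    """
    step = max(_WINDOW, max_len)
    for window_start in range(0, max(length, 1), step):
        window_end = min(window_start + step + max_len - 1, length)
        window = fetch(window_start, window_end)
        limit = min(step, len(window))
        for pos in range(limit):
            m = pattern.match(window, pos)
            if m is None or m.start() != pos:
                continue
            text = m.group(0)
            if not text:
                continue  # ignore empty matches
            if len(text) > max_len:
                text = text[:max_len]  # bounded-match contract
            if pos + len(text) <= len(window) or window_end == length:
                yield window_start + pos, text
        if window_end >= length:
            break


def search(catalog: RefSeqCatalog, query: SearchQuery) -> list[Feature]:
    """Scan the catalog for the query; results sorted by (seq, start, strand)."""
    if not catalog.has_sequence:
        raise ValueError("sequence search requires a catalog with sequence data")
    pattern = query.compile()
    names = query.refseqs if query.refseqs is not None else catalog.names()
    hits: list[Feature] = []
    for name in names:
        length = catalog.length(name)

        def fwd_fetch(a, b, _name=name):
            return catalog.get_sequence(_name, a, b)

        for offset, text in _scan(fwd_fetch, length, pattern, query.max_match_length):
            hits.append(_match_feature(name, offset, text, 1))
        if query.both_strands:

            def rev_fetch(a, b, _name=name, _len=length):
                return reverse_complement(catalog.get_sequence(_name, _len - b, _len - a))

            for r, text in _scan(rev_fetch, length, pattern, query.max_match_length):
                start = length - r - len(text)
                hits.append(_match_feature(name, start, text, -1))
    hits.sort(key=lambda f: (f.seq_id, f.start, f.strand))
    return hits


def _match_feature(seq_name: str, start: int, text: str, strand: int) -> Feature:
    return Feature(
        interval=GenomicInterval(seq_name, start, start + len(text), strand),
        type="match",
        attributes={"match": [text]},
    )
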