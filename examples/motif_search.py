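"""Scan a reference store for a motif on both strands.

Plain motifs expand IUPAC ambiguity codes (TATAWA matches TATAAA and
TATATA); matching is all-offsets, so overlapping occurrences are all
reported, and reverse-strand hits are mapped back to forward coordinates.
"""

import io
import tempfile

from trackkit import fixtures
from trackkit.refseq import import_fasta
from trackkit.search import SearchQuery, search

spec = fixtures.FixtureSpec(seed=8, n_refseqs=1, refseq_length=10_000)

with tempfile.TemporaryDirectory() as tmp:
    catalog = import_fasta(io.StringIO(fixtures.make_genome(spec)), tmp, 2_000)

    hits = search(catalog, SearchQuery("TATAWA"))  # W = A or T
    print(f"TATAWA sites in 10 kb: {len(hits)}")
    for f in hits[:5]:
        strand = "+" if f.strand == 1 else "-"
        print(f"  {f.seq_id}:{f.start}-{f.end} ({strand}) {f.attributes['match'][0]}")

    # full regular expressions work too (taken verbatim, not IUPAC-expanded)
    runs = search(catalog, SearchQuery("A{6,}", is_regex=True, both_strands=False))
    print(f"poly-A runs of >= 6: {len(runs)}")
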