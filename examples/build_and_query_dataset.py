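"""Build a complete dataset directory from synthetic inputs and query it.

Mirrors the classic static-site workflow: chunk the reference sequences,
index a GFF3 file as a lazily-loadable track, build the name index, then
answer a range query and an autocomplete request from the files alone.
"""

import tempfile
from pathlib import Path

from trackkit import fixtures, names, nclist, refseq
from trackkit.features import read_gff3

spec = fixtures.FixtureSpec(seed=1, n_refseqs=1, refseq_length=20_000, n_genes=25)

with tempfile.TemporaryDirectory() as tmp:
    data = Path(tmp) / "data"

    # 1. prepare-refseqs: chunk the genome
    fasta = Path(tmp) / "genome.fa"
    fasta.write_text(fixtures.make_genome(spec))
    catalog = refseq.import_fasta(fasta, data, chunk_size=5_000)
    print(f"indexed {len(catalog.entries)} refseq(s), "
          f"{catalog.length('ctg01')} bases in 5 kb chunks")

    # 2. flatfile-to-json: index the annotations as a track
    gff, manifest = fixtures.make_annotations(spec)
    feats = read_gff3(gff)
    track = nclist.MemoryTrack("genes", feats, {"ctg01": 20_000})
    nclist.serialize_track(track, data, chunk_feature_limit=10)

    # 3. generate-names: radix-tree index over names, aliases, refseqs
    records = names.records_from_features(feats, "genes")
    index = names.build_name_index(records, refseqs=catalog.entries)
    index.save(data)

    # Query side: everything below reads only the serialized files.
    lazy = nclist.load_track(data / "tracks" / "genes")
    hits = lazy.query("ctg01", 0, 5_000)
    print(f"features overlapping ctg01:0-5000: {len(hits)} "
          f"(chunk files opened: {lazy.chunks_opened})")

    reloaded = names.NameIndex.load(data)
    completions = reloaded.autocomplete("gene", 5)
    print("autocomplete 'gene' ->", completions)
    # Each completion is a display name; lookup gives its location(s):
    first = reloaded.lookup_exact(completions[0])[0]
    print(f"{first.name} is at {first.location.seq_id}:"
          f"{first.location.start}-{first.location.end}")
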