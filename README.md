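# trackkit

A static-site indexing and query toolkit for genome annotation tracks.

Genome browsers that run entirely in the client need the server to be
nothing more than a file host: all the heavy lifting — interval indexing,
name search, statistics — happens either once at publish time or in the
client at view time. `trackkit` implements that computational core as a
standalone Python library and command-line tool:

- **Chunked sequence store** — a FASTA file is split into fixed-size residue
  chunks so any subsequence is served by reading only the chunks it touches;
  sizes-only catalogs (chrom.sizes) support the same metadata queries.
- **Nested containment lists (NCLists)** — annotation features are indexed
  so that any interval contained in another is stored in the container's
  *sublist*; siblings sorted by (start ↑, end ↓) contain no mutual nesting,
  so sibling ends ascend and an overlap query `[s, e)` binary-searches each
  run and descends only into branches it overlaps. Large sublists are
  externalized to numbered JSON *lazy chunks* loaded only when a query's
  range overlaps their recorded span.
- **Radix-tree name index** — feature names, aliases and reference-sequence
  names keyed by their case-fold in a path-compressed prefix tree, sharded
  into per-prefix files; supports exact lookup and prefix autocomplete.
- **Query-side computations** — range queries, per-track statistics
  (count, density, score range, positional histograms), set operations and
  arithmetic on tracks, regular-expression sequence search on both strands,
  read pileups with SNP flagging, and five-source configuration merging
  with faceted track-metadata filtering.

All coordinates are interbase (0-based, half-open); GFF3's 1-based
inclusive convention is converted at the format boundary only.

## Worked example

Index a 20 kb synthetic contig with 25 nested gene models, then query the
serialized files (`examples/build_and_query_dataset.py`):

```text
indexed 1 refseq(s), 20000 bases in 5 kb chunks
features overlapping ctg01:0-5000: 8 (chunk files opened: 1)
autocomplete 'gene' -> ['gene0001', 'gene0001-alias', 'gene0001.t1', 'gene0004', 'gene0004-alias']
gene0001 is at ctg01:6299-6993
```

Eight gene models overlap the first 5 kb, and answering that query opened
exactly one lazy-chunk file — the one whose span overlaps the region. The
autocomplete lists the first five display names (features, aliases,
transcripts) whose case-folded form starts with `gene`.

SNP screening on 20× reads with spiked variants
(`examples/snp_coverage.py`):

```text
400 reads of 100 bp over 2000 bp (~20x)
mean coverage: 20.0x
true spiked sites: [(500, 'G', 0.3), (1200, 'T', 0.5), (1700, 'T', 0.05)]
called: pos 500 A->G freq 0.27 depth 30
called: pos 1200 C->T freq 0.50 depth 24
(the 5% site stays below the 0.2 threshold and is not called)
```

The pileup recovers exactly the two real variant sites; the measured
alternate frequencies (0.27, 0.50) are the spiked fractions up to the
rounding granularity of the local depth. Each remaining script in
`examples/` demonstrates one capability the same way: `interval_index.py`
(containment structure and half-open query semantics),
`combination_tracks.py` (footprint set algebra and signal arithmetic),
`motif_search.py` (IUPAC motifs and regex on both strands),
`configuration.py` (precedence merging and faceted metadata filters).

The same workflow is available from the shell:

```sh
trackkit prepare-refseqs --fasta genome.fa --out data/
trackkit flatfile-to-json --gff genes.gff3 --track-label genes --out data/
trackkit generate-names --out data/
trackkit query --out data/ --track-label genes --region ctg01:0-5000
trackkit names --out data/ --prefix gene
```

## Layout of a dataset directory

```
data/
  seq/refs.json                      refseq catalog (name, length, chunk size)
  seq/<name>/<k>.txt[.gz]            residue chunk k
  tracks/<label>/<refseq>/trackData.json   root index + statistics
  tracks/<label>/<refseq>/lf-<k>.json[.gz] lazy NCList chunks
  names/root.json, names/shard-*.json      radix-tree name index
  trackList.json                     track stanzas
```
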