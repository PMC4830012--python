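# Methods

This note records the models, conventions, parameter choices and numerical
decisions behind `trackkit`, and what its synthetic-data tests do and do not
demonstrate about real data.

## Coordinate model

Everything internal is interbase: 0-based, half-open `[start, end)`.
Position `k` denotes the gap before the (k+1)-th base, adjacent intervals
share no bases, and zero-length intervals are insertion points. GFF3's
1-based inclusive convention is converted exactly once, in the GFF3 reader
and writer; BED and BedGraph are already interbase and pass through
unchanged. Strand is an integer in {−1, 0, +1}; both `.` and `?` map to 0.
This single-convention design confines the entire off-by-one error class to
two format-boundary functions, which is why the round-trip tests include a
feature starting at position 0 (the classic boundary failure).

## Nested containment lists

`build_nclist` sorts features by (start ascending, end descending) and runs
one pass with a containment stack: a feature is pushed into the sublist of
the innermost open interval that contains it, else to the top level —
O(n log n) overall. The tie-break makes the longer of two co-started
intervals the parent and nests equal intervals first-under-second, which
gives a canonical, deterministic structure (required for byte-stable
serialization). Two consequences are load-bearing for querying:

- siblings at any level are sorted by start, and
- no sibling contains another, so sibling **ends ascend too**.

An overlap query for `[s, e)` therefore binary-searches each sibling run for
the first end > `s`, walks while start < `e`, and recurses only into nodes
it overlaps. Equivalence with a brute-force linear scan is asserted for
1 000 nested intervals × 200 queries, both in memory and through the
serialized files.

### Serialization and lazy chunks

Each refseq of a track serializes to one `trackData.json` (statistics,
attribute-layout table, top of the NCList) plus numbered `lf-<k>.json`
chunk files. Node attributes are column-compressed: distinct attribute
layouts ("classes") are tabulated once per track and each node stores a
class index plus a value array, which avoids repeating attribute names for
homogeneous tracks. A sibling run whose inline feature count would exceed
`chunk_feature_limit` (default 2 000) is greedily packed, left to right,
into chunk files of at most the limit; the externalization threshold fires
when *placing* a sublist would overflow its holder, so no chunk file ever
holds more than the limit. Each chunk reference records the span covered by
its contents, and the lazy reader opens a chunk only when a query's range
overlaps that span — the instrumented test asserts a query touching k
chunks opens exactly k files. Optional gzip of chunk files uses mtime 0 so
compressed output is byte-stable; decompressed bytes equal the uncompressed
serialization.

### Statistics

`track_stats` reports feature count, density (count divided by refseq
length), and the score range when scores are present. Histograms assign a
feature to the bin containing its **start** (not overlap-weighted), so bin
counts sum exactly to the feature count — a conservation law the tests
assert. The precomputed histogram ladder is powers-of-ten multiples of
1 kb up to the refseq length; other bin sizes are computed on demand.
Region statistics count features overlapping the region, i.e. the length of
the corresponding range query.

## Chunked sequence store

`import_fasta` splits each sequence into `chunk_size`-base files (default
20 000 — small enough for cheap range requests, few enough files for
megabase genomes). Residues are stored verbatim: case carries soft-masking
information and is never folded; characters are not validated. Reads of
`[start, end)` touch only chunks `start // chunk_size` through
`(end−1) // chunk_size`. Sizes-only catalogs answer lengths and orderings
identically to full catalogs but raise a capability error on sequence
access. Reverse complement covers the IUPAC alphabet, preserves case, and
maps anything unknown to N (a deliberate information-destroying choice,
preferred over guessing). Translation uses the standard nuclear code by
default (tables are pluggable as a full 64-codon mapping), renders stops as
`*` and ambiguous codons as `X`, and drops trailing partial codons.

## Name index

Keys are ASCII case-folds of display names; the tree is a path-compressed
radix tree (no single-child, record-free nodes), verified structurally in
tests. Autocomplete returns up to `limit` distinct display names in
lexicographic order of normalized names — a deliberate, documented contract
since ranking is out of scope. Ties among records with one normalized name
order by (track label, start). Reference-sequence names and their aliases
are always indexed, which is what keeps heavily fragmented draft assemblies
navigable. On save, any subtree holding more than `shard_record_limit`
records (default 1 000) moves to its own percent-encoded-prefix file,
recursively; loading resolves shards on first touch, and all queries are
asserted identical before and after the shard round trip.

## Track combination

Set operations act on *footprints* — per-refseq normalized interval lists —
with per-base semantics, implemented as a sweep over the union of
breakpoints. Feature identity, names and subfeatures are deliberately not
preserved: once gene models overlap, any identity-preserving definition of
"union" is ambiguous, so results are plain unnamed `region` features.
Signal arithmetic evaluates the operator on each breakpoint segment.
Missing operands follow per-operation defaults: add/subtract treat missing
as 0 (so indicator-signal addition reproduces coverage, a tested identity);
multiply/divide propagate missingness, and division by zero yields a
missing segment — the toolkit never invents data where an operand has none.
Adjacent equal-valued segments merge, so outputs are canonical.

## Pileup and SNP flagging

The pileup walks each read's CIGAR: M/=/X consume read and reference and
add base counts; D consumes reference and increments the column's deletion
tally; N consumes reference silently; I increments `insertions_following`
on the preceding column; S/H consume nothing on the reference. The column
invariant `depth = Σ base counts + deletions` is asserted everywhere. Reads
whose CIGAR disagrees with their base-string length are skipped with a
logged warning rather than poisoning the pileup.

SNP flagging is a screening rule, not genotyping: a non-reference base at a
column with depth ≥ `min_depth` (default 5) is called when
`count / (depth − deletions)` ≥ `min_alt_frequency` (default 0.2). The
denominator excludes deletions so indel evidence does not dilute
substitution evidence; N is counted in depth but never called. Both
thresholds are configurable; the defaults are conservative screening
values. Read filtering drops unmapped reads always, and duplicates,
secondary and supplementary alignments by default; proper-pair and mapping
quality gates are opt-in.

Reads come from SAM/BAM via pysam or from a plain tab-separated format
(`seq_id  start  cigar  bases  flags  [mapq]`, SAM flag integer, mapq
defaulting to 60) so every alignment test runs on text files. The extra
optional mapq column exists because the filter needs it; this is the
package's own format.

## Sequence search

Plain motifs have IUPAC codes expanded to character classes; regex mode
compiles the pattern verbatim. Matching is case-insensitive by default
(soft-masked sequence still matches). The scan is all-offsets — at each
position the leftmost match anchored there — so overlapping occurrences are
all reported. Reverse-strand hits scan the reverse complement and map a hit
at reverse offset r, length L to forward `[length − r − L, length − r)`.
To keep chunked stores sound, matches are bounded by `max_match_length`
(default 500) and scan windows overlap by that length minus one, so any
bounded match spanning a chunk or window edge lies wholly inside some
window; a test plants a motif straddling the window boundary.

## Configuration

Two dialects parse into one `ConfigTree`: JSON (object root) and a textual
stanza format (dotted `[section]` headers, `key = value`, indented
continuations, `#` comments outside quotes, `include` directives). Textual
values are typed — integer/float literals, `true`/`false`, and JSON-style
lists coerce; everything else is a string — which is what makes the two
dialects losslessly interconvertible for scalar/list values. The price is
that a *string* shaped like a literal (`"123"`) cannot survive the textual
dialect; the property tests therefore draw non-literal-shaped strings.
Values beginning with `function(` are opaque callback strings, stored and
re-emitted verbatim and never evaluated (executing embedded code is out of
scope and a hazard). Merging is a deep merge, lowest precedence first —
includes < data-directory files < top-level files < embedding-application
object < URL query parameters — scalars and lists replace, subtrees merge
recursively, and every leaf records which source supplied it. Includes
resolve depth-first at lower precedence than their includer, with cycle
detection naming the cycle. Track metadata is RFC 4180 CSV whose label
column is the first header matching `label` case-insensitively; facet
filtering is intersection across facets, OR within a facet's accepted set,
and a missing value never satisfies a filter.

## Synthetic data

The fixture generators produce the shapes that stress this toolkit, not
realistic biology: uniform-ACGT genomes; gene→mRNA→exon models with UTR
flanks (guaranteed nesting depth ≥ 2 for the containment lists); names with
heavy shared prefixes plus aliases (autocomplete stress); error-free
uniformly-placed reads. Variants are spiked by systematic thinning — an
accumulator substitutes the alternate base in a deterministic fraction of
covering reads — so the realized alternate frequency equals the spiked
frequency to within 1/depth and the ground-truth manifest states true
values rather than sampling targets; with per-read Bernoulli sampling at
20× a 0.3-frequency site would drop below the 0.2 calling threshold in
roughly a tenth of datasets, turning an exact-recovery check into a coin
flip. All randomness flows from one seed through named substreams, and
every artifact records its seed in a header comment; identical specs are
byte-identical.

Consequently, passing tests demonstrate algorithmic correctness — oracle
equivalence, conservation laws, round-trip fidelity, determinism — not
robustness to sequencing error, alignment artifacts, soft-clip-heavy reads,
or adversarial annotation files. Default problem sizes in the tests and the
acceptance script (10 kb–100 kb sequences, 10³–10⁴ features/names,
500-read pileups) were chosen so every oracle can be exhaustive per base;
all operations are linear or n log n and scale to real genomes, where only
the oracles would become infeasible.

## Known limitations

- No graph genomes, circular chromosomes, or trans-spliced features.
- SNP screening only: no genotype likelihoods, indel calls, or base
  qualities.
- Regex matches longer than `max_match_length` are truncated by contract.
- Set operations flatten feature identity (documented above).
- The on-disk JSON schema is this package's own; byte compatibility with
  any other browser's index format is a non-goal.
- The textual configuration dialect cannot represent literal-shaped strings
  or empty subtrees.
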