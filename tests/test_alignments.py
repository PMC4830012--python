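"""Read filtering, CIGAR pileup, SNP thresholding, coverage consistency."""

import io

import pytest

from trackkit import fixtures
from trackkit.alignments import (
    AlignedRead,
    PileupColumn,
    ReadFilter,
    call_snps,
    filter_reads,
    parse_cigar,
    pileup,
    read_sam,
    read_tabular,
    snp_coverage_track,
    write_tabular,
    write_vcf,
)
from trackkit.refseq import import_fasta
from trackkit.trackops import feature_coverage


def mk_read(start, cigar, bases, seq="ctg01", flags=0, mapq=60):
    return AlignedRead(seq, start, parse_cigar(cigar), bases, mapq, flags)


@pytest.fixture
def ref_catalog(tmp_path):
    seq = "ACGTA" + "ACGT" * 249  # 1001 bases
    return import_fasta(io.StringIO(f">ctg01\n{seq}\n"), tmp_path, chunk_size=100), seq


class TestFilterReads:
    def test_duplicate_dropped_when_enabled(self):
        read = mk_read(0, "4M", "ACGT", flags=0x400)
        assert filter_reads([read], ReadFilter(drop_duplicates=True)) == []
        kept = filter_reads([read], ReadFilter(drop_duplicates=False))
        assert kept == [read]

    def test_low_mapq_retained_at_zero_threshold(self):
        read = mk_read(0, "4M", "ACGT", mapq=3)
        assert filter_reads([read], ReadFilter(min_mapq=0)) == [read]
        assert filter_reads([read], ReadFilter(min_mapq=10)) == []

    def test_unmapped_always_dropped(self):
        read = mk_read(0, "4M", "ACGT", flags=0x4)
        assert filter_reads([read], ReadFilter(drop_duplicates=False)) == []

    def test_random_flag_matrix_matches_predicate_oracle(self, rng):
        policies = [
            ReadFilter(),
            ReadFilter(drop_duplicates=False, drop_secondary_and_supplementary=False),
            ReadFilter(require_proper_pair=True, min_mapq=30),
        ]
        reads = [
            mk_read(i, "4M", "ACGT",
                    flags=rng.randrange(0, 0x1000), mapq=rng.randrange(0, 61))
            for i in range(300)
        ]
        for policy in policies:
            def keep(r):
                return not (
                    r.is_unmapped
                    or (policy.drop_duplicates and r.is_duplicate)
                    or (policy.drop_secondary_and_supplementary
                        and (r.is_secondary or r.is_supplementary))
                    or (policy.require_proper_pair and not r.is_proper_pair)
                    or r.mapq < policy.min_mapq
                )
            assert filter_reads(reads, policy) == [r for r in reads if keep(r)]


class TestPileup:
    def test_depth_profile_of_two_overlapping_reads(self, ref_catalog):
        catalog, seq = ref_catalog
        reads = [mk_read(0, "4M", seq[0:4]), mk_read(1, "4M", seq[1:5])]
        cols = pileup(reads, catalog, ("ctg01", 0, 10))
        assert [(c.position, c.depth) for c in cols] == [
            (0, 1), (1, 2), (2, 2), (3, 2), (4, 1),
        ]
        assert all(c.ref_base == seq[c.position] for c in cols)

    def test_deletion_consumes_reference_and_counts(self):
        read = mk_read(0, "2M1D2M", "ACGT")
        cols = pileup([read], None, ("ctg01", 0, 10))
        by_pos = {c.position: c for c in cols}
        assert by_pos[2].deletions == 1
        assert by_pos[2].depth == 1
        assert sum(by_pos[2].counts.values()) == 0
        assert by_pos[4].depth == 1  # read spans 5 reference bases

    def test_insertion_increments_preceding_column(self):
        read = mk_read(0, "2M1I2M", "ACGTA")
        cols = pileup([read], None, ("ctg01", 0, 10))
        by_pos = {c.position: c for c in cols}
        assert by_pos[1].insertions_following == 1
        assert read.reference_span().length == 4

    def test_soft_clips_contribute_nothing(self):
        read = mk_read(5, "2S3M1S", "AACGTC")
        cols = pileup([read], None, ("ctg01", 0, 20))
        assert [c.position for c in cols] == [5, 6, 7]
        assert cols[0].counts == {"C": 1}

    def test_skip_region_contributes_nothing(self):
        read = mk_read(0, "2M5N2M", "ACGT")
        cols = pileup([read], None, ("ctg01", 0, 20))
        assert [c.position for c in cols] == [0, 1, 7, 8]

    def test_inconsistent_cigar_skipped_with_warning(self, caplog):
        bad = mk_read(0, "5M", "ACG")
        good = mk_read(0, "3M", "ACG")
        with caplog.at_level("WARNING"):
            cols = pileup([bad, good], None, ("ctg01", 0, 10))
        assert "skipping read" in caplog.text
        assert all(c.depth == 1 for c in cols)

    def test_depth_identity_and_random_cigar_oracle(self, rng):
        """Pileup equals a naive per-base event expansion on 500 random reads."""
        reads = []
        for _ in range(500):
            start = rng.randrange(0, 900)
            cigar, bases = _random_cigar(rng)
            reads.append(mk_read(start, cigar, bases))
        region = ("ctg01", 0, 1_000)
        cols = pileup(reads, None, region)
        expected_counts, expected_dels, expected_ins = _naive_pileup(reads, 1_000)
        by_pos = {c.position: c for c in cols}
        for pos in range(1_000):
            col = by_pos.get(pos)
            counts = col.counts if col else {}
            assert counts == expected_counts.get(pos, {})
            assert (col.deletions if col else 0) == expected_dels.get(pos, 0)
            assert (col.insertions_following if col else 0) == expected_ins.get(pos, 0)
        for col in cols:
            assert col.depth == sum(col.counts.values()) + col.deletions
        # column conservation: total depth = total aligned M/=/X plus deletions
        total_mx = sum(
            n for r in reads for op, n in r.cigar if op in "M=X"
        )
        total_d = sum(n for r in reads for op, n in r.cigar if op == "D")
        assert sum(c.depth for c in cols) == total_mx + total_d


def _random_cigar(rng):
    ops = []
    bases = []
    n_ops = rng.randint(1, 5)
    for i in range(n_ops):
        op = rng.choice("MMMMIDS=X")
        if i in (0, n_ops - 1) and op in "ID":
            op = "M"  # keep alignments anchored
        n = rng.randint(1, 20)
        ops.append(f"{n}{op}")
        if op in "MIS=X":
            bases.append("".join(rng.choice("ACGT") for _ in range(n)))
    return "".join(ops), "".join(bases)


def _naive_pileup(reads, span):
    counts: dict[int, dict[str, int]] = {}
    dels: dict[int, int] = {}
    ins: dict[int, int] = {}
    for r in reads:
        if r.query_length() != len(r.bases):
            continue
        ref, query = r.start, 0
        for op, n in r.cigar:
            if op in "M=X":
                for i in range(n):
                    if 0 <= ref + i < span:
                        d = counts.setdefault(ref + i, {})
                        b = r.bases[query + i]
                        d[b] = d.get(b, 0) + 1
                ref += n
                query += n
            elif op == "D":
                for i in range(n):
                    if 0 <= ref + i < span:
                        dels[ref + i] = dels.get(ref + i, 0) + 1
                ref += n
            elif op == "N":
                ref += n
            elif op == "I":
                if 0 <= ref - 1 < span:
                    ins[ref - 1] = ins.get(ref - 1, 0) + 1
                query += n
            elif op == "S":
                query += n
    return counts, dels, ins


class TestCallSnps:
    def col(self, pos=10, ref="A", counts=None, deletions=0):
        return PileupColumn(position=pos, ref_base=ref,
                            counts=counts or {}, deletions=deletions)

    def test_forty_percent_alt_called_at_defaults(self):
        (call,) = call_snps([self.col(counts={"A": 6, "G": 4})])
        assert (call.alt_base, call.alt_frequency, call.depth) == ("G", 0.4, 10)

    def test_five_percent_alt_not_called(self):
        assert call_snps([self.col(counts={"A": 19, "T": 1})]) == []

    def test_min_depth_gate(self):
        shallow = self.col(counts={"A": 2, "G": 2})
        assert call_snps([shallow]) == []
        assert len(call_snps([shallow], min_depth=4)) == 1

    def test_deletions_excluded_from_frequency_denominator(self):
        column = self.col(counts={"A": 5, "G": 5}, deletions=10)
        (call,) = call_snps([column])
        assert call.alt_frequency == 0.5
        assert call.depth == 20

    def test_n_never_called(self):
        assert call_snps([self.col(counts={"A": 5, "N": 5})]) == []

    def test_requires_reference(self):
        with pytest.raises(ValueError, match="reference"):
            call_snps([PileupColumn(position=1, counts={"A": 9})])


class TestSnpCoverageTrack:
    def test_empty_input(self):
        track, calls = snp_coverage_track([], None, ("ctg01", 0, 100))
        assert track.seq_ids() == [] and calls == []

    def test_uniform_coverage_no_variants(self, tmp_path):
        spec = fixtures.FixtureSpec(seed=13, n_refseqs=1, refseq_length=2_000,
                                    read_depth=20)
        genome = fixtures.genome_sequences(spec)
        catalog = import_fasta(
            io.StringIO(fixtures.make_genome(spec)), tmp_path, chunk_size=500
        )
        text, _ = fixtures.make_reads(spec, genome)
        reads = read_tabular(text)
        track, calls = snp_coverage_track(reads, catalog, ("ctg01", 0, 2_000))
        assert calls == []
        mid = [s for s in track.get("ctg01")
               if s.interval.start >= 200 and s.interval.end <= 1_800]
        for s in mid:
            assert 5 <= s.value <= 45  # around the 20x target

    def test_spiked_variants_recovered_exactly(self, tmp_path):
        spec = fixtures.FixtureSpec(
            seed=17, n_refseqs=1, refseq_length=2_000, read_depth=20,
            variants=((500, 0.3), (1_000, 0.5), (1_500, 0.05)),
        )
        genome = fixtures.genome_sequences(spec)
        catalog = import_fasta(
            io.StringIO(fixtures.make_genome(spec)), tmp_path, chunk_size=500
        )
        text, manifest = fixtures.make_reads(spec, genome)
        reads = read_tabular(text)
        _, calls = snp_coverage_track(reads, catalog, ("ctg01", 0, 2_000))
        assert sorted(c.position for c in calls) == [500, 1_000]
        by_pos = {c.position: c for c in calls}
        truth = {v["pos"]: v for v in manifest["variants"]}
        for pos in (500, 1_000):
            assert by_pos[pos].alt_base == truth[pos]["alt"]
            # binomial sampling at ~20x: allow three standard errors
            p = truth[pos]["freq"]
            n = sum(1 for r in reads if r.start <= pos < r.start + 100)
            tol = 3 * (p * (1 - p) / n) ** 0.5
            assert by_pos[pos].alt_frequency == pytest.approx(p, abs=tol)

    def test_depth_equals_feature_coverage_of_spans(self, rng):
        reads = []
        for _ in range(200):
            start = rng.randrange(0, 900)
            cigar, bases = _random_cigar(rng)
            reads.append(mk_read(start, cigar, bases))
        region = ("ctg01", 0, 1_000)
        track, _ = snp_coverage_track(reads, None, region)
        valid = [r for r in reads if r.query_length() == len(r.bases)]
        expected = feature_coverage(
            (r.reference_span() for r in valid), region=region
        )
        assert track == expected


class TestIO:
    def test_tabular_round_trip(self):
        reads = [mk_read(3, "2M1I2M", "ACGTA", flags=0x400)]
        back = read_tabular(write_tabular(reads, header_comment="x"))
        assert back == reads

    def test_sam_reader_agrees_with_tabular(self, tmp_path):
        sam = (
            "@HD\tVN:1.6\tSO:coordinate\n"
            "@SQ\tSN:ctg01\tLN:1000\n"
            "r1\t0\tctg01\t1\t60\t4M\t*\t0\t0\tACGT\t*\n"
            "r2\t1024\tctg01\t3\t7\t2M1D2M\tACGT\t0\t0\tACGT\t*\n"
        )
        path = tmp_path / "reads.sam"
        path.write_text(sam)
        reads = read_sam(path)
        assert len(reads) == 2
        assert reads[0].start == 0 and reads[0].cigar == [("M", 4)]
        assert reads[1].is_duplicate and reads[1].mapq == 7

    def test_vcf_output_is_one_based(self):
        calls = call_snps(
            [PileupColumn(position=0, ref_base="A", counts={"A": 5, "G": 5})]
        )
        vcf = write_vcf(calls, "ctg01")
        data_line = vcf.strip().splitlines()[-1]
        assert data_line.split("\t")[:5] == ["ctg01", "1", ".", "A", "G"]
        assert "DP=10" in data_line and "AF=0.5000" in data_line
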