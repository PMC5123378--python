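"""I/O, pileup extraction, call-set algebra and FASTQ QC tests."""
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lodn.lod_core import InconsistentInputError
from lodn.seq_io import (
    CallSet,
    ContigError,
    GenomicSite,
    ParseError,
    SequencedRead,
    VariantRecord,
    apply_qc,
    extract_pileup,
    extract_pileups,
    fastq_qc,
    read_known_sites,
    read_pileup_tsv,
    read_variants,
    subtract_callsets,
    union_callsets,
    write_variants,
)


def rec(chrom, pos, ref, alt, **kw):
    return VariantRecord(site=GenomicSite(chrom, pos), ref=ref, alt=alt, **kw)


def callset(*keys, label=""):
    return CallSet([rec(*k) for k in keys], label=label)


class TestVcfRoundTrip:
    def test_write_then_read_preserves_records(self, tmp_path):
        calls = CallSet(
            [
                rec("1", 14608116, "T", "C", id="rs1", population_af=0.04,
                    functional_class="nonsynonymous",
                    provenance={"GATK-LODN"},
                    annotations={"lod_t": 115.0, "lod_n": 9.0266, "f_hat": 0.5,
                                 "tumor_depth": 80, "normal_depth": 30}),
                rec("2", 100, "G", "A", provenance={"MuTect"}),
            ],
            label="test",
        )
        path = tmp_path / "out.vcf"
        write_variants(calls, path)
        back = read_variants(path)
        assert back.keys() == calls.keys()
        r = back.get(("1", 14608116, "T", "C"))
        assert r.id == "rs1"
        assert r.population_af == pytest.approx(0.04, rel=1e-5)
        assert r.functional_class == "nonsynonymous"
        assert "GATK-LODN" in r.provenance
        assert r.annotations["lod_t"] == pytest.approx(115.0, rel=1e-5)
        assert r.annotations["lod_n"] == pytest.approx(9.0266, rel=1e-5)
        assert r.annotations["tumor_depth"] == 80

    def test_empty_callset_gives_header_only_vcf(self, tmp_path):
        path = tmp_path / "empty.vcf"
        write_variants(CallSet(), path)
        lines = path.read_text().splitlines()
        assert lines and all(l.startswith("#") for l in lines)
        assert len(read_variants(path)) == 0

    def test_output_in_genomic_order(self, tmp_path):
        calls = callset(("2", 5, "A", "C"), ("1", 9, "G", "T"), ("1", 2, "G", "T"))
        path = tmp_path / "sorted.vcf"
        write_variants(calls, path)
        body = [l.split("\t")[:2] for l in path.read_text().splitlines()
                if not l.startswith("#")]
        assert body == [["1", "2"], ["1", "9"], ["2", "5"]]


class TestReadVariants:
    def _write(self, tmp_path, body):
        path = tmp_path / "in.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=AF,Number=A,Type=Float,Description="af">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        path.write_text(header + body)
        return path

    def test_multiallelic_row_splits_per_alt(self, tmp_path):
        path = self._write(tmp_path, "1\t100\t.\tA\tC,G\t50\tPASS\tAF=0.1,0.2\n")
        calls = read_variants(path)
        assert calls.keys() == {("1", 100, "A", "C"), ("1", 100, "A", "G")}
        assert calls.get(("1", 100, "A", "G")).population_af == pytest.approx(0.2, rel=1e-5)

    def test_indels_are_skipped(self, tmp_path):
        path = self._write(
            tmp_path,
            "1\t100\t.\tAT\tA\t50\tPASS\t.\n1\t200\t.\tT\tC\t50\tPASS\t.\n",
        )
        calls = read_variants(path)
        assert calls.keys() == {("1", 200, "T", "C")}

    def test_missing_id_becomes_none(self, tmp_path):
        path = self._write(tmp_path, "1\t100\t.\tA\tC\t50\tPASS\t.\n")
        assert read_variants(path).get(("1", 100, "A", "C")).id is None


class TestExtractPileup:
    def _sam(self, tmp_path, rows):
        """rows: (name, flag, pos0, cigar, seq, qual_char, mapq)"""
        path = tmp_path / "t.sam"
        header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 1000}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for name, flag, pos0, cigar, seq, qc, mapq in rows:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.flag = flag
                a.reference_id = 0
                a.reference_start = pos0
                a.mapping_quality = mapq
                a.cigarstring = cigar
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array(qc * len(seq))
                out.write(a)
        return path

    def test_filters_and_cigar_walk(self, tmp_path):
        # site c1:6 (pos0=5); 10-base reads starting at pos0=0
        q30, q3 = "?", "$"
        path = self._sam(
            tmp_path,
            [
                ("match", 0, 0, "10M", "AAAAACAAAA", q30, 60),       # included: C at site
                ("del", 0, 0, "5M2D5M", "AAAAAAAAAA", q30, 60),      # deletion spans site
                ("dup", 1024, 0, "10M", "AAAAACAAAA", q30, 60),      # duplicate flag
                ("lowbq", 0, 0, "10M", "AAAAACAAAA", q3, 60),        # base quality 3 < 5
                ("lowmq", 0, 0, "10M", "AAAAACAAAA", q30, 0),        # mapq 0 < 1
                ("softclip", 0, 6, "4S6M", "AAAAGAAAAA", q30, 60),   # aligned part starts after site
                ("refbase", 0, 0, "10M", "AAAAAAAAAA", q30, 60),     # included: ref base
                ("nbase", 0, 0, "10M", "AAAAANAAAA", q30, 60),       # N excluded
            ],
        )
        pileup = extract_pileup(path, GenomicSite("c1", 6), "A")
        assert pileup.depth == 2
        assert sorted(o.base for o in pileup.observations) == ["A", "C"]

    def test_softclipped_site_base_included_when_aligned(self, tmp_path):
        # 4S6M starting at pos0=4 aligns query indices 4..9 to ref 4..9
        path = self._sam(tmp_path, [("sc", 0, 4, "4S6M", "TTTTGCCCCC", "?", 60)])
        pileup = extract_pileup(path, GenomicSite("c1", 5), "A")
        assert pileup.depth == 1
        assert pileup.observations[0].base == "G"

    def test_absent_contig_raises(self, tmp_path):
        path = self._sam(tmp_path, [("r", 0, 0, "10M", "A" * 10, "?", 60)])
        with pytest.raises(ContigError, match="cX"):
            extract_pileup(path, GenomicSite("cX", 6), "A")

    def test_multi_site_extraction_matches_single(self, tmp_path):
        path = self._sam(
            tmp_path,
            [(f"r{i}", 0, i, "10M", "ACGTACGTAC", "?", 60) for i in range(5)],
        )
        sites = {GenomicSite("c1", 3): "G", GenomicSite("c1", 8): "T"}
        multi = extract_pileups(path, sites)
        for site, ref in sites.items():
            single = extract_pileup(path, site, ref)
            assert [o.base for o in multi[site].observations] == [
                o.base for o in single.observations
            ]


class TestPileupTsv:
    def test_round_trip_of_dialect(self, tmp_path):
        path = tmp_path / "p.tsv"
        path.write_text("c1\t10\tA\tAACA\t??5?\nc1\t20\tG\tGG\tII\n")
        pileups = read_pileup_tsv(path)
        p = pileups[GenomicSite("c1", 10)]
        assert p.ref_allele == "A"
        assert [o.base for o in p.observations] == list("AACA")
        assert [o.base_quality for o in p.observations] == [30, 30, 20, 30]

    def test_length_mismatch_raises_with_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("c1\t10\tA\tAAC\t??\n")
        with pytest.raises(ParseError, match=":1"):
            read_pileup_tsv(path)


class TestCallsetAlgebra:
    A = ("1", 10, "A", "C")
    B = ("1", 20, "G", "T")
    C = ("2", 5, "C", "A")

    def test_subtraction_removes_shared_keys(self):
        out = subtract_callsets(callset(self.A, self.B, self.C), callset(self.B))
        assert out.keys() == {self.A, self.C}

    def test_subtracting_empty_is_identity(self):
        tumor = callset(self.A, self.B)
        assert subtract_callsets(tumor, CallSet()).keys() == tumor.keys()

    def test_key_match_is_allele_aware(self):
        tumor = callset(("1", 10, "A", "C"))
        normal = callset(("1", 10, "A", "G"))  # same site, different alt
        assert subtract_callsets(tumor, normal).keys() == {("1", 10, "A", "C")}

    def test_union_merges_collisions(self):
        a = CallSet([rec(*self.A, provenance={"MuTect"}), rec(*self.B)])
        b = CallSet([rec(*self.A, provenance={"GATK-LODN"}), rec(*self.C)])
        out = union_callsets(a, b)
        assert out.keys() == {self.A, self.B, self.C}
        assert out.get(self.A).provenance == {"MuTect", "GATK-LODN"}

    def test_union_with_empty_is_identity(self):
        x = callset(self.A, self.B)
        assert union_callsets(CallSet(), x).keys() == x.keys()

    def test_union_conflicting_refs_rejected(self):
        with pytest.raises(InconsistentInputError):
            union_callsets(callset(("1", 10, "A", "C")), callset(("1", 10, "G", "C")))

    @given(
        st.sets(st.integers(min_value=1, max_value=30), max_size=12),
        st.sets(st.integers(min_value=1, max_value=30), max_size=12),
    )
    @settings(deadline=None, max_examples=50)
    def test_set_laws_on_random_fixtures(self, pos_a, pos_b):
        a = callset(*[("1", p, "A", "C") for p in pos_a])
        b = callset(*[("1", p, "A", "C") for p in pos_b])
        union = union_callsets(a, b)
        # inclusion-exclusion
        assert len(union) == len(a) + len(b) - len(a.keys() & b.keys())
        # subtraction complements intersection
        assert subtract_callsets(a, b).keys() == a.keys() - b.keys()
        # identity and commutativity on keys
        assert union.keys() == union_callsets(b, a).keys()


class TestKnownSites:
    def test_tsv_form(self, tmp_path):
        path = tmp_path / "known.tsv"
        path.write_text("# comment\n1\t100\tA\tC\n2\t5\tG\tT\n")
        assert read_known_sites(path) == {("1", 100, "A", "C"), ("2", 5, "G", "T")}

    def test_vcf_form(self, tmp_path):
        calls = callset(("1", 100, "A", "C"))
        path = tmp_path / "known.vcf"
        write_variants(calls, path)
        assert read_known_sites(path) == {("1", 100, "A", "C")}


class TestFastqQc:
    def _fastq(self, tmp_path, reads):
        path = tmp_path / "in.fq"
        with open(path, "w") as fh:
            for name, seq, quals in reads:
                fh.write(f"@{name}\n{seq}\n+\n{''.join(chr(q + 33) for q in quals)}\n")
        return path

    def test_high_quality_read_unchanged(self, tmp_path):
        path = self._fastq(tmp_path, [("r1", "ACGT" * 25, [30] * 100)])
        out = tmp_path / "out.fq"
        summary = fastq_qc(path, out)
        assert (summary.kept, summary.trimmed, summary.dropped) == (1, 0, 0)
        assert out.read_text() == path.read_text()

    def test_mostly_low_quality_read_dropped(self, tmp_path):
        # 90 of 100 bases below q20 -> fraction 0.9 > 0.8 -> removed
        quals = [10] * 45 + [30] * 10 + [10] * 45
        path = self._fastq(tmp_path, [("r1", "A" * 100, quals)])
        summary = fastq_qc(path, tmp_path / "out.fq")
        assert summary.dropped == 1 and summary.kept == 0

    def test_three_prime_trimming(self, tmp_path):
        quals = [30] * 45 + [10] * 5
        path = self._fastq(tmp_path, [("r1", "A" * 50, quals)])
        out = tmp_path / "out.fq"
        summary = fastq_qc(path, out)
        assert (summary.kept, summary.trimmed) == (1, 1)
        assert len(out.read_text().splitlines()[1]) == 45

    def test_exactly_eighty_percent_low_quality_kept(self, tmp_path):
        # fraction == 0.8 is not "more than 80 %"
        quals = [10] * 8 + [30] * 2
        path = self._fastq(tmp_path, [("r1", "ACGTACGTAC", quals)])
        assert fastq_qc(path, tmp_path / "out.fq").kept == 1

    def test_idempotent_and_never_longer(self, tmp_path):
        import numpy as np

        rng = np.random.default_rng(3)
        reads = [
            (f"r{i}", "".join(rng.choice(list("ACGT"), 60)),
             [int(q) for q in rng.integers(2, 41, 60)])
            for i in range(40)
        ]
        path = self._fastq(tmp_path, reads)
        once, twice = tmp_path / "once.fq", tmp_path / "twice.fq"
        s1 = fastq_qc(path, once)
        s2 = fastq_qc(once, twice)
        assert once.read_text() == twice.read_text()
        assert s2.dropped == 0 and s2.trimmed == 0
        assert s1.kept == s2.kept

    def test_length_mismatch_raises(self):
        with pytest.raises(ParseError):
            SequencedRead("r", "ACGT", (30, 30))

    def test_apply_qc_examples(self):
        read = SequencedRead("r", "ACGTA", (30, 30, 30, 10, 10))
        trimmed = apply_qc(read)
        assert trimmed.bases == "ACG"
        assert apply_qc(SequencedRead("r", "AAAA", (5, 5, 5, 5))) is None
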