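"""Transcript arithmetic, breakpoint taxonomy, dedup and origin partitioning."""

import numpy as np
import pytest
from Bio.Seq import Seq

from svfw import transcripts as tx
from svfw.classify import (
    GeneIndex,
    annotate_svs,
    classify_location,
    dedupe_svs,
    frame_for_fusion,
    multiplicity_table,
    partition_origin,
    subclassify_intergenic,
    subclassify_intragenic,
)
from svfw.models import UniqueSV, ValidatedSV
from tests.conftest import make_gene


def usv(sv_type="deletion", chromA="c1", posA=0, chromB="c1", posB=0, **kw):
    return UniqueSV(sv_id="u", sv_type=sv_type, chromA=chromA, posA=posA,
                    chromB=chromB, posB=posB, **kw)


class TestAdjustBreakpoint:
    def test_exonic_breakpoint_unchanged(self):
        g = make_gene()
        assert tx.adjust_breakpoint_to_exon(1200, g, "5_prime") == 1200

    def test_intronic_five_prime_moves_to_retained_exon_end(self):
        g = make_gene()  # exons (1000,1400) (2000,2400) (3000,3400)
        assert tx.adjust_breakpoint_to_exon(1700, g, "5_prime") == 1400

    def test_intronic_three_prime_moves_to_next_exon_start(self):
        g = make_gene()
        assert tx.adjust_breakpoint_to_exon(1700, g, "3_prime") == 2000

    def test_minus_strand_three_prime_against_splice_oracle(self):
        """Exon-adjusted junctions on a minus-strand 3' partner land where the
        fusion transcript actually switches sequence."""
        rng = np.random.default_rng(12)
        from svfw._seq import random_dna

        chrom = random_dna(rng, 6_000)
        g5 = make_gene("A", exons=((200, 500), (900, 1200)), strand="+")
        g3 = make_gene("B", exons=((3000, 3400), (4000, 4400)), strand="-")
        bp5 = 1_050            # exonic in A
        bp3 = 3_700            # intron of B
        seq, j, t3d = tx.fusion_transcript({"c1": chrom}, g5, bp5, g3, bp3)
        # role 3_prime on the minus strand retains the genomic-left exon,
        # entered at its genomic end boundary
        b3 = tx.adjust_breakpoint_to_exon(bp3, g3, "3_prime")
        assert b3 == 3_400
        s3 = tx.spliced_sequence(chrom, g3)
        assert seq[j:] == s3[t3d:]
        # the suffix begins exactly at the retained exon boundary
        from svfw._seq import revcomp
        assert seq[j : j + 50] == revcomp(chrom[3_350:3_400])

    def test_breakpoint_outside_span_raises(self):
        g = make_gene()
        with pytest.raises(ValueError):
            tx.adjust_breakpoint_to_exon(900, g, "5_prime")  # upstream of exon 1


class TestFrameStatus:
    def test_phase_zero_junction_in_frame(self):
        g5 = make_gene("A", utr5=150)
        g3 = make_gene("B", exons=((5000, 5400), (6000, 6400), (7000, 7400)))
        # CDS starts 150 nt into exon 1 (250 coding nt remain there), so a
        # coding prefix of 300 ends 50 nt into exon 2
        bp5 = 2_050  # c5 = 300
        cs3 = g3.cds_span[0]
        bp3 = cs3  # c3 = 0
        assert tx.frame_status(bp5, g5, bp3, g3) == "in_frame"
        assert tx.frame_status(bp5 + 1, g5, bp3, g3) == "out_of_frame"

    def test_breakpoint_outside_cds_raises(self):
        g5, g3 = make_gene("A"), make_gene("B")
        with pytest.raises(ValueError):
            tx.frame_status(g5.start + 5, g5, g3.cds_span[0], g3)  # 5'UTR

    def test_agrees_with_translation_oracle_on_random_junctions(self, toy_annotation):
        """Independent oracle: concatenate the retained coding sequences and
        check whether the 3' partner's native codon translation survives."""
        models, _ = toy_annotation
        coding = [m for m in models if m.biotype == "coding"]
        rng = np.random.default_rng(5)
        checked = 0
        while checked < 200:
            m5, m3 = coding[rng.integers(len(coding))], coding[rng.integers(len(coding))]
            if m5.gene_id == m3.gene_id:
                continue
            cds5 = _cds_seq(m5)
            cds3 = _cds_seq(m3)
            c5 = int(rng.integers(10, len(cds5) - 10))
            c3 = int(rng.integers(10, len(cds3) - 40))
            fused = cds5[:c5] + cds3[c3:]
            prot = str(Seq(fused[: len(fused) // 3 * 3]).translate())
            native = str(Seq(cds3).translate())
            oracle = "in_frame" if native[-8:] in prot else "out_of_frame"
            bp5 = _genomic_at_cds_offset(m5, c5)
            bp3 = _genomic_at_cds_offset(m3, c3)
            assert tx.frame_status(bp5, m5, bp3, m3) == oracle
            checked += 1


def _cds_seq(m):
    from svfw.simulate import GenomeConfig, make_genome

    genome = _oracle_genome()
    s = tx.spliced_sequence(genome.chromosomes[m.chrom], m)
    cs, ce = tx.cds_transcript_interval(m)
    return s[cs:ce]


_G = {}


def _oracle_genome():
    if "g" not in _G:
        from svfw.simulate import GenomeConfig, make_genome

        _G["g"] = make_genome(GenomeConfig(seed=11))
    return _G["g"]


def _genomic_at_cds_offset(m, c):
    """Genomic boundary whose retained coding prefix is exactly c bases."""
    cs, ce = tx.cds_transcript_interval(m)
    t = cs + c  # transcript offset of the junction boundary
    # find genomic boundary g with retained_prefix_len == t
    lo, hi = m.start, m.end
    for g in range(lo, hi + 1):
        if tx.retained_prefix_len(m, g) == t:
            if m.strand == "+" and (g == m.start or tx.retained_prefix_len(m, g - 1) == t - 1):
                return g
            if m.strand == "-" and tx.retained_prefix_len(m, g + 1) == t - 1:
                return g
    raise AssertionError("no genomic boundary found")


class TestLocationClasses:
    @pytest.fixture()
    def index(self):
        genes = [
            make_gene("G1", exons=((10_000, 10_400), (11_000, 11_400), (12_000, 12_400))),
            make_gene("G2", exons=((30_000, 30_400), (31_000, 31_400), (32_000, 32_400))),
            make_gene("GN", exons=((50_000, 50_400), (51_000, 51_400)), biotype="noncoding"),
        ]
        return genes, GeneIndex(genes)

    def test_both_breakpoints_in_introns_of_one_gene_intragenic(self, index):
        genes, idx = index
        sv = usv(posA=10_500, posB=11_600)
        loc, ga, _ = classify_location(sv, idx)
        assert loc == "intragenic" and ga.gene_id == "G1"
        assert subclassify_intragenic(sv, ga) == "intronic"

    def test_gene_to_unannotated_is_intergenic(self, index):
        _genes, idx = index
        sv = usv(posA=10_200, posB=70_000)
        loc, _, _ = classify_location(sv, idx)
        assert loc == "intergenic"

    def test_far_from_all_genes_is_desert(self, index):
        _genes, idx = index
        sv = usv(posA=70_000, posB=71_000)
        assert classify_location(sv, idx)[0] == "gene_desert"

    def test_exonic_cds_disruptive(self, index):
        genes, idx = index
        g1 = genes[0]
        cds_pos = g1.cds_span[0] + 30
        sv = usv(posA=cds_pos, posB=10_600)
        assert subclassify_intragenic(sv, g1) == "exonic_cds_disruptive"

    def test_noncoding_exon(self, index):
        genes, idx = index
        gn = genes[2]
        sv = usv(posA=50_100, posB=50_600)
        assert subclassify_intragenic(sv, gn) == "exonic_noncoding"


class TestSubclassifyIntergenic:
    @pytest.fixture()
    def idx(self):
        genes = [
            make_gene("A", exons=((10_000, 10_400), (11_000, 11_400), (12_000, 12_400))),
            make_gene("B", exons=((40_000, 40_400), (41_000, 41_400), (42_000, 42_400))),
            make_gene("R", strand="-", exons=((70_000, 70_400), (71_000, 71_400), (72_000, 72_400))),
        ]
        return {g.gene_id: g for g in genes}, GeneIndex(genes)

    def test_promoter_fusion(self, idx):
        genes, index = idx
        sv = usv(posA=7_000, posB=36_000)  # upstream windows of A and B
        sub, frame, p5, p3 = subclassify_intergenic(sv, index)
        assert (sub, p5, p3) == ("promoter", "A", "B")
        assert frame == "not_applicable"

    def test_cds_to_cds_coding_fusion_with_frame(self, idx):
        genes, index = idx
        a, b = genes["A"], genes["B"]
        sv = usv(posA=a.cds_span[0] + 30, posB=b.cds_span[0] + 30)
        sub, frame, p5, p3 = subclassify_intergenic(sv, index)
        assert sub == "coding_fusion" and p5 == "A" and p3 == "B"
        assert frame in ("in_frame", "out_of_frame")
        assert frame == frame_for_fusion(sv.posA, a, sv.posB, b)

    def test_wrong_orientation_is_uncharacterized(self, idx):
        genes, index = idx
        r = genes["R"]  # minus strand: reads INTO a junction retaining its right side
        sv = usv(posA=genes["A"].cds_span[0] + 30, posB=r.cds_span[0] + 30)
        sub, _, _, _ = subclassify_intergenic(sv, index)
        assert sub == "uncharacterized_rna"

    def test_coding_to_unannotated_five_prime_truncated(self, idx):
        genes, index = idx
        sv = usv(posA=genes["A"].cds_span[0] + 30, posB=90_000)
        sub, _, p5, p3 = subclassify_intergenic(sv, index)
        assert sub == "five_prime_truncated" and p5 == "A" and p3 == ""


class TestDedupeAndOrigin:
    def _v(self, posA, posB, sample, svt="deletion"):
        return ValidatedSV(sv_id="x", sv_type=svt, chromA="c1", posA=posA,
                           orientA="L", chromB="c1", posB=posB, orientB="R",
                           supporting_contig="", sample_id=sample)

    def test_identical_sv_across_samples_merges(self):
        triples = []
        for p in ("P1", "P2", "P3"):
            triples.append((p, "tumor", self._v(100, 600, p)))
            triples.append((p, "blood", self._v(100, 600, p)))
        uniques = dedupe_svs(triples)
        assert len(uniques) == 1
        assert uniques[0].multiplicity == 3
        counts = partition_origin(uniques)
        assert uniques[0].origin == "germline"
        assert counts == {"germline": 1, "somatic": 0, "blood_only": 0}

    def test_small_offset_within_tolerance_merges(self):
        triples = [("P1", "tumor", self._v(100, 600, "P1")),
                   ("P2", "tumor", self._v(104, 596, "P2"))]
        assert len(dedupe_svs(triples, tolerance_bp=10)) == 1
        assert len(dedupe_svs(triples, tolerance_bp=2)) == 2

    def test_origin_partition_example(self):
        # tumor set {A, B}; blood set {B, C}
        triples = [("P1", "tumor", self._v(100, 600, "P1")),
                   ("P1", "tumor", self._v(5_000, 5_600, "P1")),
                   ("P2", "blood", self._v(5_000, 5_600, "P2")),
                   ("P2", "blood", self._v(9_000, 9_600, "P2"))]
        uniques = dedupe_svs(triples)
        partition_origin(uniques)
        by_pos = {u.posA: u.origin for u in uniques}
        assert by_pos == {100: "somatic", 5_000: "germline", 9_000: "blood_only"}

    def test_no_blood_samples_all_somatic(self):
        triples = [("P1", "tumor", self._v(100, 600, "P1")),
                   ("P2", "tumor", self._v(5_000, 5_600, "P2"))]
        uniques = dedupe_svs(triples)
        counts = partition_origin(uniques)
        assert counts["somatic"] == 2 and counts["germline"] == 0

    def test_empty_carriers_error(self):
        with pytest.raises(ValueError):
            partition_origin([usv(carriers={})])

    def test_multiplicity_percentages_sum_to_hundred(self):
        triples = []
        rngpos = [(100, 600), (5_000, 5_600), (9_000, 9_600)]
        for i, (a, b) in enumerate(rngpos):
            for p in ["P1", "P2", "P3"][: i + 1]:
                triples.append((p, "tumor", self._v(a, b, p)))
        uniques = dedupe_svs(triples)
        partition_origin(uniques)
        table = multiplicity_table(uniques, 3)
        somatic = table[table.origin == "somatic"]
        assert somatic["count"].sum() == 3
        assert somatic["percent"].sum() == pytest.approx(100.0, abs=0.5)
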