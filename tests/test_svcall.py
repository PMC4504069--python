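"""Mapper, discordant-pair signatures, and cluster typing."""

import pytest
from hypothesis import given, settings, strategies as st

from svfw._seq import revcomp
from svfw.models import DiscordantPair, LibraryStats
from svfw.svcall import (
    GenomeMapper,
    cluster_signatures,
    detect_discordant,
    map_reads,
    min_support_for,
    pair_signature,
)
from tests.conftest import make_aln


class TestMinSupport:
    def test_stated_formula_at_thirty_x(self, lib):
        # depth 30, mu 350, L 75 -> physical coverage 70 -> threshold 9
        assert min_support_for(30.0, lib) == 9

    def test_floor_of_three_at_low_depth(self, lib):
        assert min_support_for(1e-6, lib) == 3

    @given(st.floats(min_value=0.1, max_value=200.0), st.floats(min_value=0.1, max_value=200.0))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_depth(self, d1, d2):
        lib = LibraryStats(75, 350.0, 35.0)
        lo, hi = sorted((d1, d2))
        assert min_support_for(lo, lib) <= min_support_for(hi, lib)

    def test_rejects_nonpositive_depth(self, lib):
        with pytest.raises(ValueError):
            min_support_for(0, lib)


class TestPairSignature:
    def test_concordant_at_mean_insert(self, lib):
        sig, obs = pair_signature(("c1", 1000, "+"), ("c1", 1000 + 350 - 75, "-"), lib)
        assert sig is None and obs == 350

    def test_large_insert_beyond_window(self, lib):
        sig, obs = pair_signature(("c1", 1000, "+"), ("c1", 1000 + 700 - 75, "-"), lib, k_sd=3.0)
        assert sig == "large_insert" and obs == 700

    def test_short_insert(self, lib):
        sig, _ = pair_signature(("c1", 1000, "+"), ("c1", 1000 + 160 - 75, "-"), lib)
        assert sig == "short_insert"

    def test_same_strand(self, lib):
        assert pair_signature(("c1", 0, "+"), ("c1", 300, "+"), lib)[0] == "same_strand"

    def test_everted_order_reversed(self, lib):
        # reverse mate upstream of the forward mate
        assert pair_signature(("c1", 500, "+"), ("c1", 100, "-"), lib)[0] == "everted"

    def test_interchromosomal(self, lib):
        assert pair_signature(("c1", 0, "+"), ("c2", 0, "-"), lib)[0] == "interchrom"

    @given(st.integers(0, 10_000), st.integers(0, 10_000),
           st.sampled_from("+-"), st.sampled_from("+-"))
    @settings(max_examples=80, deadline=None)
    def test_signature_is_pure_and_single(self, p1, p2, s1, s2):
        lib = LibraryStats(75, 350.0, 35.0)
        a = pair_signature(("c1", p1, s1), ("c1", p2, s2), lib)
        b = pair_signature(("c1", p1, s1), ("c1", p2, s2), lib)
        assert a == b


class TestMapper:
    def test_unique_read_maps_mapq_60(self, flat_genome):
        mapper = GenomeMapper(flat_genome)
        seq = flat_genome.chromosomes["c1"][5000:5075]
        assert mapper.map_read(seq) == ("c1", 5000, "+", 60)

    def test_reverse_strand_read(self, flat_genome):
        mapper = GenomeMapper(flat_genome)
        seq = revcomp(flat_genome.chromosomes["c2"][700:775])
        assert mapper.map_read(seq) == ("c2", 700, "-", 60)

    def test_two_locus_read_gets_mapq_zero(self, flat_genome):
        dup = flat_genome.chromosomes["c1"][100:175]
        genome = type(flat_genome)(
            chromosomes={"c1": flat_genome.chromosomes["c1"] + dup},
            masks=flat_genome.masks,
        )
        mapper = GenomeMapper(genome)
        assert mapper.map_read(dup)[3] == 0

    def test_junction_spanning_read_goes_to_unmapped_store(self, flat_genome):
        ref = flat_genome.chromosomes["c1"]
        donor = ref[:4000] + ref[4500:]  # 500 bp deletion
        junction_read = donor[3960:4035]  # 40 bases each side
        assert junction_read not in ref
        mapping = map_reads([("r1", junction_read, revcomp(ref[100:175]))], flat_genome)
        assert [(rid, mate) for rid, mate, _s in mapping.unmapped_store] == [("r1", 1)]

    def test_pcr_exact_duplicates_collapsed(self, flat_genome):
        ref = flat_genome.chromosomes["c1"]
        pair = ("rX", ref[1000:1075], revcomp(ref[1275:1350]))
        mapping = map_reads([pair, ("rY",) + pair[1:]], flat_genome)
        assert mapping.duplicates_removed == 1
        assert len(mapping.records) == 1


def mk_pairs(sig, n, lib, chrom="c1", a0=10_000, b0=10_600, strands=("+", "-"), spread=30):
    """Hand-built discordant pairs with the requested geometry."""
    out = []
    L = lib.read_length
    for i in range(n):
        a = make_aln(f"p{i}", chrom, a0 - L + i * spread % 90, strands[0])
        b = make_aln(f"p{i}", chrom, b0 + (i * spread) % 90, strands[1], mate=2)
        obs = b.start + L - a.start if sig in ("large_insert", "short_insert") else None
        out.append(DiscordantPair(f"p{i}", a, b, sig, obs))
    return out


class TestClusterSignatures:
    def test_single_deletion_cluster(self, lib):
        pairs = mk_pairs("large_insert", 8, lib, a0=10_000, b0=10_800)
        calls = cluster_signatures(pairs, lib, min_support=5)
        assert len(calls) == 1
        call = calls[0]
        assert call.sv_type == "deletion"
        assert call.support == 8

    def test_below_threshold_emits_nothing(self, lib):
        pairs = mk_pairs("large_insert", 3, lib, a0=10_000, b0=10_800)
        assert cluster_signatures(pairs, lib, min_support=5) == []

    def test_min_support_must_be_at_least_two(self, lib):
        with pytest.raises(ValueError):
            cluster_signatures([], lib, min_support=1)

    def test_small_everted_cluster_is_small_duplication(self, lib):
        # everted pairs around a sub-100 bp duplication: reverse mate barely
        # upstream of the forward mate
        # duplication of [4940, 5020): reverse mates start at/after 4940,
        # forward mates end at/before 5020
        L = lib.read_length
        pairs = []
        for i in range(6):
            b = make_aln(f"e{i}", "c1", 4_940 + i, "-", mate=2)
            a = make_aln(f"e{i}", "c1", 5_020 - L - i, "+")
            pairs.append(DiscordantPair(f"e{i}", b, a, "everted", None))
        calls = cluster_signatures(pairs, lib, min_support=3)
        assert [c.sv_type for c in calls] == ["small_duplication"]

    def test_large_everted_cluster_is_tandem_duplication(self, lib):
        # duplication of [5000, 5600)
        L = lib.read_length
        pairs = []
        for i in range(6):
            b = make_aln(f"e{i}", "c1", 5_000 + i * 11, "-", mate=2)
            a = make_aln(f"e{i}", "c1", 5_600 - L - i * 7, "+")
            pairs.append(DiscordantPair(f"e{i}", b, a, "everted", None))
        calls = cluster_signatures(pairs, lib, min_support=3)
        assert [c.sv_type for c in calls] == ["tandem_duplication"]

    def test_reciprocal_interchrom_clusters_merge_to_one_translocation(self, lib):
        L = lib.read_length
        pairs = []
        for i in range(5):  # derivative 1: chr1(+) -> chr2(-)
            a = make_aln(f"d1{i}", "c1", 8_000 - L - i * 20, "+")
            b = make_aln(f"d1{i}", "c2", 3_000 + i * 20, "-", mate=2)
            pairs.append(DiscordantPair(f"d1{i}", a, b, "interchrom", None))
        for i in range(5):  # derivative 2: chr2(+) -> chr1(-)
            a = make_aln(f"d2{i}", "c1", 8_000 + i * 20, "-", mate=2)
            b = make_aln(f"d2{i}", "c2", 3_000 - L - i * 20, "+")
            pairs.append(DiscordantPair(f"d2{i}", a, b, "interchrom", None))
        calls = cluster_signatures(pairs, lib, min_support=3)
        assert [c.sv_type for c in calls] == ["translocation"]
        assert calls[0].support == 10

    def test_undefined_needs_comparable_contradictory_clusters(self, lib):
        dele = mk_pairs("large_insert", 8, lib, a0=10_000, b0=10_800)
        # two stray short-insert pairs at the same locus: absorbed as noise
        stray = mk_pairs("short_insert", 2, lib, a0=10_050, b0=10_250)
        calls = cluster_signatures(dele + stray, lib, min_support=5)
        assert [c.sv_type for c in calls] == ["deletion"]
        # comparable support -> genuinely ambiguous -> undefined
        both = mk_pairs("large_insert", 6, lib, a0=10_000, b0=10_800) + mk_pairs(
            "short_insert", 6, lib, a0=10_020, b0=10_760
        )
        calls = cluster_signatures(both, lib, min_support=5)
        assert [c.sv_type for c in calls] == ["undefined"]

    def test_detect_discordant_applies_mapq_filter(self, lib):
        good = (make_aln("a", "c1", 100, "+"), make_aln("a", "c1", 5_000, "-", mate=2))
        low = (
            make_aln("b", "c1", 100, "+", mapq=20),
            make_aln("b", "c1", 5_000, "-", mate=2),
        )
        out = detect_discordant([good, low], lib)
        assert [p.read_id for p in out] == ["a"]
        assert out[0].signature == "large_insert"
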