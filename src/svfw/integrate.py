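"""RNA and expression integration.

detect_rna_fusions matches reads against the spliced transcriptome: a read
whose prefix (>= 10 bases) lies in one gene's exonic sequence and whose suffix
(>= 10 bases) lies in another's is split-read evidence, with the switch point
mapped back to genomic coordinates on exon boundaries; pairs whose mates map
wholly into the two partner genes in fusion-consistent orientation are
spanning evidence. A fusion call needs both kinds of support, and junctions
confined to a single gene locus are discarded.

DNA breakpoints are matched to RNA junctions after intron-to-exon adjustment
(introns are spliced out, so an intronic DNA breakpoint appears in RNA at the
closest retained exon boundary).
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from ._seq import KmerIndex, revcomp
from .models import FusionTranscriptCall, GeneModel, ReferenceGenome, UniqueSV
from . import transcripts as tx
from .transcripts import adjust_breakpoint_to_exon  # re-exported pipeline surface

__all__ = [
    "adjust_breakpoint_to_exon",
    "detect_rna_fusions",
    "match_fusion_to_sv",
    "expression_calls",
    "Transcriptome",
]

MIN_SPLIT_OVERLAP = 10
JUNCTION_TOLERANCE = 10
FOLD_CHANGE_THRESHOLD = 2.0


def _transcript_to_genomic(model: GeneModel, t: int) -> int:
    """Genomic position of transcript base ``t`` (0-based)."""
    order = model.exons if model.strand == "+" else model.exons[::-1]
    acc = 0
    for s, e in order:
        ln = e - s
        if t < acc + ln:
            off = t - acc
            return s + off if model.strand == "+" else e - 1 - off
        acc += ln
    raise IndexError(f"transcript offset {t} outside {model.transcript_id}")


def junction_5_genomic(model: GeneModel, t_end: int) -> int:
    """Genomic boundary after the last retained base of a 5' partner whose
    transcript prefix of length ``t_end`` is kept."""
    g = _transcript_to_genomic(model, t_end - 1)
    return g + 1 if model.strand == "+" else g


def junction_3_genomic(model: GeneModel, t_start: int) -> int:
    """Genomic boundary before the first retained base of a 3' partner."""
    g = _transcript_to_genomic(model, t_start)
    return g if model.strand == "+" else g + 1


class Transcriptome:
    """Spliced transcript sequences with a shared k-mer lookup."""

    def __init__(self, genome: ReferenceGenome, models: list[GeneModel], seed_len: int = 12):
        self.models = {m.gene_id: m for m in models}
        self.seqs = {
            m.gene_id: tx.spliced_sequence(genome.chromosomes[m.chrom], m)
            for m in models
        }
        self.seed_len = seed_len
        self.index = KmerIndex(self.seqs, seed_len)

    def locate(self, seq: str) -> tuple[str, int, str] | None:
        """(gene_id, transcript pos, sense) of a full-length exact match."""
        for query, sense in ((seq, "sense"), (revcomp(seq), "antisense")):
            for si, pos in self.index.candidates(query[: self.seed_len]):
                ref = self.index.seqs[si]
                if ref[pos : pos + len(query)] == query:
                    return self.index.names[si], pos, sense
        return None

    def prefix_match(self, seq: str) -> tuple[str, int, int] | None:
        """Longest exact prefix of ``seq`` inside a transcript (sense):
        (gene_id, transcript pos of prefix start, prefix length)."""
        best = None
        for si, pos in self.index.candidates(seq[: self.seed_len]):
            qs, qe = self.index.extend_match(si, pos, seq, 0)
            if qs != 0:
                continue
            if best is None or qe > best[2]:
                best = (self.index.names[si], pos, qe)
        return best

    def suffix_match(self, seq: str, start: int) -> tuple[str, int, int] | None:
        """Exact match of seq[start:] in a transcript: (gene_id, transcript
        pos of the suffix start, matched length)."""
        if len(seq) - start < self.seed_len:
            return None
        best = None
        for si, pos in self.index.candidates(seq[start : start + self.seed_len]):
            qs, qe = self.index.extend_match(si, pos, seq, start)
            if qs > start or qe < len(seq):
                continue
            if best is None or qe - start > best[2]:
                best = (self.index.names[si], pos, qe - start)
        return best


def _split_read_junction(transcriptome: Transcriptome, seq: str):
    """Fusion junction evidence from one (possibly reverse-complemented) read."""
    for query in (seq, revcomp(seq)):
        pm = transcriptome.prefix_match(query)
        if pm is None:
            continue
        gene5, pos5, plen = pm
        if plen < MIN_SPLIT_OVERLAP or len(query) - plen < MIN_SPLIT_OVERLAP:
            continue
        sm = transcriptome.suffix_match(query, plen)
        if sm is None:
            continue
        gene3, pos3, _slen = sm
        if gene3 == gene5:
            return None  # confined to a single gene locus
        m5 = transcriptome.models[gene5]
        m3 = transcriptome.models[gene3]
        j5 = junction_5_genomic(m5, pos5 + plen)
        j3 = junction_3_genomic(m3, pos3)
        return gene5, gene3, j5, j3, m5.chrom, m3.chrom
    return None


def detect_rna_fusions(
    reads: list[tuple[str, str, str]],
    transcriptome: Transcriptome,
    sample_id: str,
) -> list[FusionTranscriptCall]:
    """Aggregate split-read and spanning-pair evidence into fusion calls."""
    split: dict[tuple, int] = defaultdict(int)
    meta: dict[tuple, tuple[str, str]] = {}
    spanning: dict[frozenset, int] = defaultdict(int)
    for _rid, m1, m2 in reads:
        a1 = transcriptome.locate(m1)
        a2 = transcriptome.locate(m2)
        if a1 is not None and a2 is not None:
            g1, _p1, s1 = a1
            g2, _p2, s2 = a2
            if g1 != g2 and s1 != s2:
                spanning[frozenset((g1, g2))] += 1
            continue
        for seq, located in ((m1, a1), (m2, a2)):
            if located is not None:
                continue
            hit = _split_read_junction(transcriptome, seq)
            if hit is not None:
                g5, g3, j5, j3, c5, c3 = hit
                key = (g5, g3, j5, j3)
                split[key] += 1
                meta[key] = (c5, c3)
    calls = []
    for (g5, g3, j5, j3), n_split in sorted(split.items()):
        n_span = spanning.get(frozenset((g5, g3)), 0)
        if n_split >= 1 and n_span >= 1:
            c5, c3 = meta[(g5, g3, j5, j3)]
            calls.append(
                FusionTranscriptCall(
                    gene_5=g5, gene_3=g3, junction_5=j5, junction_3=j3,
                    chrom_5=c5, chrom_3=c3,
                    split_reads=n_split, spanning_pairs=n_span, sample_id=sample_id,
                )
            )
    return calls


# ---------------------------------------------------------------------------
# DNA <-> RNA matching


def _sv_breakpoint_in_gene(sv: UniqueSV, model: GeneModel) -> int:
    """The SV breakpoint that falls in (or upstream of) the given gene.

    Gene-body containment outranks a promoter-window association: for
    adjacent-gene fusions the 5' partner's breakpoint can sit inside the 3'
    partner's promoter window."""
    bps = [
        (c, p) for c, p in ((sv.chromA, sv.posA), (sv.chromB, sv.posB))
        if c == model.chrom
    ]
    for _c, pos in bps:
        if model.start <= pos < model.end:
            return pos
    lo, hi = model.promoter_window()
    for _c, pos in bps:
        if lo <= pos < hi:
            return pos
    raise ValueError(f"{sv.sv_id}: no breakpoint in {model.gene_id}")


def rna_eligible(sv: UniqueSV) -> bool:
    """Promoter-subclass SVs cannot be distinguished at the RNA level and are
    excluded from fusion-transcript matching."""
    return (
        sv.location_class == "intergenic"
        and sv.subclass != "promoter"
        and sv.origin in ("germline", "somatic")
    )


def match_fusion_to_sv(
    svs: list[UniqueSV],
    fusion_calls: list[FusionTranscriptCall],
    models: list[GeneModel],
    tolerance_bp: int = JUNCTION_TOLERANCE,
) -> dict[str, int]:
    """Flag eligible SVs as expressed when a fusion call in >= 1 cancer sample
    matches partner genes and exon-adjusted junction coordinates."""
    by_gene = {m.gene_id: m for m in models}
    by_pair: dict[tuple[str, str], list[FusionTranscriptCall]] = defaultdict(list)
    for fc in fusion_calls:
        by_pair[(fc.gene_5, fc.gene_3)].append(fc)
    counts = {"eligible": 0, "expressed": 0, "expressed_germline": 0, "expressed_somatic": 0}
    for sv in svs:
        if not rna_eligible(sv):
            continue
        counts["eligible"] += 1
        sv.expressed = False
        if not sv.partner_5 or not sv.partner_3 or sv.partner_5 not in by_gene:
            continue
        m5 = by_gene[sv.partner_5]
        m3 = by_gene.get(sv.partner_3)
        if m3 is None:
            continue
        try:
            bp5 = _sv_breakpoint_in_gene(sv, m5)
            bp3 = _sv_breakpoint_in_gene(sv, m3)
            j5 = adjust_breakpoint_to_exon(bp5, m5, "5_prime") if not tx.is_exonic(m5, bp5) else bp5
            j3 = adjust_breakpoint_to_exon(bp3, m3, "3_prime") if not tx.is_exonic(m3, bp3) else bp3
        except ValueError:
            continue
        # compare junctions in transcript coordinates: chance homology across
        # a splice can shift a genomic junction by a whole intron while the
        # transcript offset moves by only a base or two
        t5 = tx.retained_prefix_len(m5, j5)
        t3 = tx.retained_prefix_len(m3, j3)
        for fc in by_pair.get((sv.partner_5, sv.partner_3), []):
            dt5 = abs(tx.retained_prefix_len(m5, fc.junction_5) - t5)
            dt3 = abs(tx.retained_prefix_len(m3, fc.junction_3) - t3)
            if dt5 <= tolerance_bp and dt3 <= tolerance_bp:
                sv.expressed = True
                break
        if sv.expressed:
            counts["expressed"] += 1
            counts[f"expressed_{sv.origin}"] += 1
    return counts


# ---------------------------------------------------------------------------
# expression fold-changes

EXPRESSION_SUBCLASSES = ("promoter", "alt_5utr", "alt_3utr")


def affected_gene(sv: UniqueSV) -> str:
    """Gene whose expression a promoter/UTR SV is expected to change: the 3'
    partner gains a new promoter/5'UTR; an altered 3'UTR affects the 5'
    partner."""
    return sv.partner_3 if sv.subclass in ("promoter", "alt_5utr") else sv.partner_5


def expression_calls(
    matrix: pd.DataFrame,
    svs: list[UniqueSV],
    control_columns: list[str],
    threshold: float = FOLD_CHANGE_THRESHOLD,
) -> tuple[list, dict[str, int]]:
    """Per-carrier fold-changes for promoter/UTR SVs.

    fold_change = cancer value / mean of control values; differential when it
    exceeds the threshold in either direction. An SV is differential if any
    carrier cancer sample passes. Genes missing from the matrix are recorded
    as not evaluable."""
    from .models import ExpressionCall

    control_mean = matrix[control_columns].mean(axis=1)
    calls: list[ExpressionCall] = []
    counts = {
        "eligible": 0, "differential": 0, "differential_germline": 0,
        "differential_somatic": 0, "up": 0, "down": 0, "not_evaluable": 0,
    }
    for sv in svs:
        if sv.location_class != "intergenic" or sv.subclass not in EXPRESSION_SUBCLASSES:
            continue
        if sv.origin not in ("germline", "somatic"):
            continue
        counts["eligible"] += 1
        gene = affected_gene(sv)
        if gene not in matrix.index:
            counts["not_evaluable"] += 1
            continue
        carriers = [p for p, v in sorted(sv.carriers.items()) if v in ("tumor", "both")]
        sv.differential = False
        direction = None
        for p in carriers:
            if p not in matrix.columns:
                continue
            fc = float(matrix.loc[gene, p] / control_mean.loc[gene])
            diff = fc > threshold or fc < 1.0 / threshold
            calls.append(ExpressionCall(gene, p, fc, diff))
            if diff and not sv.differential:
                sv.differential = True
                direction = "up" if fc > threshold else "down"
        if sv.differential:
            counts["differential"] += 1
            counts[f"differential_{sv.origin}"] += 1
            counts[direction] += 1
    return calls, counts
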