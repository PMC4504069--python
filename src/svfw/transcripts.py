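"""Transcript-coordinate arithmetic: splicing, breakpoint/exon adjustment, frames.

The conventions used throughout:

* a DNA junction boundary at genomic coordinate ``g`` with the *upstream*
  (transcript 5') side retained keeps exonic bases ``< g`` for a plus-strand
  transcript and exonic bases ``>= g`` for a minus-strand transcript;
* the exon-adjusted coordinate of an intronic breakpoint is the genomic
  boundary of the retained exon adjacent to the junction (exon end for a
  plus-strand 5' role, exon start for a plus-strand 3' role; mirrored on the
  minus strand), so DNA-side and RNA-side junction coordinates coincide.
"""

from __future__ import annotations

from ._seq import revcomp
from .models import GeneModel


def transcript_length(model: GeneModel) -> int:
    return sum(e - s for s, e in model.exons)


def spliced_sequence(chrom_seq: str, model: GeneModel) -> str:
    """Sense-strand spliced sequence of the transcript."""
    seq = "".join(chrom_seq[s:e] for s, e in model.exons)
    return seq if model.strand == "+" else revcomp(seq)


def exon_containing(model: GeneModel, gpos: int) -> int | None:
    """Index (genomic order) of the exon containing gpos, else None."""
    for i, (s, e) in enumerate(model.exons):
        if s <= gpos < e:
            return i
    return None


def is_exonic(model: GeneModel, gpos: int) -> bool:
    return exon_containing(model, gpos) is not None


def adjust_breakpoint_to_exon(bp: int, model: GeneModel, role: str) -> int:
    """Move an intronic DNA breakpoint to the closest retained exon boundary.

    role '5_prime': the transcript part upstream of the junction is retained;
    role '3_prime': the part downstream. Exonic breakpoints are returned
    unchanged. Raises ValueError when nothing is retained on the required side
    (the fusion is not transcribable).
    """
    if role not in ("5_prime", "3_prime"):
        raise ValueError(f"unknown role {role!r}")
    if not (model.start <= bp < model.end):
        raise ValueError(f"breakpoint {bp} outside transcript span of {model.transcript_id}")
    if is_exonic(model, bp):
        return bp
    exons = model.exons
    upstream_retained = role == "5_prime"
    if model.strand == "-":
        # transcript orientation is reversed relative to the genome
        upstream_retained = not upstream_retained
    if upstream_retained:
        # keep exons genomically left of bp; boundary = end of the last one
        left = [e for s, e in exons if e <= bp]
        if not left:
            raise ValueError("no exon retained upstream of the junction")
        return left[-1]
    right = [s for s, e in exons if s >= bp]
    if not right:
        raise ValueError("no exon retained downstream of the junction")
    return right[0]


def retained_prefix_len(model: GeneModel, boundary: int) -> int:
    """Transcript bases retained upstream of a junction boundary (exon-adjusted)."""
    if model.strand == "+":
        return sum(min(e, boundary) - s for s, e in model.exons if s < boundary)
    return sum(e - max(s, boundary) for s, e in model.exons if e > boundary)


def cds_transcript_interval(model: GeneModel) -> tuple[int, int]:
    """CDS as a half-open interval in transcript coordinates."""
    if model.cds_span is None:
        raise ValueError(f"{model.transcript_id} is non-coding")
    cs, ce = model.cds_span
    if model.strand == "+":
        start = retained_prefix_len(model, cs)
        end = retained_prefix_len(model, ce)
    else:
        start = retained_prefix_len(model, ce)
        end = retained_prefix_len(model, cs)
    return start, end


def region_of(model: GeneModel, gpos: int, promoter_size: int = 5000) -> str:
    """Genic region of a genomic position: promoter/utr5/cds/utr3/intron/
    noncoding_exon/outside."""
    pw = model.promoter_window(promoter_size)
    if pw[0] <= gpos < pw[1]:
        return "promoter"
    if not (model.start <= gpos < model.end):
        return "outside"
    if not is_exonic(model, gpos):
        return "intron"
    if model.biotype != "coding" or model.cds_span is None:
        return "noncoding_exon"
    cs, ce = model.cds_span
    if cs <= gpos < ce:
        return "cds"
    before_cds = gpos < cs if model.strand == "+" else gpos >= ce
    return "utr5" if before_cds else "utr3"


def coding_prefix_len(model: GeneModel, boundary: int) -> int:
    """Coding bases retained upstream of an (exon-adjusted) junction boundary."""
    t = retained_prefix_len(model, boundary)
    cs, ce = cds_transcript_interval(model)
    return max(0, min(t, ce) - cs)


def frame_status(bp5: int, model5: GeneModel, bp3: int, model3: GeneModel) -> str:
    """'in_frame' / 'out_of_frame' for a CDS-CDS junction.

    bp5/bp3 must lie inside (or adjust into) the CDS of their transcripts;
    intronic inputs are exon-adjusted first. c5 = coding bases of the 5'
    partner retained upstream of the junction; c3 = coding bases of the 3'
    partner discarded upstream of it. In frame iff c5 == c3 (mod 3).
    """
    b5 = adjust_breakpoint_to_exon(bp5, model5, "5_prime")
    b3 = adjust_breakpoint_to_exon(bp3, model3, "3_prime")
    for b, m in ((b5, model5), (b3, model3)):
        cs, ce = cds_transcript_interval(m)
        t = retained_prefix_len(m, b)
        if not (cs <= t <= ce):
            raise ValueError(
                f"breakpoint {b} outside CDS of {m.transcript_id}; route to a UTR subclass"
            )
    c5 = coding_prefix_len(model5, b5)
    c3 = coding_prefix_len(model3, b3)
    return "in_frame" if c5 % 3 == c3 % 3 else "out_of_frame"


def fusion_transcript(
    chrom_seqs: dict[str, str],
    model5: GeneModel,
    bp5: int,
    model3: GeneModel,
    bp3: int,
) -> tuple[str, int, int]:
    """Spliced fusion transcript: 5' partner exons up to the junction plus 3'
    partner exons after it. Returns (sequence, junction offset in the fusion,
    3'-partner offset where the suffix starts)."""
    b5 = adjust_breakpoint_to_exon(bp5, model5, "5_prime")
    b3 = adjust_breakpoint_to_exon(bp3, model3, "3_prime")
    t5 = retained_prefix_len(model5, b5)
    t3_discard = retained_prefix_len(model3, b3)
    seq5 = spliced_sequence(chrom_seqs[model5.chrom], model5)[:t5]
    full3 = spliced_sequence(chrom_seqs[model3.chrom], model3)
    seq3 = full3[t3_discard:]
    if t5 == 0 or len(seq3) == 0:
        raise ValueError("fusion transcript has an empty partner side")
    return seq5 + seq3, t5, t3_discard


def canonical_transcript(models: list[GeneModel]) -> GeneModel:
    """Longest CDS, ties broken by transcript length then lexicographic id."""

    def key(m: GeneModel):
        cds_len = 0
        if m.cds_span is not None:
            cs, ce = cds_transcript_interval(m)
            cds_len = ce - cs
        return (-cds_len, -transcript_length(m), m.transcript_id)

    return sorted(models, key=key)[0]
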