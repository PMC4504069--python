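"""Domain records shared across the pipeline stages.

Coordinates are 0-based half-open throughout. A breakpoint is the position of
the first reference base after the junction on its partner locus; orientation
``"L"`` means the reference segment to the *left* of the breakpoint is joined
into the junction, ``"R"`` the segment to the right.
"""

from __future__ import annotations

from dataclasses import dataclass, field


SV_CLASSES = (
    "deletion",
    "insertion",
    "inversion",
    "tandem_duplication",
    "inverted_duplication",
    "translocation",
    "transposition",
)

DISCARD_CLASSES = ("small_duplication", "co_amplicon", "undefined")


@dataclass
class ReferenceGenome:
    """Chromosome sequences plus mask interval sets and excluded-name patterns.

    masks: mask-set name -> chrom -> sorted list of (start, end) intervals.
    excluded_names: substrings marking mitochondrial / Y / unlocalized chroms.
    """

    chromosomes: dict[str, str]
    masks: dict[str, dict[str, list[tuple[int, int]]]] = field(default_factory=dict)
    excluded_names: set[str] = field(default_factory=lambda: {"chrM", "chrY", "Un", "hap"})

    def is_excluded(self, chrom: str) -> bool:
        return any(pat in chrom for pat in self.excluded_names)

    def mask_intervals(self, mask: str, chrom: str) -> list[tuple[int, int]]:
        return self.masks.get(mask, {}).get(chrom, [])

    def validate(self) -> None:
        for mask, per_chrom in self.masks.items():
            for chrom, ivs in per_chrom.items():
                n = len(self.chromosomes[chrom])
                for s, e in ivs:
                    if not (0 <= s < e <= n):
                        raise ValueError(f"mask {mask} interval ({s},{e}) outside {chrom}")


@dataclass
class GeneModel:
    """A single strand-aware transcript with exon/CDS/UTR structure."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]  # sorted, disjoint, genomic
    cds_span: tuple[int, int] | None = None  # genomic; None for noncoding
    biotype: str = "coding"  # 'coding' | 'noncoding'

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Genomic coordinate of the transcription start site."""
        return self.start if self.strand == "+" else self.end - 1

    def promoter_window(self, size: int = 5000) -> tuple[int, int]:
        """Genomic interval counted as promoter (upstream of the TSS)."""
        if self.strand == "+":
            return (max(0, self.start - size), self.start)
        return (self.end, self.end + size)


@dataclass
class LibraryStats:
    """Paired-end library model: forward-reverse mates, truncated-normal insert."""

    read_length: int = 75
    insert_mean: float = 350.0
    insert_sd: float = 35.0

    def __post_init__(self):
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if self.insert_mean <= 2 * self.read_length:
            raise ValueError("insert_mean must exceed 2 x read_length")
        if self.insert_sd <= 0:
            raise ValueError("insert_sd must be positive")


@dataclass
class PlantedSV:
    """Truth record for one simulated structural variant."""

    sv_id: str
    sv_type: str
    chromA: str
    posA: int
    chromB: str
    posB: int
    size: int
    origin: str  # 'germline' | 'somatic'
    samples: tuple[str, ...]  # patient ids carrying the SV
    transcribed: bool = False
    expressed_change: float = 1.0
    # planted taxonomy (what classify should recover)
    location_class: str = "gene_desert"
    subclass: str = "none"
    frame: str = "not_applicable"
    gene5: str = ""
    gene3: str = ""
    affected_gene: str = ""
    target_pos: int = -1  # transposition re-insertion site


@dataclass(slots=True)
class Alignment:
    read_id: str
    mate: int
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int
    is_mapped: bool = True


@dataclass(slots=True)
class DiscordantPair:
    read_id: str
    alnA: Alignment  # lexicographically smaller (chrom, start)
    alnB: Alignment
    signature: str  # large_insert | short_insert | same_strand | everted | interchrom
    observed_insert: int | None = None


@dataclass
class SVCall:
    call_id: str
    sv_type: str
    chromA: str
    startA: int
    endA: int
    chromB: str
    startB: int
    endB: int
    support: int
    sample_id: str
    size_estimate: float = 0.0
    target_chrom: str = ""
    target_pos: int = -1


@dataclass
class Contig:
    contig_id: str
    sequence: str
    source_call_id: str
    k_values: set[int] = field(default_factory=set)


@dataclass
class SplitFragment:
    contig_start: int
    contig_end: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str


@dataclass
class SplitAlignment:
    contig_id: str
    fragments: list[SplitFragment]


@dataclass
class ValidatedSV:
    sv_id: str
    sv_type: str
    chromA: str
    posA: int
    orientA: str  # 'L' | 'R'
    chromB: str
    posB: int
    orientB: str
    supporting_contig: str
    sample_id: str
    homology_len: int = 0


@dataclass
class UniqueSV:
    """A deduplicated SV with per-patient carrier status and origin."""

    sv_id: str
    sv_type: str
    chromA: str
    posA: int
    chromB: str
    posB: int
    carriers: dict[str, str] = field(default_factory=dict)  # patient -> tumor|blood|both
    origin: str = ""  # germline | somatic | blood_only
    multiplicity: int = 0
    # annotation layer
    location_class: str = ""
    subclass: str = ""
    frame: str = "not_applicable"
    partner_5: str = ""
    partner_3: str = ""
    expressed: bool = False
    differential: bool = False


@dataclass
class FusionTranscriptCall:
    gene_5: str
    gene_3: str
    junction_5: int  # exonic genomic coordinate on gene_5's chrom
    junction_3: int
    chrom_5: str
    chrom_3: str
    split_reads: int
    spanning_pairs: int
    sample_id: str


@dataclass
class ExpressionCall:
    gene_id: str
    sample_id: str
    fold_change: float
    differential: bool
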