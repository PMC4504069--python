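"""Reference-genome and gene-annotation generators.

The toy reference mirrors the awkward parts of a real assembly that the
filtering stage has to cope with: telomeric tracts and N-filled assembly gaps
near the chromosome ends, repetitive low-complexity tracts in the interior,
and an excluded-name chromosome (a toy chrY) that the exclusion filter must
drop. Mask tracts follow a Poisson model: tract count ~ Poisson(density x
length / tract_length) with fixed-length tracts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import random_dna
from ..models import GeneModel, ReferenceGenome


@dataclass
class GenomeConfig:
    seed: int = 0
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 760_000, "chr2": 740_000}
    )
    low_complexity_density: float = 0.02
    low_complexity_tract: int = 500
    telomere_len: int = 2_000
    gap_len: int = 800
    include_excluded_chrom: bool = True
    excluded_chrom_len: int = 60_000

    def __post_init__(self):
        for name, n in self.chrom_lengths.items():
            if n < 100_000:
                raise ValueError(f"chromosome {name} shorter than 100 kb")
        if not (0.0 <= self.low_complexity_density <= 1.0):
            raise ValueError("mask density must be in [0, 1]")


# interior guard: calls within 100 kb of a telomere/gap are filtered, so the
# simulator treats [guard, len - guard) as the plantable region
INTERIOR_GUARD = 102_000


def _place_tracts(rng, n_tracts: int, tract: int, lo: int, hi: int) -> list[tuple[int, int]]:
    """Place fixed-length, non-overlapping tracts uniformly in [lo, hi)."""
    placed: list[tuple[int, int]] = []
    attempts = 0
    while len(placed) < n_tracts and attempts < 50 * max(1, n_tracts):
        attempts += 1
        s = int(rng.integers(lo, hi - tract))
        iv = (s, s + tract)
        if all(iv[1] <= a or iv[0] >= b for a, b in placed):
            placed.append(iv)
    placed.sort()
    return placed


def make_genome(config: GenomeConfig) -> ReferenceGenome:
    """Build a masked multi-chromosome reference; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    chroms: dict[str, str] = {}
    low: dict[str, list[tuple[int, int]]] = {}
    gaps: dict[str, list[tuple[int, int]]] = {}
    cent: dict[str, list[tuple[int, int]]] = {}

    for name, length in config.chrom_lengths.items():
        seq = list(random_dna(rng, length))
        telo = config.telomere_len
        cent[name] = [(0, telo), (length - telo, length)]
        # one N-filled assembly gap inside each telomeric tract
        gaps[name] = []
        for lo, hi in cent[name]:
            gs = int(rng.integers(lo + 200, hi - config.gap_len - 100))
            gaps[name].append((gs, gs + config.gap_len))
            seq[gs : gs + config.gap_len] = "N" * config.gap_len
        gaps[name].sort()
        # interior low-complexity tracts: repetitive dinucleotide runs
        d = config.low_complexity_density
        tract = config.low_complexity_tract
        n_tracts = int(rng.poisson(d * length / tract)) if d > 0 else 0
        ivs = _place_tracts(rng, n_tracts, tract, INTERIOR_GUARD, length - INTERIOR_GUARD)
        for s, e in ivs:
            unit = ["AT", "CA", "GT", "AG"][int(rng.integers(0, 4))]
            seq[s:e] = (unit * ((e - s) // 2 + 1))[: e - s]
        low[name] = ivs
        chroms[name] = "".join(seq)

    if config.include_excluded_chrom:
        name = "chrY_toy"
        length = config.excluded_chrom_len
        seq = list(random_dna(rng, length))
        mid = length // 2
        cent[name] = [(mid - 2_000, mid + 2_000)]
        gaps[name] = []
        low[name] = []
        chroms[name] = "".join(seq)

    genome = ReferenceGenome(
        chromosomes=chroms,
        masks={"low_complexity": low, "assembly_gap": gaps, "centromere_telomere": cent},
    )
    genome.validate()
    return genome


# ---------------------------------------------------------------------------
# annotation


@dataclass
class AnnotationConfig:
    seed: int = 1
    n_genes: int = 80
    coding_fraction: float = 0.80
    minus_strand_fraction: float = 0.20
    n_deserts_per_chrom: int = 3
    desert_len: int = 22_000
    desert_clearance: int = 5_000
    gene_gap_range: tuple[int, int] = (3_000, 5_500)


def _build_coding_structure(rng, start: int) -> tuple[list[tuple[int, int]], int, int]:
    """Exon intervals from ``start`` plus (utr5_len, utr3_len) in transcript bases."""
    n_exons = int(rng.integers(4, 7))
    exons = []
    pos = start
    for i in range(n_exons):
        # terminal exons are long enough to hold a UTR plus coding sequence
        ex_len = int(rng.integers(320, 480)) if i in (0, n_exons - 1) else int(rng.integers(170, 360))
        exons.append((pos, pos + ex_len))
        pos += ex_len
        if i < n_exons - 1:
            pos += int(rng.integers(650, 1200))
    total = sum(e - s for s, e in exons)
    utr5 = int(rng.integers(140, 240))
    utr3 = int(rng.integers(140, 260))
    utr3 += (total - utr5 - utr3) % 3  # force CDS length to a multiple of 3
    return exons, utr5, utr3


def _cds_genomic_span(exons, strand, utr5, utr3) -> tuple[int, int]:
    """Genomic CDS span given UTR lengths in transcript coordinates."""
    total = sum(e - s for s, e in exons)
    t_lo, t_hi = utr5, total - utr3  # CDS interval in transcript coords
    order = exons if strand == "+" else exons[::-1]
    g_positions = []
    acc = 0
    for s, e in order:
        ln = e - s
        for t in (t_lo, t_hi - 1):
            if acc <= t < acc + ln:
                off = t - acc
                g = s + off if strand == "+" else e - 1 - off
                g_positions.append(g)
        acc += ln
    lo, hi = min(g_positions), max(g_positions)
    return lo, hi + 1


def make_annotation(
    genome: ReferenceGenome, config: AnnotationConfig
) -> tuple[list[GeneModel], dict[str, list[tuple[int, int]]]]:
    """Place non-overlapping single-transcript genes and gene-desert intervals.

    Coding genes get >=2 exons with 5'UTR/CDS/3'UTR; CDS length is a multiple
    of 3. Deserts are guaranteed gene-free within the configured clearance.
    """
    rng = np.random.default_rng(config.seed)
    main_chroms = [c for c in genome.chromosomes if not genome.is_excluded(c)]

    deserts: dict[str, list[tuple[int, int]]] = {c: [] for c in main_chroms}
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in main_chroms}
    for chrom in main_chroms:
        length = len(genome.chromosomes[chrom])
        lo, hi = INTERIOR_GUARD, length - INTERIOR_GUARD
        span = (hi - lo) // max(1, config.n_deserts_per_chrom)
        for i in range(config.n_deserts_per_chrom):
            ds = lo + i * span + span - config.desert_len - 2_000
            deserts[chrom].append((ds, ds + config.desert_len))
            forbidden[chrom].append(
                (ds - config.desert_clearance, ds + config.desert_len + config.desert_clearance)
            )
        forbidden[chrom].extend(genome.mask_intervals("low_complexity", chrom))
        forbidden[chrom].sort()

    n_coding = int(round(config.n_genes * config.coding_fraction))
    coding_flags = [True] * n_coding + [False] * (config.n_genes - n_coding)
    rng.shuffle(coding_flags)

    # distribute genes across chromosomes proportionally to usable space
    weights = np.array(
        [len(genome.chromosomes[c]) - 2 * INTERIOR_GUARD for c in main_chroms], float
    )
    del weights  # placement walks both chromosomes, least-filled first

    models: list[GeneModel] = []
    cursors = {
        c: INTERIOR_GUARD + int(rng.integers(2_000, 6_000)) for c in main_chroms
    }
    limits = {c: len(genome.chromosomes[c]) - INTERIOR_GUARD for c in main_chroms}
    gi = 0
    while gi < config.n_genes:
        open_chroms = [c for c in main_chroms if cursors[c] < limits[c] - 8_000]
        if not open_chroms:
            break
        # fill the chromosome with the most remaining room first
        chrom = max(open_chroms, key=lambda c: limits[c] - cursors[c])
        cursor = cursors[chrom]
        coding = coding_flags[gi]
        strand = "-" if rng.random() < config.minus_strand_fraction else "+"
        if coding:
            exons, utr5, utr3 = _build_coding_structure(rng, cursor)
        else:
            n_exons = int(rng.integers(2, 4))
            exons, pos = [], cursor
            for i in range(n_exons):
                ex_len = int(rng.integers(200, 500))
                exons.append((pos, pos + ex_len))
                pos += ex_len + (int(rng.integers(500, 1500)) if i < n_exons - 1 else 0)
            utr5 = utr3 = 0
        span = (exons[0][0], exons[-1][1])
        if span[1] >= limits[chrom]:
            cursors[chrom] = limits[chrom]  # chromosome exhausted
            continue
        clash = next(
            (f for f in forbidden[chrom] if not (span[1] <= f[0] or span[0] >= f[1])),
            None,
        )
        if clash is not None:
            cursors[chrom] = clash[1] + 500
            continue
        gid = f"G{gi + 1:03d}"
        models.append(
            GeneModel(
                gene_id=gid,
                transcript_id=f"T{gi + 1:03d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds_span=_cds_genomic_span(exons, strand, utr5, utr3) if coding else None,
                biotype="coding" if coding else "noncoding",
            )
        )
        cursors[chrom] = span[1] + int(rng.integers(*config.gene_gap_range))
        gi += 1

    if gi < config.n_genes:
        raise ValueError(
            f"genome too small for requested gene count (placed {gi}/{config.n_genes})"
        )
    return models, deserts
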