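"""RNA read simulation: background transcriptome plus fusion transcripts.

Each tumor sample expresses every annotated transcript at a background depth
and, for the planted SVs marked transcribed that it carries, a spliced fusion
transcript (5' partner exons up to the junction + 3' partner exons after it).
Junction coverage is high enough that at least one read overlaps the fusion
junction by >= 10 bases on each side and at least one pair spans it;
untranscribed fusions contribute no junction-crossing reads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._seq import revcomp
from ..models import GeneModel, LibraryStats, PlantedSV, ReferenceGenome
from .. import transcripts as tx


@dataclass
class RnaConfig:
    read_length: int = 75
    insert_mean: float = 200.0
    insert_sd: float = 20.0
    background_depth: float = 6.0
    fusion_depth: float = 45.0

    @property
    def lib(self) -> LibraryStats:
        return LibraryStats(self.read_length, self.insert_mean, self.insert_sd)


def fusion_for_sv(
    genome: ReferenceGenome, models_by_gene: dict[str, GeneModel], sv: PlantedSV
) -> tuple[str, int, int]:
    """Spliced fusion transcript for a planted, transcribed SV."""
    if not sv.gene5 or not sv.gene3:
        raise ValueError(f"{sv.sv_id} marked transcribed but has no partner genes")
    m5, m3 = models_by_gene[sv.gene5], models_by_gene[sv.gene3]
    return tx.fusion_transcript(genome.chromosomes, m5, sv.posA, m3, sv.posB)


def _pairs_from_transcript(
    rng, seq: str, n_pairs: int, lib: LibraryStats, prefix: str
) -> list[tuple[str, str, str]]:
    L = lib.read_length
    n = len(seq)
    if n < 2 * L:
        return []
    inserts = np.clip(
        np.rint(rng.normal(lib.insert_mean, lib.insert_sd, n_pairs)).astype(int),
        2 * L,
        None,
    )
    inserts = np.minimum(inserts, n)
    starts = rng.integers(0, np.maximum(1, n - inserts + 1))
    out = []
    for i in range(n_pairs):
        f, ins = int(starts[i]), int(inserts[i])
        out.append((f"{prefix}:{i}", seq[f : f + L], revcomp(seq[f + ins - L : f + ins])))
    return out


def simulate_rna(
    genome: ReferenceGenome,
    models: list[GeneModel],
    truth: list[PlantedSV],
    patient: str,
    config: RnaConfig,
    seed: int,
) -> list[tuple[str, str, str]]:
    """Paired-end RNA reads for one tumor sample."""
    rng = np.random.default_rng(seed)
    lib = config.lib
    by_gene = {m.gene_id: m for m in models}
    reads: list[tuple[str, str, str]] = []
    for m in models:
        seq = tx.spliced_sequence(genome.chromosomes[m.chrom], m)
        n_pairs = int(round(config.background_depth * len(seq) / (2 * lib.read_length)))
        if n_pairs:
            reads.extend(
                _pairs_from_transcript(rng, seq, n_pairs, lib, f"rna:{patient}:{m.gene_id}")
            )
    for sv in truth:
        if not sv.transcribed or patient not in sv.samples:
            continue
        seq, _j5, _j3 = fusion_for_sv(genome, by_gene, sv)
        n_pairs = int(round(config.fusion_depth * len(seq) / (2 * lib.read_length)))
        reads.extend(
            _pairs_from_transcript(rng, seq, max(n_pairs, 30), lib, f"rna:{patient}:{sv.sv_id}")
        )
    return reads
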