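"""Shared fixtures: small deterministic genomes, annotations and helpers."""

from __future__ import annotations

import numpy as np
import pytest

from svfw._seq import random_dna
from svfw.models import Alignment, GeneModel, LibraryStats, ReferenceGenome
from svfw.simulate import (
    AnnotationConfig,
    GenomeConfig,
    PlantConfig,
    make_annotation,
    make_genome,
    plant_svs,
)

LIB = LibraryStats(read_length=75, insert_mean=350.0, insert_sd=35.0)


@pytest.fixture(scope="session")
def toy_genome():
    """Default-scale masked reference (built once per session)."""
    return make_genome(GenomeConfig(seed=11))


@pytest.fixture(scope="session")
def toy_annotation(toy_genome):
    models, deserts = make_annotation(toy_genome, AnnotationConfig(seed=12))
    return models, deserts


@pytest.fixture(scope="session")
def toy_planted(toy_genome, toy_annotation):
    models, deserts = toy_annotation
    return plant_svs(toy_genome, models, deserts, PlantConfig(seed=13))


@pytest.fixture()
def lib():
    return LibraryStats(read_length=75, insert_mean=350.0, insert_sd=35.0)


@pytest.fixture()
def flat_genome():
    """A mask-free two-chromosome reference for mapper/assembly unit tests."""
    rng = np.random.default_rng(424242)
    return ReferenceGenome(
        chromosomes={"c1": random_dna(rng, 30_000), "c2": random_dna(rng, 20_000)},
        masks={"low_complexity": {}, "assembly_gap": {}, "centromere_telomere": {}},
    )


def make_gene(
    gene_id="GX",
    chrom="c1",
    strand="+",
    exons=((1000, 1400), (2000, 2400), (3000, 3400)),
    utr5=150,
    utr3=150,
    biotype="coding",
):
    """Build a GeneModel with UTR lengths given in transcript bases."""
    exons = [tuple(e) for e in exons]
    total = sum(e - s for s, e in exons)
    cds = None
    if biotype == "coding":
        from svfw.simulate.genome import _cds_genomic_span

        utr3 = utr3 + (total - utr5 - utr3) % 3
        cds = _cds_genomic_span(exons, strand, utr5, utr3)
    return GeneModel(
        gene_id=gene_id,
        transcript_id="T" + gene_id,
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds_span=cds,
        biotype=biotype,
    )


def make_aln(read_id, chrom, start, strand, mate=1, mapq=60, read_length=75):
    return Alignment(read_id, mate, chrom, start, start + read_length, strand, mapq)
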