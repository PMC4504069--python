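"""File-format adapters: FASTA/FASTQ (Biopython), GTF, BED, minimal SAM, TSV.

All writers are deterministic (ordering fixed by the caller's data structures)
so identical configs and seeds yield byte-identical files.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import GeneModel, PlantedSV, ReferenceGenome, SVCall, ValidatedSV

TRUTH_COLUMNS = [
    "sv_id", "sv_type", "chromA", "posA", "chromB", "posB", "size", "origin",
    "samples", "transcribed", "expressed_change", "location_class", "subclass",
    "frame", "gene5", "gene3", "affected_gene", "target_pos",
]

CALL_COLUMNS = [
    "call_id", "sv_type", "chromA", "startA", "endA", "chromB", "startB",
    "endB", "support", "sample_id",
]

VALIDATED_COLUMNS = [
    "sv_id", "sv_type", "chromA", "posA", "orientA", "chromB", "posB",
    "orientB", "homology_len", "supporting_contig", "sample_id",
]


def write_fasta(path: str | Path, sequences: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq_pairs(path1: str | Path, path2: str | Path,
                      pairs: list[tuple[str, str, str]]) -> None:
    """pairs: (read_id, seq1, seq2); mates written as id/1 and id/2."""
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for rid, s1, s2 in pairs:
            q1 = "I" * len(s1)
            q2 = "I" * len(s2)
            f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[tuple[str, str, str]]:
    out = []
    it1 = SeqIO.parse(str(path1), "fastq")
    it2 = SeqIO.parse(str(path2), "fastq")
    for r1, r2 in zip(it1, it2):
        rid = r1.id.rsplit("/", 1)[0]
        out.append((rid, str(r1.seq).upper(), str(r2.seq).upper()))
    return out


# ---------------------------------------------------------------------------
# GTF (1-based inclusive on disk; converted from/to 0-based half-open)

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def write_gtf(path: str | Path, models: list[GeneModel]) -> None:
    with open(path, "w") as fh:
        for m in models:
            attrs = (
                f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                f'biotype "{m.biotype}";'
            )
            for s, e in m.exons:
                fh.write(
                    f"{m.chrom}\tsvfw\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_span is not None:
                cs, ce = m.cds_span
                fh.write(
                    f"{m.chrom}\tsvfw\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{attrs}\n"
                )


def read_gtf(path: str | Path) -> list[GeneModel]:
    exons: dict[str, GeneModel] = {}
    cds: dict[str, tuple[int, int]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _src, feat, start, end, _score, strand, _frame, attr = (
                line.rstrip("\n").split("\t")
            )
            a = dict(_ATTR_RE.findall(attr))
            tid = a["transcript_id"]
            s, e = int(start) - 1, int(end)
            if feat == "exon":
                if tid not in exons:
                    exons[tid] = GeneModel(
                        gene_id=a["gene_id"], transcript_id=tid, chrom=chrom,
                        strand=strand, exons=[], cds_span=None,
                        biotype=a.get("biotype", "coding"),
                    )
                    order.append(tid)
                exons[tid].exons.append((s, e))
            elif feat == "CDS":
                cds[tid] = (s, e)
    models = []
    for tid in order:
        m = exons[tid]
        m.exons.sort()
        m.cds_span = cds.get(tid)
        if m.cds_span is None:
            m.biotype = "noncoding"
        models.append(m)
    return models


# ---------------------------------------------------------------------------
# BED masks (0-based half-open, unchanged)

def write_bed(path: str | Path, intervals: dict[str, list[tuple[int, int]]]) -> None:
    with open(path, "w") as fh:
        for chrom in intervals:
            for s, e in intervals[chrom]:
                fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    out: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, s, e = line.split()[:3]
            out.setdefault(chrom, []).append((int(s), int(e)))
    for ivs in out.values():
        ivs.sort()
    return out


def write_masks(outdir: str | Path, genome: ReferenceGenome) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mask, per_chrom in genome.masks.items():
        write_bed(outdir / f"{mask}.bed", per_chrom)


def read_masks(maskdir: str | Path) -> dict[str, dict[str, list[tuple[int, int]]]]:
    maskdir = Path(maskdir)
    return {p.stem: read_bed(p) for p in sorted(maskdir.glob("*.bed"))}


# ---------------------------------------------------------------------------
# minimal SAM (mandatory columns + MAPQ)

def write_sam(path: str | Path, genome: ReferenceGenome,
              alignments: list) -> None:
    """alignments: Alignment records (unmapped ones get flag 4, pos 0)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in genome.chromosomes.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for aln, seq in alignments:
            flag = 64 if aln.mate == 1 else 128
            flag |= 1
            if not aln.is_mapped:
                fh.write(f"{aln.read_id}\t{flag | 4}\t*\t0\t0\t*\t*\t0\t0\t{seq}\t*\n")
                continue
            if aln.strand == "-":
                flag |= 16
            cigar = f"{aln.end - aln.start}M"
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.chrom}\t{aln.start + 1}\t{aln.mapq}"
                f"\t{cigar}\t*\t0\t0\t{seq}\t*\n"
            )


# ---------------------------------------------------------------------------
# TSV tables

def truth_to_frame(svs: list[PlantedSV]) -> pd.DataFrame:
    rows = []
    for sv in svs:
        d = sv.__dict__.copy()
        d["samples"] = ",".join(sv.samples)
        rows.append(d)
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def frame_to_truth(df: pd.DataFrame) -> list[PlantedSV]:
    out = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        d["samples"] = tuple(str(d["samples"]).split(","))
        d["transcribed"] = bool(d["transcribed"])
        out.append(PlantedSV(**d))
    return out


def calls_to_frame(calls: list[SVCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(call, c) for c in CALL_COLUMNS} for call in calls],
        columns=CALL_COLUMNS,
    )


def frame_to_calls(df: pd.DataFrame) -> list[SVCall]:
    return [SVCall(**{c: row._asdict()[c] for c in CALL_COLUMNS})
            for row in df.itertuples(index=False)]


def validated_to_frame(svs: list[ValidatedSV]) -> pd.DataFrame:
    return pd.DataFrame(
        [{c: getattr(sv, c) for c in VALIDATED_COLUMNS} for sv in svs],
        columns=VALIDATED_COLUMNS,
    )


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
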