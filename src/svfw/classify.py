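"""Cross-sample deduplication, germline/somatic partitioning, and the
breakpoint taxonomy (intergenic / intragenic / gene-desert with subclasses).

Fusion-partner assignment works per junction: the 5' partner is the gene whose
transcription reads *into* the junction on the donor-upstream side, the 3'
partner the gene reading *away* on the downstream side. Each SV type implies
one or two junction configurations over its breakpoint pair (e.g. a reciprocal
translocation has two); a configuration with no valid 5'->3' layout fails, and
an SV whose configurations all fail is an uncharacterized RNA.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree

from . import transcripts as tx
from .models import GeneModel, UniqueSV, ValidatedSV

PROMOTER_SIZE = 5000
INTERGENIC_PRECEDENCE = [
    "promoter",
    "alt_5utr",
    "coding_fusion",
    "alt_3utr",
    "five_prime_truncated",
]
EXONIC_PRECEDENCE = ["cds", "utr5", "utr3", "noncoding_exon"]


class GeneIndex:
    """Interval lookup of gene bodies and promoter windows, canonical per gene."""

    def __init__(self, models: list[GeneModel], promoter_size: int = PROMOTER_SIZE):
        self.promoter_size = promoter_size
        by_gene: dict[str, list[GeneModel]] = defaultdict(list)
        for m in models:
            by_gene[m.gene_id].append(m)
        self.canonical: dict[str, GeneModel] = {
            g: tx.canonical_transcript(ms) for g, ms in by_gene.items()
        }
        self._body: dict[str, IntervalTree] = defaultdict(IntervalTree)
        self._assoc: dict[str, IntervalTree] = defaultdict(IntervalTree)
        for g, m in self.canonical.items():
            self._body[m.chrom][m.start : m.end] = g
            lo, hi = m.promoter_window(promoter_size)
            self._assoc[m.chrom][min(lo, m.start) : max(hi, m.end)] = g

    def known_chrom(self, chrom: str) -> bool:
        return True  # association trees are sparse; unknown chroms just miss

    def genes_at(self, chrom: str, pos: int) -> list[str]:
        return sorted({iv.data for iv in self._assoc[chrom][pos]})

    def body_genes_at(self, chrom: str, pos: int) -> list[str]:
        return sorted({iv.data for iv in self._body[chrom][pos]})

    def associated_gene(self, chrom: str, pos: int) -> GeneModel | None:
        """Single gene associated with a position: gene bodies outrank
        promoter-window hits; residual ties break on gene id."""
        body = self.body_genes_at(chrom, pos)
        if body:
            return self.canonical[body[0]]
        hits = self.genes_at(chrom, pos)
        return self.canonical[hits[0]] if hits else None


# ---------------------------------------------------------------------------
# location classes


def classify_location(sv: UniqueSV, index: GeneIndex) -> tuple[str, GeneModel | None, GeneModel | None]:
    """intergenic / intragenic / gene_desert plus the associated gene models."""
    ga = index.associated_gene(sv.chromA, sv.posA)
    gb = index.associated_gene(sv.chromB, sv.posB)
    if ga is None and gb is None:
        return "gene_desert", None, None
    if ga is not None and gb is not None and ga.gene_id == gb.gene_id:
        return "intragenic", ga, gb
    return "intergenic", ga, gb


# ---------------------------------------------------------------------------
# junction geometry

# For each SV type: the junction configurations implied by its breakpoint pair.
# Each configuration is ((bp_label, orient_X), (bp_label, orient_Y)) where X is
# the side ending at the junction and Y the side starting at it; orient 'L'
# means the reference sequence left of the breakpoint forms that side ('R'
# implies the side is reverse-complemented when it ends at the junction, and
# vice versa).
JUNCTION_CONFIGS: dict[str, list[tuple[tuple[str, str], tuple[str, str]]]] = {
    "deletion": [(("A", "L"), ("B", "R"))],
    "insertion": [(("A", "L"), ("B", "R"))],
    "transposition": [(("A", "L"), ("B", "R"))],
    "inversion": [(("A", "L"), ("B", "L")), (("A", "R"), ("B", "R"))],
    "tandem_duplication": [(("B", "L"), ("A", "R"))],
    "inverted_duplication": [(("B", "L"), ("B", "L")), (("A", "R"), ("B", "R"))],
    "translocation": [(("A", "L"), ("B", "R")), (("B", "L"), ("A", "R"))],
}


def _feeds_junction(strand: str, orient: str) -> bool:
    # X side: transcription runs toward the junction
    return (orient == "L") == (strand == "+")


def _reads_away(strand: str, orient: str) -> bool:
    # Y side: transcription runs away from the junction
    return (orient == "R") == (strand == "+")


def _region_at_junction(model: GeneModel, bp: int, role: str) -> str:
    """Genic region of the breakpoint; intronic breakpoints are evaluated at
    the retained exon boundary (transcripts lose introns)."""
    region = tx.region_of(model, bp, PROMOTER_SIZE)
    if region != "intron":
        return region
    b = tx.adjust_breakpoint_to_exon(bp, model, role)
    probe = b - 1 if (role == "5_prime") == (model.strand == "+") else b
    return tx.region_of(model, probe, PROMOTER_SIZE)


def frame_for_fusion(bp5: int, m5: GeneModel, bp3: int, m3: GeneModel) -> str:
    """Frame of a coding 5' partner joined at bp5 to partner m3 at bp3.

    Junctions upstream of the 3' CDS retain the whole ORF (c3 = 0); junctions
    past its stop leave no ORF to continue and are out of frame.
    """
    b5 = tx.adjust_breakpoint_to_exon(bp5, m5, "5_prime")
    b3 = tx.adjust_breakpoint_to_exon(bp3, m3, "3_prime")
    c5 = tx.coding_prefix_len(m5, b5)
    cs3, ce3 = tx.cds_transcript_interval(m3)
    t3 = tx.retained_prefix_len(m3, b3)
    if t3 >= ce3:
        return "out_of_frame"
    c3 = max(0, t3 - cs3)
    return "in_frame" if c5 % 3 == c3 % 3 else "out_of_frame"


def subclassify_intergenic(
    sv: UniqueSV, index: GeneIndex
) -> tuple[str, str, str, str]:
    """Returns (subclass, frame, partner_5, partner_3)."""
    bps = {"A": (sv.chromA, sv.posA), "B": (sv.chromB, sv.posB)}
    configs = JUNCTION_CONFIGS.get(sv.sv_type, [(("A", "L"), ("B", "R"))])
    candidates: list[tuple[str, str, str, str]] = []
    for (lx, ox), (ly, oy) in configs:
        cx, px = bps[lx]
        cy, py = bps[ly]
        gx = index.associated_gene(cx, px)
        gy = index.associated_gene(cy, py)
        if gx is None or gx.biotype != "coding":
            continue
        if not _feeds_junction(gx.strand, ox):
            continue
        role5 = "5_prime" if ox == "L" or gx.strand == "-" else "5_prime"
        if gy is None or gy.biotype != "coding":
            sub = "five_prime_truncated"
            region5 = _region_at_junction(gx, px, "5_prime")
            if region5 == "promoter":
                continue  # no gene material truncated; not evaluable
            candidates.append((sub, "not_applicable", gx.gene_id, gy.gene_id if gy else ""))
            continue
        if gy.gene_id == gx.gene_id or not _reads_away(gy.strand, oy):
            continue
        region5 = _region_at_junction(gx, px, "5_prime")
        if region5 == "promoter":
            sub, frame = "promoter", "not_applicable"
        elif region5 == "utr5":
            sub, frame = "alt_5utr", "not_applicable"
        elif region5 == "cds":
            sub = "coding_fusion"
            frame = frame_for_fusion(px, gx, py, gy)
        elif region5 == "utr3":
            sub, frame = "alt_3utr", "not_applicable"
        else:
            continue
        candidates.append((sub, frame, gx.gene_id, gy.gene_id))
    if not candidates:
        return "uncharacterized_rna", "not_applicable", "", ""
    candidates.sort(key=lambda c: INTERGENIC_PRECEDENCE.index(c[0]))
    return candidates[0]


def subclassify_intragenic(sv: UniqueSV, model: GeneModel) -> str:
    regions = []
    for chrom, pos in ((sv.chromA, sv.posA), (sv.chromB, sv.posB)):
        if chrom == model.chrom and model.start <= pos < model.end:
            regions.append(tx.region_of(model, pos, PROMOTER_SIZE))
        else:
            regions.append("outside")
    exonic = [r for r in regions if r in EXONIC_PRECEDENCE]
    if not exonic:
        return "intronic"
    exonic.sort(key=EXONIC_PRECEDENCE.index)
    return {
        "cds": "exonic_cds_disruptive",
        "utr5": "exonic_5utr",
        "utr3": "exonic_3utr",
        "noncoding_exon": "exonic_noncoding",
    }[exonic[0]]


# ---------------------------------------------------------------------------
# deduplication and origin


def dedupe_svs(
    validated: list[tuple[str, str, ValidatedSV]], tolerance_bp: int = 10
) -> list[UniqueSV]:
    """Merge per-sample validated SVs into unique SVs.

    ``validated``: (patient_id, tissue, sv) triples over the whole cohort.
    Identity: same sv_type and chromosome pair with both breakpoints within
    ``tolerance_bp`` (transitive closure); canonical coordinates are the
    smallest in the group.
    """
    items = list(validated)
    n = len(items)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    buckets: dict[tuple, list[int]] = defaultdict(list)
    for i, (_p, _t, sv) in enumerate(items):
        buckets[(sv.sv_type, sv.chromA, sv.chromB)].append(i)
    for idxs in buckets.values():
        idxs.sort(key=lambda i: items[i][2].posA)
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                i, j = idxs[a], idxs[b]
                si, sj = items[i][2], items[j][2]
                if sj.posA - si.posA > tolerance_bp:
                    break
                if abs(sj.posB - si.posB) <= tolerance_bp:
                    union(i, j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(n):
        groups[find(i)].append(i)

    uniques: list[UniqueSV] = []
    for gi, members in enumerate(groups.values()):
        svs = [items[i][2] for i in members]
        rep = min(svs, key=lambda s: (s.chromA, s.posA, s.chromB, s.posB))
        carriers: dict[str, set[str]] = defaultdict(set)
        for i in members:
            patient, tissue, _sv = items[i]
            carriers[patient].add(tissue)
        cmap = {
            p: ("both" if ts == {"tumor", "blood"} else next(iter(ts)))
            for p, ts in carriers.items()
        }
        uniques.append(
            UniqueSV(
                sv_id=f"U{gi + 1:04d}",
                sv_type=rep.sv_type,
                chromA=rep.chromA,
                posA=rep.posA,
                chromB=rep.chromB,
                posB=rep.posB,
                carriers=cmap,
                multiplicity=sum(1 for v in cmap.values() if v in ("tumor", "both")),
            )
        )
    uniques.sort(key=lambda u: (u.chromA, u.posA, u.chromB, u.posB, u.sv_type))
    for i, u in enumerate(uniques):
        u.sv_id = f"U{i + 1:04d}"
    return uniques


def partition_origin(uniques: list[UniqueSV]) -> dict[str, int]:
    """Fill origin labels; germline = seen in >=1 tumor and >=1 blood sample,
    somatic = tumor-only, blood_only = blood-only."""
    counts = {"germline": 0, "somatic": 0, "blood_only": 0}
    for u in uniques:
        if not u.carriers:
            raise ValueError(f"{u.sv_id} has no carriers")
        tissues = set()
        for v in u.carriers.values():
            tissues.update({"tumor", "blood"} if v == "both" else {v})
        if "tumor" in tissues and "blood" in tissues:
            u.origin = "germline"
        elif "tumor" in tissues:
            u.origin = "somatic"
        else:
            u.origin = "blood_only"
        counts[u.origin] += 1
    return counts


def multiplicity_table(uniques: list[UniqueSV], n_samples: int) -> pd.DataFrame:
    """Histogram of multiplicity x origin with per-origin percentages."""
    rows = []
    for origin in ("germline", "somatic"):
        svs = [u for u in uniques if u.origin == origin]
        total = len(svs)
        for m in range(1, n_samples + 1):
            c = sum(1 for u in svs if u.multiplicity == m)
            rows.append(
                {
                    "multiplicity": m,
                    "origin": origin,
                    "count": c,
                    "percent": round(100.0 * c / total, 1) if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def annotate_svs(uniques: list[UniqueSV], models: list[GeneModel]) -> list[UniqueSV]:
    """Assign location class, subclass, frame and partner genes in place."""
    index = GeneIndex(models)
    known = set()
    for m in models:
        known.add(m.chrom)
    for u in uniques:
        loc, ga, gb = classify_location(u, index)
        u.location_class = loc
        if loc == "intergenic":
            sub, frame, p5, p3 = subclassify_intergenic(u, index)
            u.subclass, u.frame, u.partner_5, u.partner_3 = sub, frame, p5, p3
        elif loc == "intragenic":
            u.subclass = subclassify_intragenic(u, ga)
            u.frame = "not_applicable"
            u.partner_5 = u.partner_3 = ga.gene_id
        else:
            u.subclass = "none"
            u.frame = "not_applicable"
            u.partner_5 = u.partner_3 = ""
    return uniques
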