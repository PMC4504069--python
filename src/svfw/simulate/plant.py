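"""Plant structural variants into matched tumor/blood donor genomes.

Donor chromosomes are represented as lists of reference segments (plus novel
insertions), so every edit is expressed in reference coordinates and truth
breakpoints fall out exactly. Placements are rejected when a junction would
carry micro-homology (the validator could then not recover the planted
coordinate base-exactly) or when a breakpoint's gene association would be
ambiguous, keeping the truth set unambiguous by construction.

The default roster covers all seven structural classes and every taxonomy
subclass of the breakpoint annotation (promoter / alternative UTR / coding
fusion in- and out-of-frame / 5'-truncated / uncharacterized; intronic and
the exonic subclasses; gene-desert SVs), with germline SVs shared across
patients and somatic SVs private to tumors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .._seq import random_dna, revcomp
from ..classify import GeneIndex
from ..models import GeneModel, PlantedSV, ReferenceGenome
from .. import transcripts as tx
from .genome import INTERIOR_GUARD

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class PlacementError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# donor genome as reference segments


class DonorGenome:
    """An edited genome built from reference segments and novel sequence."""

    def __init__(self, genome: ReferenceGenome):
        self.ref = genome
        self.chroms: dict[str, list[tuple]] = {
            name: [("ref", name, 0, len(seq), "+")]
            for name, seq in genome.chromosomes.items()
        }

    def _find(self, chrom: str, pos: int) -> tuple[str, int]:
        for name, segs in self.chroms.items():
            for i, s in enumerate(segs):
                if s[0] == "ref" and s[1] == chrom and s[4] == "+" and s[2] <= pos < s[3]:
                    return name, i
        raise ValueError(f"reference position {chrom}:{pos} not pristine in donor")

    def _cut(self, chrom: str, pos: int) -> None:
        name, i = self._find(chrom, pos)
        _, c, s, e, _ = self.chroms[name][i]
        if pos > s:
            self.chroms[name][i : i + 1] = [("ref", c, s, pos, "+"), ("ref", c, pos, e, "+")]

    def _index_at(self, chrom: str, pos: int) -> tuple[str, int]:
        for name, segs in self.chroms.items():
            for i, s in enumerate(segs):
                if s[0] == "ref" and s[1] == chrom and s[2] == pos and s[4] == "+":
                    return name, i
        raise ValueError(f"no segment boundary at {chrom}:{pos}")

    def apply(self, op: tuple) -> None:
        kind = op[0]
        if kind == "deletion":
            _, c, s, e = op
            self._cut(c, s)
            self._cut(c, e)
            name, i = self._index_at(c, s)
            _, j = self._index_at(c, e)
            del self.chroms[name][i:j]
        elif kind == "insertion":
            _, c, p, seq = op
            self._cut(c, p)
            name, i = self._index_at(c, p)
            self.chroms[name].insert(i, ("novel", seq))
        elif kind == "inversion":
            _, c, s, e = op
            self._cut(c, s)
            self._cut(c, e)
            name, i = self._index_at(c, s)
            self.chroms[name][i] = ("ref", c, s, e, "-")
        elif kind == "tandem_duplication":
            _, c, s, e = op
            self._cut(c, s)
            self._cut(c, e)
            name, i = self._index_at(c, s)
            self.chroms[name].insert(i, ("ref", c, s, e, "+"))
        elif kind == "inverted_duplication":
            _, c, s, e = op
            self._cut(c, s)
            self._cut(c, e)
            name, i = self._index_at(c, e)
            self.chroms[name].insert(i, ("ref", c, s, e, "-"))
        elif kind == "transposition":
            _, c, s, e, t = op
            self._cut(c, s)
            self._cut(c, e)
            name, i = self._index_at(c, s)
            _, j = self._index_at(c, e)
            moved = self.chroms[name][i:j]
            del self.chroms[name][i:j]
            self._cut(c, t)
            name2, k = self._index_at(c, t)
            self.chroms[name2][k:k] = moved
        elif kind == "translocation":
            _, c1, p1, c2, p2 = op
            self._cut(c1, p1)
            self._cut(c2, p2)
            n1, i = self._index_at(c1, p1)
            n2, j = self._index_at(c2, p2)
            if n1 == n2:
                raise ValueError("translocation breakpoints collapsed onto one donor chromosome")
            tail1, tail2 = self.chroms[n1][i:], self.chroms[n2][j:]
            self.chroms[n1] = self.chroms[n1][:i] + tail2
            self.chroms[n2] = self.chroms[n2][:j] + tail1
        else:
            raise ValueError(f"unknown op {kind}")

    def sequences(self) -> dict[str, str]:
        out = {}
        for name, segs in self.chroms.items():
            parts = []
            for s in segs:
                if s[0] == "novel":
                    parts.append(s[1])
                else:
                    _, c, a, b, strand = s
                    piece = self.ref.chromosomes[c][a:b]
                    parts.append(piece if strand == "+" else revcomp(piece))
            out[name] = "".join(parts)
        return out


# ---------------------------------------------------------------------------
# junction micro-homology screening

# A junction side is ("ref", chrom, pos, 'L'|'R') or ("novel", seq). For the X
# side (ends at the junction) 'L' is the forward sequence left of pos and 'R'
# the reverse-complemented sequence right of pos; for the Y side (starts at
# the junction) 'R' is forward-right and 'L' reverse-complemented-left.


def _x_chars(genome, side):
    if side[0] == "novel":
        return side[1][-1], None
    _, c, pos, o = side
    seq = genome.chromosomes[c]
    if o == "L":
        return seq[pos - 1], seq[pos]
    return _COMP[seq[pos]], _COMP[seq[pos - 1]]


def _y_chars(genome, side):
    if side[0] == "novel":
        return side[1][0], None
    _, c, pos, o = side
    seq = genome.chromosomes[c]
    if o == "R":
        return seq[pos], seq[pos - 1]
    return _COMP[seq[pos - 1]], _COMP[seq[pos]]


def junction_clean(genome: ReferenceGenome, x_side, y_side) -> bool:
    """True when neither flank extends across the junction (zero homology)."""
    last_x, cont_x = _x_chars(genome, x_side)
    first_y, prec_y = _y_chars(genome, y_side)
    if cont_x is not None and first_y == cont_x:
        return False
    if prec_y is not None and last_x == prec_y:
        return False
    return True


def op_junctions(op: tuple) -> list[tuple]:
    kind = op[0]
    if kind == "deletion":
        _, c, s, e = op
        return [(("ref", c, s, "L"), ("ref", c, e, "R"))]
    if kind == "insertion":
        _, c, p, seq = op
        return [(("ref", c, p, "L"), ("novel", seq)), (("novel", seq), ("ref", c, p, "R"))]
    if kind == "inversion":
        _, c, s, e = op
        return [
            (("ref", c, s, "L"), ("ref", c, e, "L")),
            (("ref", c, s, "R"), ("ref", c, e, "R")),
        ]
    if kind == "tandem_duplication":
        _, c, s, e = op
        return [(("ref", c, e, "L"), ("ref", c, s, "R"))]
    if kind == "inverted_duplication":
        _, c, s, e = op
        return [
            (("ref", c, e, "L"), ("ref", c, e, "L")),
            (("ref", c, s, "R"), ("ref", c, e, "R")),
        ]
    if kind == "transposition":
        _, c, s, e, t = op
        return [
            (("ref", c, s, "L"), ("ref", c, e, "R")),
            (("ref", c, t, "L"), ("ref", c, s, "R")),
            (("ref", c, e, "L"), ("ref", c, t, "R")),
        ]
    if kind == "translocation":
        _, c1, p1, c2, p2 = op
        return [
            (("ref", c1, p1, "L"), ("ref", c2, p2, "R")),
            (("ref", c2, p2, "L"), ("ref", c1, p1, "R")),
        ]
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# configuration and roster


@dataclass
class RosterEntry:
    sv_type: str
    category: str
    origin: str  # germline | somatic | blood_only
    transcribed: bool = False
    expressed_change: float = 1.0
    min_carriers: int = 1


def default_roster() -> list[RosterEntry]:
    R = RosterEntry
    return [
        # intergenic taxonomy
        R("translocation", "promoter", "somatic", False, 4.0),
        R("deletion", "promoter", "germline", False, 0.2),
        R("deletion", "promoter", "somatic", False, 1.0),
        R("deletion", "alt_5utr", "somatic", True, 3.0),
        R("deletion", "alt_5utr", "germline", False, 1.0),
        R("deletion", "alt_3utr", "somatic", True, 0.25),
        R("deletion", "alt_3utr", "germline", False, 1.0),
        R("translocation", "coding_inframe", "somatic", True, 1.0),
        R("translocation", "coding_inframe", "somatic", True, 1.0),
        R("deletion", "coding_inframe", "somatic", True, 1.0),
        R("deletion", "coding_outframe", "somatic", True, 1.0),
        R("translocation", "coding_outframe", "germline", False, 1.0),
        R("deletion", "coding_outframe", "somatic", False, 1.0),
        R("deletion", "five_prime_truncated", "somatic", True, 1.0),
        R("deletion", "five_prime_truncated", "germline", False, 1.0),
        R("deletion", "five_prime_truncated_desert", "somatic", False, 1.0),
        R("deletion", "uncharacterized", "somatic", False, 1.0),
        R("deletion", "uncharacterized", "germline", False, 1.0),
        # intragenic taxonomy
        R("deletion", "intronic", "germline"),
        R("deletion", "intronic", "germline"),
        R("deletion", "intronic", "somatic"),
        R("deletion", "intronic", "somatic"),
        R("deletion", "intronic_minus", "germline"),
        R("inversion", "intronic_single", "somatic"),
        R("inversion", "intronic_span", "germline"),
        R("insertion", "intronic_point", "somatic"),
        R("tandem_duplication", "intronic_single", "germline"),
        R("deletion", "exonic_5utr", "somatic"),
        R("deletion", "exonic_3utr", "somatic"),
        R("deletion", "exonic_3utr", "germline"),
        R("deletion", "exonic_cds", "somatic"),
        R("deletion", "exonic_cds", "germline"),
        R("deletion", "exonic_noncoding", "somatic"),
        R("deletion", "exonic_noncoding", "germline"),
        # gene deserts, all classes
        R("deletion", "desert", "germline"),
        R("deletion", "desert", "germline"),
        R("deletion", "desert", "somatic"),
        R("deletion", "desert", "somatic"),
        R("deletion", "desert", "somatic"),
        R("inversion", "desert", "germline"),
        R("inversion", "desert", "somatic"),
        R("tandem_duplication", "desert", "germline"),
        R("tandem_duplication", "desert", "somatic"),
        R("inverted_duplication", "desert", "germline"),
        R("inverted_duplication", "desert", "somatic"),
        R("inverted_duplication", "desert", "somatic"),
        # germline insertions segregate across individuals; two or more
        # carriers keep their origin identifiable at marginal read support
        R("insertion", "desert", "germline", min_carriers=2),
        R("insertion", "desert", "somatic"),
        R("insertion", "desert", "somatic"),
        R("transposition", "desert", "germline"),
        R("transposition", "desert", "germline"),
        R("transposition", "desert", "somatic"),
        R("transposition", "desert", "somatic"),
        # blood-only background variation
        R("deletion", "desert", "blood_only"),
        R("deletion", "desert", "blood_only"),
    ]


@dataclass
class PlantConfig:
    seed: int = 2
    patients: tuple[str, ...] = ("P1", "P2", "P3", "P4", "P5", "P6")
    roster: list[RosterEntry] = field(default_factory=default_roster)
    padding: int = 1000
    max_retries: int = 400
    germline_carrier_probs: tuple[float, ...] = (0.45, 0.25, 0.15, 0.08, 0.05, 0.02)
    somatic_carrier_probs: tuple[float, ...] = (0.94, 0.06)


@dataclass
class PlantResult:
    truth: list[PlantedSV]
    ops: dict[str, tuple]
    patients: tuple[str, ...]
    genome: ReferenceGenome

    def donor(self, patient: str, tissue: str) -> DonorGenome:
        donor = DonorGenome(self.genome)
        svs = [sv for sv in self.truth if patient in sv.samples and _in_tissue(sv, tissue)]
        trans = [sv for sv in svs if sv.sv_type == "translocation"]
        others = [sv for sv in svs if sv.sv_type != "translocation"]
        for sv in sorted(trans, key=lambda s: s.posA) + others:
            donor.apply(self.ops[sv.sv_id])
        return donor


def _in_tissue(sv: PlantedSV, tissue: str) -> bool:
    if sv.origin == "germline":
        return True
    if sv.origin == "somatic":
        return tissue == "tumor"
    return tissue == "blood"  # blood_only


# ---------------------------------------------------------------------------
# the planter


class _Planter:
    def __init__(self, genome, models, deserts, config):
        self.genome = genome
        self.models = models
        self.deserts = deserts
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.index = GeneIndex(models)
        self.occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in genome.chromosomes}
        self.used_genes: set[str] = set()
        self.main_chroms = [c for c in genome.chromosomes if not genome.is_excluded(c)]
        self.genes_by_chrom: dict[str, list[GeneModel]] = {c: [] for c in self.main_chroms}
        for m in models:
            self.genes_by_chrom[m.chrom].append(m)
        for lst in self.genes_by_chrom.values():
            lst.sort(key=lambda m: m.start)
        # translocation monotonicity cursors (chr1 position, chr2 position)
        self.tl_cursor = [0, 0]
        self.truth: list[PlantedSV] = []
        self.ops: dict[str, tuple] = {}

    # -- geometry helpers ---------------------------------------------------

    def _window_clean(self, chrom: str, pos: int, w: int = 200) -> bool:
        length = len(self.genome.chromosomes[chrom])
        if not (INTERIOR_GUARD <= pos < length - INTERIOR_GUARD):
            return False
        lo, hi = pos - w, pos + w
        for mask in self.genome.masks.values():
            for s, e in mask.get(chrom, []):
                if s < hi and lo < e:
                    return False
        return True

    def _free(self, chrom: str, lo: int, hi: int) -> bool:
        return all(hi + self.cfg.padding <= s or lo - self.cfg.padding >= e
                   for s, e in self.occupied[chrom])

    def _reserve(self, chrom: str, lo: int, hi: int) -> None:
        self.occupied[chrom].append((lo - self.cfg.padding, hi + self.cfg.padding))

    def _assoc_ok(self, chrom: str, pos: int, expect: str | None) -> bool:
        """The breakpoint associates with the intended gene under the
        classifier's rules (gene bodies outrank promoter windows; a
        window-only association must be unique)."""
        hits = self.index.genes_at(chrom, pos)
        if expect is None:
            return not hits
        body = self.index.body_genes_at(chrom, pos)
        if body:
            return body == [expect]
        return hits == [expect]

    def _clean_op(self, op: tuple) -> bool:
        return all(junction_clean(self.genome, x, y) for x, y in op_junctions(op))

    def _ri(self, lo: int, hi: int) -> int:
        return int(self.rng.integers(lo, hi))

    # -- gene pickers -------------------------------------------------------

    def _adjacent_pairs(self, strandB="+", biotypeB="coding", max_between=2):
        """Candidate (5' gene, 3' gene, co-deleted genes between) triples for
        a same-chromosome deletion fusion. Up to ``max_between`` unused genes
        may sit between the partners (the fusion deletion removes them); the
        spanned interval must not cross a gene desert."""
        pairs = []
        for chrom in self.main_chroms:
            genes = self.genes_by_chrom[chrom]
            for i, a in enumerate(genes):
                if a.gene_id in self.used_genes or a.strand != "+" or a.biotype != "coding":
                    continue
                for j in range(i + 1, min(i + 2 + max_between, len(genes))):
                    b = genes[j]
                    if b.gene_id in self.used_genes:
                        continue
                    between = genes[i + 1 : j]
                    if any(m.gene_id in self.used_genes for m in between):
                        break
                    if b.strand != strandB or b.biotype != biotypeB:
                        continue
                    gap = b.start - a.end
                    if not 3000 <= gap <= 28000:
                        continue
                    if any(
                        d[0] < b.start and a.end < d[1]
                        for d in self.deserts.get(chrom, [])
                    ):
                        continue
                    pairs.append((a, b, between))
        # prefer truly adjacent pairs so intervening genes are not wasted
        pairs.sort(key=lambda p: (len(p[2]), p[1].start - p[0].end))
        return pairs[:8]

    def _pick(self, items):
        if not items:
            raise PlacementError("no candidates")
        return items[self._ri(0, len(items))]

    def _free_gene(self, strand=None, biotype="coding", chrom=None, min_intron=0, pred=None):
        cands = []
        for m in self.models:
            if m.gene_id in self.used_genes:
                continue
            if strand and m.strand != strand:
                continue
            if m.biotype != biotype:
                continue
            if chrom and m.chrom != chrom:
                continue
            if min_intron and max(self._introns_len(m), default=0) < min_intron:
                continue
            if pred and not pred(m):
                continue
            cands.append(m)
        return cands

    @staticmethod
    def _introns(m: GeneModel) -> list[tuple[int, int]]:
        return [(e1, s2) for (_s1, e1), (s2, _e2) in zip(m.exons, m.exons[1:])]

    def _introns_len(self, m):
        return [b - a for a, b in self._introns(m)]

    def _cds_pos(self, m: GeneModel, phase: int | None, margin: int = 25) -> int:
        """An exonic CDS position, optionally with a required coding-prefix phase."""
        cs, ce = m.cds_span
        cands = []
        for s, e in m.exons:
            lo, hi = max(s, cs) + margin, min(e, ce) - margin
            for g in range(lo, hi):
                if phase is None or tx.coding_prefix_len(m, g) % 3 == phase:
                    cands.append(g)
        if not cands:
            raise PlacementError(f"no CDS position with phase {phase} in {m.gene_id}")
        return self._pick(cands)

    def _utr_pos(self, m: GeneModel, which: str, margin: int = 15,
                 min_prefix: int = 0, min_suffix: int = 0) -> int:
        """An exonic UTR position; optional floors on the retained transcript
        prefix/suffix keep fusion transcripts long enough on both sides for
        spanning-pair evidence (a whole read must fit in each partner)."""
        cs, ce = m.cds_span
        if (which == "utr5") == (m.strand == "+"):
            lo, hi = m.start + margin, cs - margin  # genomic-left UTR
        else:
            lo, hi = ce + margin, m.end - margin
        tlen = tx.transcript_length(m)
        cands = []
        for g in range(lo, hi):
            if tx.region_of(m, g) not in ("utr5", "utr3"):
                continue
            prefix = tx.retained_prefix_len(m, g)
            if prefix < min_prefix or tlen - prefix < min_suffix:
                continue
            cands.append(g)
        if not cands:
            raise PlacementError(f"no {which} position in {m.gene_id}")
        return self._pick(cands)

    def _desert_span(self, size: int, chrom=None):
        """A free interval of the given size inside a desert: enumerate the
        unoccupied sub-windows of every desert and draw one."""
        windows: list[tuple[str, int, int]] = []
        for c, ivs in self.deserts.items():
            if chrom and c != chrom:
                continue
            lc = [(s - 250, e + 250) for s, e in
                  self.genome.mask_intervals("low_complexity", c)]
            for dlo, dhi in ivs:
                free = [(dlo + 1500, dhi - 1500)]
                for olo, ohi in sorted(self.occupied[c] + lc):
                    nxt = []
                    for flo, fhi in free:
                        if ohi <= flo or olo >= fhi:
                            nxt.append((flo, fhi))
                            continue
                        if olo > flo:
                            nxt.append((flo, olo))
                        if ohi < fhi:
                            nxt.append((ohi, fhi))
                    free = nxt
                pad = self.cfg.padding
                windows.extend(
                    (c, flo + pad, fhi - pad - size)
                    for flo, fhi in free
                    if fhi - flo >= size + 2 * pad + 1
                )
        if not windows:
            raise PlacementError("no free desert span")
        weights = np.array([hi - lo for _c, lo, hi in windows], float)
        c, lo, hi = windows[int(self.rng.choice(len(windows), p=weights / weights.sum()))]
        return c, self._ri(lo, max(lo + 1, hi))

    # -- per-category proposals --------------------------------------------

    def propose(self, entry: RosterEntry) -> tuple[tuple, PlantedSV]:
        cat, svt = entry.category, entry.sv_type
        if cat in ("promoter", "alt_5utr", "alt_3utr", "coding_inframe",
                   "coding_outframe", "five_prime_truncated", "uncharacterized"):
            return self._propose_intergenic(entry)
        if cat == "five_prime_truncated_desert":
            return self._propose_trunc_desert(entry)
        if cat.startswith("intronic") or cat.startswith("exonic"):
            return self._propose_intragenic(entry)
        if cat == "desert":
            return self._propose_desert(entry)
        raise PlacementError(f"unknown category {cat}")

    def _fusion_positions(self, cat, a, b):
        """Breakpoints in partner genes A (5') and B (3') for a fusion class."""
        if cat == "promoter":
            pa = a.tss - self._ri(2500, 4500)
            pb = b.tss - self._ri(800, 1500)
        elif cat == "alt_5utr":
            pa = self._utr_pos(a, "utr5", min_prefix=120)
            pb = self._utr_pos(b, "utr5")
        elif cat == "alt_3utr":
            pa = self._utr_pos(a, "utr3")
            pb = self._utr_pos(b, "utr3", min_suffix=120)
        elif cat in ("coding_inframe", "coding_outframe"):
            pa = self._cds_pos(a, None)
            phase5 = tx.coding_prefix_len(a, pa) % 3
            want = phase5 if cat == "coding_inframe" else (phase5 + 1) % 3
            pb = self._cds_pos(b, want)
        elif cat == "five_prime_truncated":
            pa = self._cds_pos(a, None)
            pb = self._ri(b.start + 30, b.end - 30)
            if not tx.is_exonic(b, pb):
                raise PlacementError("retry noncoding position")
            if tx.transcript_length(b) - tx.retained_prefix_len(b, pb) < 120:
                raise PlacementError("3' suffix too short for spanning pairs")
        elif cat == "uncharacterized":
            pa = self._cds_pos(a, None)
            pb = self._cds_pos(b, None)
        else:
            raise PlacementError(cat)
        return pa, pb

    _SUBCLASS = {
        "promoter": "promoter",
        "alt_5utr": "alt_5utr",
        "alt_3utr": "alt_3utr",
        "coding_inframe": "coding_fusion",
        "coding_outframe": "coding_fusion",
        "five_prime_truncated": "five_prime_truncated",
        "five_prime_truncated_desert": "five_prime_truncated",
        "uncharacterized": "uncharacterized_rna",
    }

    def _truth_fusion(self, entry, svt, a, b, pa, pb, chromA, chromB, size):
        sub = self._SUBCLASS[entry.category]
        frame = "not_applicable"
        if sub == "coding_fusion":
            frame = "in_frame" if entry.category == "coding_inframe" else "out_of_frame"
        unchar = sub == "uncharacterized_rna"
        affected = ""
        if sub == "promoter" or sub == "alt_5utr":
            affected = b.gene_id
        elif sub == "alt_3utr":
            affected = a.gene_id
        return PlantedSV(
            sv_id="", sv_type=svt, chromA=chromA, posA=pa, chromB=chromB, posB=pb,
            size=size, origin=entry.origin, samples=(),
            transcribed=entry.transcribed, expressed_change=entry.expressed_change,
            location_class="intergenic", subclass=sub, frame=frame,
            gene5="" if unchar else a.gene_id,
            gene3="" if unchar else (b.gene_id if b is not None else ""),
            affected_gene=affected,
        )

    def _propose_intergenic(self, entry):
        cat, svt = entry.category, entry.sv_type
        if svt == "deletion":
            # an uncharacterized-orientation fusion joins onto a minus-strand
            # partner (both genes read into the junction -> no canonical layout)
            want_strandB = "-" if cat == "uncharacterized" else "+"
            want_biotypeB = "noncoding" if cat == "five_prime_truncated" else "coding"
            a, b, between = self._pick(self._adjacent_pairs(want_strandB, want_biotypeB))
            pa, pb = self._fusion_positions(cat, a, b)
            if pb <= pa + 150:
                raise PlacementError("fusion deletion too small")
            op = ("deletion", a.chrom, pa, pb)
            sv = self._truth_fusion(entry, svt, a, b, pa, pb, a.chrom, a.chrom, pb - pa)
            extents = [(a.chrom, pa, pb)]
            genes_used = (a, b, *between)
        elif svt == "translocation":
            c1, c2 = self.main_chroms[0], self.main_chroms[1]
            strandB = "-" if cat == "uncharacterized" else "+"
            # successive translocations must be coordinate-monotone on both
            # chromosomes so reciprocal tail swaps stay well defined
            cand_a = self._free_gene(strand="+", chrom=c1,
                                     pred=lambda m: m.start > self.tl_cursor[0] + 6000)
            cand_b = self._free_gene(strand=strandB, chrom=c2,
                                     pred=lambda m: m.start > self.tl_cursor[1] + 6000)
            a, b = self._pick(cand_a[:8]), self._pick(cand_b[:8])
            pa, pb = self._fusion_positions(cat, a, b)
            op = ("translocation", c1, pa, c2, pb)
            sv = self._truth_fusion(entry, svt, a, b, pa, pb, c1, c2, 0)
            extents = [(c1, pa, pa + 1), (c2, pb, pb + 1)]
            genes_used = (a, b)
        else:
            raise PlacementError(f"{svt} not supported for {cat}")
        self._check_fusion(cat, entry, a, b, pa, pb, op, extents)
        self._commit(op, sv, extents, genes=genes_used)
        return op, sv

    def _check_fusion(self, cat, entry, a, b, pa, pb, op, extents):
        expect_a = a.gene_id
        expect_b = b.gene_id if b is not None else None
        for chrom, pos, expect in (
            (extents[0][0], pa, expect_a),
            (extents[-1][0], pb, expect_b),
        ):
            if not self._window_clean(chrom, pos):
                raise PlacementError("masked breakpoint window")
            if not self._assoc_ok(chrom, pos, expect):
                raise PlacementError("ambiguous gene association")
        for chrom, lo, hi in extents:
            if not self._free(chrom, lo, hi):
                raise PlacementError("occupied")
        if not self._clean_op(op):
            raise PlacementError("junction homology")

    def _propose_trunc_desert(self, entry):
        # coding gene adjacent to a desert, deleted into it
        cands = []
        for chrom in self.main_chroms:
            genes = self.genes_by_chrom[chrom]
            for dlo, dhi in self.deserts.get(chrom, []):
                left = [m for m in genes if m.end < dlo and m.gene_id not in self.used_genes
                        and m.strand == "+" and m.biotype == "coding"]
                if not left:
                    continue
                a = left[-1]
                if any(m.start > a.end and m.end < dlo for m in genes):
                    continue  # another gene between A and the desert
                cands.append((a, chrom, dlo))
        a, chrom, dlo = self._pick(cands)
        pa = self._cds_pos(a, None)
        pb = dlo + self._ri(1500, 8000)
        op = ("deletion", chrom, pa, pb)
        sv = self._truth_fusion(entry, "deletion", a, None, pa, pb, chrom, chrom, pb - pa)
        extents = [(chrom, pa, pb)]
        self._check_fusion(entry.category, entry, a, None, pa, pb, op, extents)
        self._commit(op, sv, extents, genes=(a,))
        return op, sv

    def _propose_intragenic(self, entry):
        cat, svt = entry.category, entry.sv_type
        strand = "-" if cat == "intronic_minus" else "+"
        biotype = "noncoding" if cat == "exonic_noncoding" else "coding"
        g = self._pick(self._free_gene(strand=strand, biotype=biotype,
                                       min_intron=900)[:6])
        introns = self._introns(g)
        big = [iv for iv in introns if iv[1] - iv[0] >= 900]
        if not big:
            raise PlacementError("no long intron")
        if cat in ("intronic", "intronic_minus"):
            ilo, ihi = self._pick(big)
            size = self._ri(200, min(400, ihi - ilo - 80))
            s = self._ri(ilo + 25, ihi - size - 25)
            op = ("deletion", g.chrom, s, s + size)
            bpA, bpB = s, s + size
            sub = "intronic"
        elif cat == "intronic_single":
            ilo, ihi = self._pick([iv for iv in big if iv[1] - iv[0] >= 700 + 60])
            size = min(650, ihi - ilo - 60)
            if svt == "inversion":
                size = max(600, size)
            else:  # tandem duplication
                size = self._ri(500, max(501, size))
            s = self._ri(ilo + 25, max(ilo + 26, ihi - size - 25))
            op = (svt, g.chrom, s, s + size)
            bpA, bpB = s, s + size
            sub = "intronic"
        elif cat == "intronic_span":
            if len(introns) < 2:
                raise PlacementError("need two introns")
            i1 = self._pick(list(range(len(introns) - 1)))
            i2 = i1 + 1
            s = self._ri(introns[i1][0] + 25, introns[i1][1] - 25)
            e = self._ri(introns[i2][0] + 25, introns[i2][1] - 25)
            if e - s < 600:
                raise PlacementError("span too small")
            op = ("inversion", g.chrom, s, e)
            bpA, bpB, size = s, e, e - s
            sub = "intronic"
        elif cat == "intronic_point":
            ilo, ihi = self._pick(big)
            p = self._ri(ilo + 40, ihi - 40)
            seq = random_dna(self.rng, self._ri(106, 126))
            op = ("insertion", g.chrom, p, seq)
            bpA, bpB, size = p, p, len(seq)
            sub = "intronic"
        elif cat == "exonic_5utr":
            pa = self._utr_pos(g, "utr5")
            ilo, ihi = introns[0] if g.strand == "+" else introns[-1]
            pb = self._ri(ilo + 25, ihi - 25)
            s, e = min(pa, pb), max(pa, pb)
            if e - s < 150:
                raise PlacementError("too small")
            op = ("deletion", g.chrom, s, e)
            bpA, bpB, size = s, e, e - s
            sub = "exonic_5utr"
        elif cat == "exonic_3utr":
            pa = self._utr_pos(g, "utr3")
            ilo, ihi = introns[-1] if g.strand == "+" else introns[0]
            pb = self._ri(ilo + 25, ihi - 25)
            s, e = min(pa, pb), max(pa, pb)
            if e - s < 150:
                raise PlacementError("too small")
            op = ("deletion", g.chrom, s, e)
            bpA, bpB, size = s, e, e - s
            sub = "exonic_3utr"
        elif cat == "exonic_cds":
            pa = self._cds_pos(g, None)
            ex = tx.exon_containing(g, pa)
            if ex is None or ex >= len(introns):
                raise PlacementError("no following intron")
            ilo, ihi = introns[ex]
            pb = self._ri(ilo + 25, ihi - 25)
            s, e = min(pa, pb), max(pa, pb)
            if e - s < 150:
                raise PlacementError("too small")
            op = ("deletion", g.chrom, s, e)
            bpA, bpB, size = s, e, e - s
            sub = "exonic_cds_disruptive"
        elif cat == "exonic_noncoding":
            ex0 = g.exons[0]
            pa = self._ri(ex0[0] + 20, ex0[1] - 20)
            ilo, ihi = introns[0]
            pb = self._ri(ilo + 25, ihi - 25)
            s, e = min(pa, pb), max(pa, pb)
            if e - s < 150:
                raise PlacementError("too small")
            op = ("deletion", g.chrom, s, e)
            bpA, bpB, size = s, e, e - s
            sub = "exonic_noncoding"
        else:
            raise PlacementError(cat)

        for pos in (bpA, bpB):
            if not self._window_clean(g.chrom, pos):
                raise PlacementError("masked window")
            if not self._assoc_ok(g.chrom, pos, g.gene_id):
                raise PlacementError("ambiguous association")
        lo, hi = min(bpA, bpB), max(bpA, bpB) + 1
        if op[0] in ("tandem_duplication", "inverted_duplication"):
            hi += size
        if not self._free(g.chrom, lo, hi):
            raise PlacementError("occupied")
        if not self._clean_op(op):
            raise PlacementError("junction homology")
        sv = PlantedSV(
            sv_id="", sv_type=svt, chromA=g.chrom, posA=bpA, chromB=g.chrom,
            posB=bpB, size=size, origin=entry.origin, samples=(),
            transcribed=False, expressed_change=entry.expressed_change,
            location_class="intragenic", subclass=sub, frame="not_applicable",
            gene5=g.gene_id, gene3=g.gene_id,
        )
        self._commit(op, sv, [(g.chrom, lo, hi)], genes=(g,))
        return op, sv

    def _propose_desert(self, entry):
        svt = entry.sv_type
        if svt == "deletion":
            size = self._ri(200, 900)
        elif svt == "inversion":
            size = self._ri(650, 900)
        elif svt == "tandem_duplication":
            size = self._ri(500, 700)
        elif svt == "inverted_duplication":
            size = self._ri(700, 850)
        elif svt == "insertion":
            size = self._ri(106, 126)
        elif svt == "transposition":
            size = self._ri(110, 140)
        else:
            raise PlacementError(svt)
        span = size * (2 if svt in ("tandem_duplication", "inverted_duplication") else 1)
        chrom, s = self._desert_span(span + 200)
        extents = [(chrom, s, s + span)]
        if svt == "insertion":
            seq = random_dna(self.rng, size)
            op = ("insertion", chrom, s, seq)
            bpA = bpB = s
        elif svt == "transposition":
            e = s + size
            cands = [
                t
                for dlo, dhi in self.deserts[chrom]
                for t in range(dlo + 1500, dhi - 1500, 97)
                if abs(t - s) > 2500 and self._free(chrom, t, t + 1)
                and self._window_clean(chrom, t)
            ]
            if not cands:
                raise PlacementError("no transposition target")
            t = self._pick(cands)
            op = ("transposition", chrom, s, e, t)
            bpA, bpB = s, e
            extents = [(chrom, s, e), (chrom, t, t + 1)]
        else:
            op = (svt, chrom, s, s + size)
            bpA, bpB = s, s + size
        for pos in set([bpA, bpB] + ([op[4]] if svt == "transposition" else [])):
            if not self._window_clean(chrom, pos):
                raise PlacementError("masked window")
            if not self._assoc_ok(chrom, pos, None):
                raise PlacementError("gene too close to desert SV")
        for c, lo, hi in extents:
            if not self._free(c, lo, hi):
                raise PlacementError("occupied")
        if not self._clean_op(op):
            raise PlacementError("junction homology")
        sv = PlantedSV(
            sv_id="", sv_type=svt, chromA=chrom, posA=bpA, chromB=chrom, posB=bpB,
            size=size, origin=entry.origin, samples=(),
            location_class="gene_desert", subclass="none",
            target_pos=op[4] if svt == "transposition" else -1,
        )
        self._commit(op, sv, extents, genes=())
        return op, sv

    def _commit(self, op, sv, extents, genes):
        for c, lo, hi in extents:
            self._reserve(c, lo, hi)
        for g in genes:
            if g is not None:
                self.used_genes.add(g.gene_id)
        if op[0] == "translocation":
            self.tl_cursor[0] = max(self.tl_cursor[0], op[2])
            self.tl_cursor[1] = max(self.tl_cursor[1], op[4])
        sv.sv_id = f"SV{len(self.truth) + 1:03d}"
        self.truth.append(sv)
        self.ops[sv.sv_id] = op

    # -- carriers -----------------------------------------------------------

    def assign_carriers(self, min_carriers: dict[str, int] | None = None):
        min_carriers = min_carriers or {}
        patients = list(self.cfg.patients)
        for sv in self.truth:
            if sv.origin == "germline":
                probs = np.array(self.cfg.germline_carrier_probs[: len(patients)])
                n = 1 + int(self.rng.choice(len(probs), p=probs / probs.sum()))
            elif sv.origin == "somatic":
                probs = np.array(self.cfg.somatic_carrier_probs)
                n = 1 + int(self.rng.choice(len(probs), p=probs / probs.sum()))
            else:
                n = 1
            n = min(len(patients), max(n, min_carriers.get(sv.sv_id, 1)))
            chosen = self.rng.choice(len(patients), size=n, replace=False)
            sv.samples = tuple(sorted(patients[i] for i in chosen))


def plant_svs(
    genome: ReferenceGenome,
    models: list[GeneModel],
    deserts: dict[str, list[tuple[int, int]]],
    config: PlantConfig | None = None,
) -> PlantResult:
    """Place the roster's SVs, assign carriers, and return truth plus donor
    factory. Raises PlacementError naming the category when a placement cannot
    be satisfied within the retry budget."""
    config = config or PlantConfig()
    planter = _Planter(genome, models, deserts, config)

    def priority(entry: RosterEntry) -> int:
        # place entries with the scarcest gene requirements first
        if entry.category == "uncharacterized":
            return 0
        if entry.category in ("five_prime_truncated", "exonic_noncoding",
                              "five_prime_truncated_desert"):
            return 1
        if entry.sv_type == "translocation":
            return 2
        if entry.category in ("promoter", "alt_5utr", "alt_3utr",
                              "coding_inframe", "coding_outframe"):
            return 3
        if entry.sv_type in ("transposition", "inverted_duplication",
                             "tandem_duplication"):
            return 4  # need the largest free desert windows
        if entry.category.startswith(("intronic", "exonic")):
            return 5
        return 6

    min_carriers: dict[str, int] = {}
    for entry in sorted(config.roster, key=priority):
        placed = False
        last_err = None
        for _ in range(config.max_retries):
            try:
                _op, sv = planter.propose(entry)
                min_carriers[sv.sv_id] = entry.min_carriers
                placed = True
                break
            except PlacementError as err:
                last_err = err
        if not placed:
            raise PlacementError(
                f"could not place {entry.sv_type}/{entry.category}: {last_err}"
            )
    for sv in planter.truth:
        if sv.sv_type in ("deletion", "insertion") and sv.size <= 20:
            raise PlacementError(f"{sv.sv_id} below the minimum reportable size")
        if sv.sv_type == "tandem_duplication" and not 100 <= sv.size <= 10_000_000:
            raise PlacementError(f"{sv.sv_id} tandem duplication out of range")
    planter.assign_carriers(min_carriers)
    return PlantResult(
        truth=planter.truth, ops=planter.ops, patients=config.patients, genome=genome
    )
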