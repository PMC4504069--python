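"""Assembly-based SV validation at base-pair resolution.

For every filtered call: gather the local + unmapped read pool, assemble it
with a multi-k de Bruijn sweep (k from half the read length to the read
length in 2-bp steps, merged across k with redundant contigs removed),
split-map contigs back to the reference by greedy maximal-exact-match
chaining, and confirm the call when a contig's fragment pattern implies the
same SV type with junction coordinates inside the call regions. Breakpoints
inside junction micro-homology are left-aligned; a confirmation must be
reproduced under a second split-mapping parameterization or the call is
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import KmerIndex, revcomp
from .models import (
    Contig,
    LibraryStats,
    ReferenceGenome,
    SplitAlignment,
    SplitFragment,
    SVCall,
    ValidatedSV,
)
from .svcall import MappingResult

GATHER_WINDOW = 500
MIN_FRAGMENT = 20
PRUNE_COVERAGE = 2


# ---------------------------------------------------------------------------
# read gathering


def gather_reads(
    call: SVCall,
    mapping: MappingResult,
    position_index: dict | None = None,
    window: int = GATHER_WINDOW,
    include_global_unmapped: bool = False,
    max_pairs: int = 800,
) -> list[str]:
    """Read pool for one call: both mates of every pair with >=1 mate mapped
    within ``window`` of either region (this includes unmapped mates of such
    pairs, i.e. junction-spanning reads), optionally plus the global unmapped
    pool. Duplicate reads are removed; the pool is capped at the pairs closest
    to a region edge."""
    if position_index is None:
        position_index = mapping.position_index()
    regions = [(call.chromA, call.startA, call.endA), (call.chromB, call.startB, call.endB)]
    if call.target_pos >= 0:
        regions.append((call.target_chrom, call.target_pos, call.target_pos + 1))
    hits: dict[int, int] = {}
    for chrom, lo, hi in regions:
        if chrom not in position_index:
            continue
        starts, idx = position_index[chrom]
        a = int(np.searchsorted(starts, lo - window - mapping.read_length))
        b = int(np.searchsorted(starts, hi + window))
        center = (lo + hi) // 2
        for k in range(a, b):
            i = int(idx[k])
            d = abs(int(starts[k]) - center)
            if i not in hits or d < hits[i]:
                hits[i] = d
    order = sorted(hits, key=lambda i: (hits[i], i))[:max_pairs]
    seqs: list[str] = []
    seen: set[str] = set()
    for i in order:
        _rid, _a1, _a2, s1, s2 = mapping.records[i]
        for s in (s1, s2):
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    if include_global_unmapped:
        for _rid, _mate, s in mapping.unmapped_store:
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    return seqs


# ---------------------------------------------------------------------------
# multi-k de Bruijn assembly


def kmer_values(read_length: int) -> list[int]:
    """k sweep: ceil(L/2) up to L in 2-bp increments."""
    k0 = (read_length + 1) // 2
    return list(range(k0, read_length + 1, 2))


def _count_kmers(reads: list[bytes], k: int) -> dict[bytes, int]:
    """Exact k-mer counts over the pool (both strands already in ``reads``)."""
    counts: dict[bytes, int] = {}
    get = counts.get
    for r in reads:
        n = len(r) - k + 1
        if b"N" in r:
            continue
        for i in range(n):
            km = r[i : i + k]
            counts[km] = get(km, 0) + 1
    return counts


def _unitigs(kmers: dict[bytes, int], k: int, min_len: int) -> list[bytes]:
    bases = (b"A", b"C", b"G", b"T")

    def succs(km: bytes) -> list[bytes]:
        suf = km[1:]
        return [suf + b for b in bases if suf + b in kmers]

    def preds(km: bytes) -> list[bytes]:
        pre = km[:-1]
        return [b + pre for b in bases if b + pre in kmers]

    contigs: list[bytes] = []
    visited: set[bytes] = set()
    starts = []
    for km in kmers:
        p = preds(km)
        if len(p) != 1 or len(succs(p[0])) != 1:
            starts.append(km)
    for km in sorted(starts):
        if km in visited:
            continue
        path = bytearray(km)
        visited.add(km)
        cur = km
        while True:
            s = succs(cur)
            if len(s) != 1:
                break
            nxt = s[0]
            if len(preds(nxt)) != 1 or nxt in visited:
                break
            visited.add(nxt)
            path.append(nxt[-1])
            cur = nxt
        if len(path) >= min_len:
            contigs.append(bytes(path))
    return contigs


def _greedy_paths(kmers: dict[bytes, int], k: int, min_len: int, reverse_tiebreak: bool) -> list[bytes]:
    """Second assembler pass: greedy highest-coverage extension through
    branches, with a configurable base-order tie-break."""
    bases = (b"T", b"G", b"C", b"A") if reverse_tiebreak else (b"A", b"C", b"G", b"T")
    visited: set[bytes] = set()
    contigs: list[bytes] = []
    order = sorted(kmers, key=lambda km: (-kmers[km], km))
    for start in order:
        if start in visited:
            continue
        path = bytearray(start)
        visited.add(start)
        cur = start
        while True:
            suf = cur[1:]
            cands = [suf + b for b in bases if suf + b in kmers and suf + b not in visited]
            if not cands:
                break
            nxt = max(cands, key=lambda km: kmers[km])
            visited.add(nxt)
            path.append(nxt[-1])
            cur = nxt
        if len(path) >= min_len:
            contigs.append(bytes(path))
    return contigs


def _merge_redundant(contigs: list[tuple[str, set[int]]]) -> list[tuple[str, set[int]]]:
    """Drop contigs that are substrings (or reverse-complement substrings) of
    a longer retained contig; merge k-value provenance of duplicates."""
    contigs = sorted(contigs, key=lambda c: (-len(c[0]), c[0]))
    kept: list[tuple[str, set[int]]] = []
    for seq, ks in contigs:
        rc = revcomp(seq)
        absorbed = False
        for kseq, kks in kept:
            if seq in kseq or rc in kseq:
                kks.update(ks)
                absorbed = True
                break
        if not absorbed:
            kept.append((seq, set(ks)))
    return kept


def assemble_multik(
    pool: list[str],
    read_length: int,
    source_call_id: str = "",
    prune: int = PRUNE_COVERAGE,
) -> list[Contig]:
    """Multi-k de Bruijn assembly of a read pool, merged across k.

    Both strands of every read enter the graph; k-mers below the pruning
    coverage are removed (tips/bubbles from stray sequence); unbranched paths
    of at least read length are contigs. A second read-off pass with greedy
    coverage-ranked extension and a different tie-break augments the set.
    """
    if not pool:
        raise ValueError("empty read pool")
    if min(len(s) for s in pool) < kmer_values(read_length)[0]:
        raise ValueError("reads shorter than the smallest k")
    both = [s.encode() for s in pool] + [revcomp(s).encode() for s in pool]
    raw: list[tuple[str, set[int]]] = []
    for k in kmer_values(read_length):
        counts = _count_kmers(both, k)
        kmers = {km: c for km, c in counts.items() if c >= prune}
        if not kmers:
            continue
        for seq in _unitigs(kmers, k, read_length):
            raw.append((seq.decode(), {k}))
        for seq in _greedy_paths(kmers, k, read_length, reverse_tiebreak=True):
            raw.append((seq.decode(), {k}))
    merged = _merge_redundant(raw)
    return [
        Contig(f"{source_call_id}c{i + 1}", seq, source_call_id, ks)
        for i, (seq, ks) in enumerate(merged)
    ]


# ---------------------------------------------------------------------------
# split-mapping


class SplitMapper:
    """Greedy maximal-exact-match chaining of contigs onto the reference."""

    def __init__(self, genome: ReferenceGenome, seed_len: int = MIN_FRAGMENT):
        self.genome = genome
        self.seed_len = seed_len
        self.index = KmerIndex(genome.chromosomes, seed_len)

    def _best_match(self, query: str, lo: int, hi: int, tiebreak: str):
        """Longest exact reference match seeded inside query[lo:hi]."""
        k = self.seed_len
        best = None  # (length, qs, qe, si, ref_start)
        memo: set[tuple[int, int]] = set()
        offsets = range(lo, hi - k + 1)
        if tiebreak == "last":
            offsets = reversed(offsets)
        for q in offsets:
            for si, pos in self.index.candidates(query[q : q + k]):
                diag = (si, pos - q)
                if diag in memo:
                    continue
                memo.add(diag)
                qs, qe = self.index.extend_match(si, pos, query, q)
                length = qe - qs
                if best is None or length > best[0]:
                    best = (length, qs, qe, si, qs + (pos - q))
        return best

    def split_map(self, contig: str, tiebreak: str = "first") -> SplitAlignment | None:
        """Chain maximal exact matches over the contig (either strand)."""
        n = len(contig)
        rc = revcomp(contig)
        fragments: list[SplitFragment] = []
        todo = [(0, n)]
        while todo:
            lo, hi = todo.pop()
            if hi - lo < MIN_FRAGMENT:
                continue
            fw = self._best_match(contig, lo, hi, tiebreak)
            rv = self._best_match(rc, n - hi, n - lo, tiebreak)
            cand = []
            if fw is not None:
                length, qs, qe, si, rs = fw
                cand.append((length, qs, qe, si, rs, "+"))
            if rv is not None:
                length, qs, qe, si, rs = rv
                # map reverse-complement coordinates back onto the contig
                cand.append((length, n - qe, n - qs, si, rs, "-"))
            if not cand:
                continue
            cand.sort(key=lambda c: (-c[0], c[1]))
            length, qs, qe, si, rs, strand = cand[0]
            if length < MIN_FRAGMENT:
                continue
            fragments.append(
                SplitFragment(
                    contig_start=qs,
                    contig_end=qe,
                    chrom=self.index.names[si],
                    ref_start=rs,
                    ref_end=rs + length,
                    strand=strand,
                )
            )
            if qs - lo >= MIN_FRAGMENT:
                todo.append((lo, qs))
            if hi - qe >= MIN_FRAGMENT:
                todo.append((qe, hi))
        if not fragments:
            return None
        fragments.sort(key=lambda f: f.contig_start)
        return SplitAlignment(contig_id="", fragments=fragments)


# ---------------------------------------------------------------------------
# breakpoint confirmation


@dataclass
class JunctionHypothesis:
    sv_type: str
    chromA: str
    posA: int
    orientA: str
    chromB: str
    posB: int
    orientB: str
    homology: int
    contig_gap: int
    contig_id: str


def _fragment_pair_hypothesis(f1: SplitFragment, f2: SplitFragment, contig_id: str) -> JunctionHypothesis | None:
    h = max(0, f1.contig_end - f2.contig_start)
    if h > 10:
        return None
    gap = max(0, f2.contig_start - f1.contig_end)
    if f1.strand == "+":
        c1, o1 = f1.ref_end, "L"
    else:
        c1, o1 = f1.ref_start, "R"
    if f2.strand == "+":
        c2, o2 = f2.ref_start, "R"
    else:
        c2, o2 = f2.ref_end, "L"
    # left-align within the homology tract: move the first fragment's junction
    # coordinate back along its reading direction
    if h:
        c1 = c1 - h if f1.strand == "+" else c1 + h
    bp1 = (f1.chrom, c1, o1)
    bp2 = (f2.chrom, c2, o2)
    (cA, pA, oA), (cB, pB, oB) = sorted((bp1, bp2), key=lambda b: (b[0], b[1]))
    if f1.chrom != f2.chrom:
        svt = "translocation"
    elif f1.strand != f2.strand:
        svt = "inversion_like"
    elif gap >= MIN_FRAGMENT and abs(pB - pA) <= 10 and {oA, oB} == {"L", "R"}:
        # novel sequence between two flanks at one locus; a contig assembled
        # in reverse complement presents the orientations in (R, L) order
        svt = "insertion"
    elif (oA, oB) == ("L", "R") and pB > pA:
        svt = "deletion"
    elif (oA, oB) == ("R", "L") and pA < pB:
        svt = "tandem_duplication"
    else:
        return None
    return JunctionHypothesis(svt, cA, pA, oA, cB, pB, oB, h, gap, contig_id)


_COMPATIBLE = {
    "deletion": {"deletion"},
    "insertion": {"insertion"},
    "inversion": {"inversion_like"},
    "inverted_duplication": {"inversion_like"},
    "tandem_duplication": {"tandem_duplication"},
    "translocation": {"translocation"},
    "transposition": {"deletion"},
}


def confirm_breakpoints(
    call: SVCall,
    contigs: list[Contig],
    splitmapper: SplitMapper,
    lib: LibraryStats,
    slack: int | None = None,
) -> tuple[ValidatedSV | None, str]:
    """Confirm a call against its contigs' split alignments.

    Returns (validated, reason); reason is "confirmed", "no_supporting_contig",
    "type_mismatch" or "aligner_disagreement". Confirmation requires the same
    junction under a second split-mapping parameterization.
    """
    if slack is None:
        slack = int(lib.insert_mean + 3 * lib.insert_sd)
    hypotheses: list[JunctionHypothesis] = []
    by_contig: dict[str, Contig] = {c.contig_id: c for c in contigs}
    for c in contigs:
        sa = splitmapper.split_map(c.sequence, tiebreak="first")
        if sa is None or len(sa.fragments) < 2:
            continue
        for f1, f2 in zip(sa.fragments, sa.fragments[1:]):
            hyp = _fragment_pair_hypothesis(f1, f2, c.contig_id)
            if hyp is not None:
                hypotheses.append(hyp)
    if not hypotheses:
        return None, "no_supporting_contig"

    def in_regions(h: JunctionHypothesis) -> bool:
        okA = h.chromA == call.chromA and call.startA - slack <= h.posA <= call.endA + slack
        okB = h.chromB == call.chromB and call.startB - slack <= h.posB <= call.endB + slack
        return okA and okB

    compatible = [
        h for h in hypotheses
        if h.sv_type in _COMPATIBLE.get(call.sv_type, set()) and in_regions(h)
    ]
    if not compatible:
        return None, "type_mismatch"
    compatible.sort(key=lambda h: (h.homology, h.posA, h.posB, h.orientA, h.contig_id))
    best = compatible[0]
    # independent re-mapping with a different seed-match order must agree
    sa2 = splitmapper.split_map(by_contig[best.contig_id].sequence, tiebreak="last")
    confirmed2 = False
    if sa2 is not None:
        for f1, f2 in zip(sa2.fragments, sa2.fragments[1:]):
            h2 = _fragment_pair_hypothesis(f1, f2, best.contig_id)
            if h2 is not None and (h2.posA, h2.posB, h2.sv_type) == (
                best.posA, best.posB, best.sv_type
            ):
                confirmed2 = True
                break
    if not confirmed2:
        return None, "aligner_disagreement"
    return (
        ValidatedSV(
            sv_id=call.call_id,
            sv_type=call.sv_type,
            chromA=best.chromA,
            posA=best.posA,
            orientA=best.orientA,
            chromB=best.chromB,
            posB=best.posB,
            orientB=best.orientB,
            supporting_contig=best.contig_id,
            sample_id=call.sample_id,
            homology_len=best.homology,
        ),
        "confirmed",
    )


def validate_calls(
    calls: list[SVCall],
    mapping: MappingResult,
    genome: ReferenceGenome,
    lib: LibraryStats,
    splitmapper: SplitMapper | None = None,
    include_global_unmapped: bool = False,
) -> tuple[list[ValidatedSV], dict[str, str]]:
    """Run gather -> assemble -> split-map -> confirm for every call."""
    splitmapper = splitmapper or SplitMapper(genome)
    position_index = mapping.position_index()
    validated: list[ValidatedSV] = []
    reasons: dict[str, str] = {}
    for call in calls:
        pool = gather_reads(
            call, mapping, position_index,
            include_global_unmapped=include_global_unmapped,
        )
        if not pool:
            reasons[call.call_id] = "unvalidatable_empty_pool"
            continue
        contigs = assemble_multik(pool, mapping.read_length, call.call_id)
        sv, reason = confirm_breakpoints(call, contigs, splitmapper, lib)
        reasons[call.call_id] = reason
        if sv is not None:
            validated.append(sv)
    return validated, reasons
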