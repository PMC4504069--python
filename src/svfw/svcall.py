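"""Paired-end mapping and discordant-cluster SV calling.

The in-repo mapper does exact/seeded-greedy placement (MAPQ 60 unique, 0 for
ties, linear per-mismatch penalty when a substitution rate is simulated);
junction-crossing reads have no contiguous reference match and land in the
unmapped store that feeds targeted assembly. Discordant pairs are clustered
per signature, then cluster geometry is refined into the seven structural
classes (see cluster_signatures).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from ._seq import KmerIndex, revcomp
from .models import Alignment, DiscordantPair, LibraryStats, ReferenceGenome, SVCall

MAPQ_MIN = 35


def min_support_for(depth: float, lib: LibraryStats, divisor: float = 8.0) -> int:
    """Coverage-dependent minimum paired-end support for an emitted call.

    physical coverage = depth * insert_mean / (2 * read_length); the threshold
    is max(3, round(physical / divisor)) and is monotone in depth.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    physical = depth * lib.insert_mean / (2.0 * lib.read_length)
    return max(3, int(physical / divisor + 0.5))


# ---------------------------------------------------------------------------
# mapping


class GenomeMapper:
    """Exact seeded mapper against a reference genome."""

    def __init__(self, genome: ReferenceGenome, seed_len: int = 31, max_mismatch: int = 3):
        self.genome = genome
        self.seed_len = seed_len
        self.max_mismatch = max_mismatch
        self.index = KmerIndex(genome.chromosomes, seed_len)

    def _exact_hits(self, seq: str, max_hits: int = 2) -> list[tuple[int, int]]:
        """Up to ``max_hits`` exact placements (two suffice to prove ambiguity,
        and repetitive-tract seeds can have thousands of candidates)."""
        hits = []
        n = len(seq)
        seqs = self.index.seqs
        for si, pos in self.index.candidates(seq[: self.seed_len]):
            if seqs[si][pos : pos + n] == seq:
                hits.append((si, pos))
                if len(hits) >= max_hits:
                    break
        return hits

    def _fuzzy_hit(self, seq: str) -> tuple[int, int, int] | None:
        """Single best placement with mismatches, seeded at the read tail."""
        off = len(seq) - self.seed_len
        best = None
        for si, pos in self.index.candidates(seq[off:]):
            start = pos - off
            if start < 0:
                continue
            ref = self.index.seqs[si][start : start + len(seq)]
            if len(ref) < len(seq):
                continue
            mm = sum(a != b for a, b in zip(ref, seq))
            if mm <= self.max_mismatch and (best is None or mm < best[2]):
                best = (si, start, mm)
        return best

    def map_read(self, seq: str) -> tuple[str, int, str, int] | None:
        """(chrom, start, strand, mapq) of the placement, or None if unmapped."""
        if "N" in seq:
            return None
        fwd = self._exact_hits(seq)
        if len(fwd) >= 2:
            si, pos = fwd[0]
            return (self.index.names[si], pos, "+", 0)
        rc = revcomp(seq)
        rev = self._exact_hits(rc)
        total = len(fwd) + len(rev)
        if total == 1:
            si, pos = fwd[0] if fwd else rev[0]
            return (self.index.names[si], pos, "+" if fwd else "-", 60)
        if total > 1:
            si, pos = (fwd + rev)[0]
            return (self.index.names[si], pos, "+" if fwd else "-", 0)
        if self.max_mismatch > 0:
            for s, strand in ((seq, "+"), (rc, "-")):
                hit = self._fuzzy_hit(s)
                if hit is not None:
                    si, start, mm = hit
                    # steep linear penalty: any mismatched placement falls
                    # below the MAPQ 35 SV-evidence cutoff (junction-crossing
                    # reads with chance end matches must not nudge clusters)
                    return (self.index.names[si], start, strand, max(0, 60 - 30 * mm))
        return None


@dataclass
class MappingResult:
    """Per-pair placements plus the unmapped-read store.

    records[i] = (read_id, aln1, aln2, seq1, seq2) with aln = (chrom, start,
    strand, mapq) or None. unmapped_store holds (read_id, mate, seq) for every
    unmapped mate.
    """

    read_length: int
    records: list[tuple] = field(default_factory=list)
    duplicates_removed: int = 0

    @property
    def unmapped_store(self) -> list[tuple[str, int, str]]:
        out = []
        for rid, a1, a2, s1, s2 in self.records:
            if a1 is None:
                out.append((rid, 1, s1))
            if a2 is None:
                out.append((rid, 2, s2))
        return out

    def position_index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (sorted starts, record indices) over mapped mates."""
        tmp: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for i, (_rid, a1, a2, _s1, _s2) in enumerate(self.records):
            if a1 is not None:
                tmp[a1[0]].append((a1[1], i))
            if a2 is not None:
                tmp[a2[0]].append((a2[1], i))
        out = {}
        for chrom, lst in tmp.items():
            lst.sort()
            starts = np.array([p for p, _ in lst], dtype=np.int64)
            idx = np.array([i for _, i in lst], dtype=np.int64)
            out[chrom] = (starts, idx)
        return out


def map_reads(
    reads: list[tuple[str, str, str]],
    genome: ReferenceGenome,
    mapper: GenomeMapper | None = None,
) -> MappingResult:
    """Place both mates of every pair; collapse PCR-exact duplicates."""
    if not genome.chromosomes:
        raise ValueError("empty genome")
    mapper = mapper or GenomeMapper(genome)
    L = len(reads[0][1]) if reads else 0
    result = MappingResult(read_length=L)
    seen: set[tuple] = set()
    for rid, s1, s2 in reads:
        a1 = mapper.map_read(s1)
        a2 = mapper.map_read(s2)
        if a1 is not None and a2 is not None:
            key = (a1[0], a1[1], a1[2], a2[0], a2[1], a2[2])
            if key in seen:
                result.duplicates_removed += 1
                continue
            seen.add(key)
        result.records.append((rid, a1, a2, s1, s2))
    return result


# ---------------------------------------------------------------------------
# discordant-pair signatures


def pair_signature(
    a1: tuple[str, int, str],
    a2: tuple[str, int, str],
    lib: LibraryStats,
    k_sd: float = 2.5,
) -> tuple[str | None, int | None]:
    """Signature of a mapped pair given (chrom, start, strand) per mate.

    Returns (signature, observed_insert); signature None means concordant.
    """
    L = lib.read_length
    (c1, p1, s1), (c2, p2, s2) = a1, a2
    if c1 != c2:
        return "interchrom", None
    if s1 == s2:
        return "same_strand", None
    fwd, rev = (a1, a2) if s1 == "+" else (a2, a1)
    if rev[1] < fwd[1]:
        return "everted", None
    observed = rev[1] + L - fwd[1]
    if observed > lib.insert_mean + k_sd * lib.insert_sd:
        return "large_insert", observed
    if observed < lib.insert_mean - k_sd * lib.insert_sd:
        return "short_insert", observed
    return None, observed


def detect_discordant(
    pairs: list[tuple[Alignment, Alignment]],
    lib: LibraryStats,
    k_sd: float = 2.5,
) -> list[DiscordantPair]:
    """MAPQ-filter mapped pairs and keep those violating the library model."""
    out = []
    for aln1, aln2 in pairs:
        if not (aln1.is_mapped and aln2.is_mapped):
            continue
        if aln1.mapq < MAPQ_MIN or aln2.mapq < MAPQ_MIN:
            continue
        sig, obs = pair_signature(
            (aln1.chrom, aln1.start, aln1.strand),
            (aln2.chrom, aln2.start, aln2.strand),
            lib,
            k_sd,
        )
        if sig is None:
            continue
        a, b = sorted((aln1, aln2), key=lambda x: (x.chrom, x.start))
        out.append(DiscordantPair(aln1.read_id, a, b, sig, obs))
    return out


def discordant_from_mapping(
    mapping: MappingResult, lib: LibraryStats, k_sd: float = 2.5
) -> list[DiscordantPair]:
    pairs = []
    for rid, a1, a2, _s1, _s2 in mapping.records:
        if a1 is None or a2 is None or a1[3] < MAPQ_MIN or a2[3] < MAPQ_MIN:
            continue
        sig, obs = pair_signature(a1[:3], a2[:3], lib, k_sd)
        if sig is None:
            continue
        L = mapping.read_length
        alns = [
            Alignment(rid, m, c, p, p + L, s, q)
            for m, (c, p, s, q) in ((1, a1), (2, a2))
        ]
        a, b = sorted(alns, key=lambda x: (x.chrom, x.start))
        pairs.append(DiscordantPair(rid, a, b, sig, obs))
    return pairs


# ---------------------------------------------------------------------------
# clustering and type refinement


@dataclass
class _Cluster:
    sig: str
    strandA: str
    strandB: str
    chromA: str
    chromB: str
    members: list[DiscordantPair]
    regionA: tuple[int, int] = (0, 0)
    regionB: tuple[int, int] = (0, 0)

    @property
    def support(self) -> int:
        return len(self.members)

    def mean_observed(self) -> float:
        vals = [p.observed_insert for p in self.members if p.observed_insert is not None]
        return float(np.mean(vals)) if vals else float("nan")

    def mid(self, side: str) -> float:
        r = self.regionA if side == "A" else self.regionB
        return 0.5 * (r[0] + r[1])


def _side_region(alns: list[Alignment], window: int) -> tuple[int, int]:
    """Maximal junction interval compatible with all member alignments."""
    strand = alns[0].strand
    if strand == "+":
        lo = max(a.end for a in alns)
        hi = min(a.start for a in alns) + window
    else:
        lo = max(a.end for a in alns) - window
        hi = min(a.start for a in alns)
    if hi <= lo:
        lo, hi = min(lo, hi), max(lo, hi) + 1
    return int(lo), int(hi)


def _junction_interval(aln: Alignment, rw: int) -> tuple[int, int]:
    """Interval that must contain the junction given one anchoring mate."""
    if aln.strand == "+":
        return (aln.end, aln.start + rw)
    return (aln.end - rw, aln.start)


def _consensus(members: list[DiscordantPair], rw: int) -> list[DiscordantPair]:
    """Largest member subset jointly consistent with one junction pair.

    Each mate constrains its junction coordinate to an interval; for
    same-chromosome clusters the A-side junction cannot lie right of the
    B-side one. Evaluated by scanning candidate A-points and maximising
    B-coverage among compatible members (O(n^2))."""
    ivA = [_junction_interval(p.alnA, rw) for p in members]
    ivB = [_junction_interval(p.alnB, rw) for p in members]
    same_chrom = members[0].alnA.chrom == members[0].alnB.chrom
    best: tuple[int, int, list] | None = None
    for xA in sorted({lo for lo, _ in ivA}):
        sa = [i for i, (lo, hi) in enumerate(ivA) if lo <= xA <= hi]
        if best is not None and len(sa) <= best[0]:
            continue
        # best-covered B point among A-compatible members, honouring xB >= xA
        cands = []
        for i in sa:
            lo, hi = ivB[i]
            if same_chrom:
                lo = max(lo, xA)
            if lo <= hi:
                cands.append((i, lo, hi))
        for _j, xB, _hi in cands:
            sb = [i for i, lo, hi in cands if lo <= xB <= hi]
            if best is None or len(sb) > best[0]:
                best = (len(sb), xA, sb)
    if best is None:
        return members
    keep = set(best[2])
    return [members[i] for i in range(len(members)) if i in keep]


def _near(r1: tuple[int, int], r2: tuple[int, int], w: int) -> bool:
    return r1[0] - w < r2[1] and r2[0] - w < r1[1]


def _raw_clusters(
    pairs: list[DiscordantPair],
    window: int,
    region_window: int | None = None,
    insert_tol: float | None = None,
) -> list[_Cluster]:
    groups: dict[tuple, list[DiscordantPair]] = defaultdict(list)
    for p in pairs:
        key = (p.signature, p.alnA.strand, p.alnB.strand, p.alnA.chrom, p.alnB.chrom)
        groups[key].append(p)
    clusters: list[_Cluster] = []
    for key, members in groups.items():
        members.sort(key=lambda p: p.alnA.start)
        parent = list(range(len(members)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if members[j].alnA.start - members[i].alnA.start > window:
                    break
                if abs(members[j].alnB.start - members[i].alnB.start) <= window:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        sub: dict[int, list[DiscordantPair]] = defaultdict(list)
        for i in range(len(members)):
            sub[find(i)].append(members[i])
        rw = region_window or window
        for ms in sub.values():
            parts = [ms]
            if insert_tol and len(ms) >= 3 and key[0] in ("large_insert", "short_insert"):
                # far-insert-tail pairs from ordinary genome can co-locate with
                # a real junction cluster; their implied event size disagrees
                obs = sorted(p.observed_insert for p in ms)
                med = obs[len(obs) // 2]
                core = [p for p in ms if abs(p.observed_insert - med) <= insert_tol]
                outliers = [p for p in ms if abs(p.observed_insert - med) > insert_tol]
                parts = [core] + [[p] for p in outliers]
            # geometric consensus: every retained member's junction interval
            # must cover a common point on both sides
            refined = []
            for grp in parts:
                if len(grp) < 3:
                    refined.append(grp)
                    continue
                core = _consensus(grp, rw)
                rest = [p for p in grp if p not in core]
                refined.append(core)
                refined.extend([p] for p in rest)
            parts = refined
            for grp in parts:
                if not grp:
                    continue
                c = _Cluster(key[0], key[1], key[2], key[3], key[4], grp)
                c.regionA = _side_region([p.alnA for p in grp], rw)
                c.regionB = _side_region([p.alnB for p in grp], rw)
                clusters.append(c)
    return clusters


def cluster_signatures(
    pairs: list[DiscordantPair],
    lib: LibraryStats,
    min_support: int,
    sample_id: str = "S",
) -> list[SVCall]:
    """Merge signature clusters into typed SV calls.

    Refinement rules: reciprocal interchromosomal clusters merge to one
    translocation; a (+,+)/(-,-) same-strand cluster pair with matching
    regions is an inversion, while a self-co-located same-strand cluster
    paired with an opposite-orientation spanning cluster marks an inserted
    reverse-complement copy (inverted duplication); an insertion-signature
    cluster linked by distant-mate clusters to a size-matched deletion
    cluster is a transposition (links are consumed); a short-insert cluster
    co-located with an everted cluster is absorbed into the duplication;
    everted clusters span tandem duplications (< 100 bp implies a
    small_duplication artifact, overlapping duplications sharing a margin are
    co_amplicons); contradictory co-located insert clusters are undefined.
    """
    if min_support < 2:
        raise ValueError("min_support must be >= 2")
    W = int(lib.insert_mean + 3 * lib.insert_sd)
    # junction regions use a wider insert bound so they always contain the
    # true breakpoint even for pairs in the far insert-size tail
    clusters = _raw_clusters(
        pairs, W, int(lib.insert_mean + 5 * lib.insert_sd), 4.5 * lib.insert_sd
    )
    consumed: set[int] = set()
    calls: list[tuple] = []  # (sv_type, cA, rA, cB, rB, support, size_est, target)

    def alive(kind=None):
        return [
            (i, c) for i, c in enumerate(clusters)
            if i not in consumed and (kind is None or c.sig == kind)
        ]

    # 1. reciprocal interchromosomal clusters -> translocation
    inter = alive("interchrom")
    done = set()
    for i, c1 in inter:
        if i in done:
            continue
        partner = None
        for j, c2 in inter:
            if j <= i or j in done:
                continue
            if (c1.chromA, c1.chromB) != (c2.chromA, c2.chromB):
                continue
            if _near(c1.regionA, c2.regionA, W) and _near(c1.regionB, c2.regionB, W):
                partner = (j, c2)
                break
        support = c1.support
        rA, rB = c1.regionA, c1.regionB
        if partner is not None:
            j, c2 = partner
            support += c2.support
            rA = (min(rA[0], c2.regionA[0]), max(rA[1], c2.regionA[1]))
            rB = (min(rB[0], c2.regionB[0]), max(rB[1], c2.regionB[1]))
            done.add(j)
            consumed.add(j)
        done.add(i)
        consumed.add(i)
        calls.append(("translocation", c1.chromA, rA, c1.chromB, rB, support, 0.0, None))

    # 2. same-strand cluster pairing: inversions and inverted duplications
    ss = alive("same_strand")
    done = set()
    for i, c1 in ss:
        if i in done:
            continue
        mate = None
        for j, c2 in ss:
            if j == i or j in done:
                continue
            if c1.chromA != c2.chromA or c1.chromB != c2.chromB:
                continue
            if c1.strandA == c2.strandA:
                continue
            if _near(c1.regionA, c2.regionA, W) and _near(c1.regionB, c2.regionB, W):
                mate = (j, c2, "inversion")
                break
            self1 = _near(c1.regionA, c1.regionB, 0)
            self2 = _near(c2.regionA, c2.regionB, 0)
            if self1 != self2:
                point, spanning = (c1, c2) if self1 else (c2, c1)
                if _near(point.regionB, spanning.regionB, W) and not _near(
                    point.regionA, spanning.regionA, W
                ):
                    mate = (j, c2, "inverted_duplication")
                    break
        if mate is None:
            done.add(i)
            consumed.add(i)
            calls.append(
                ("inversion", c1.chromA, c1.regionA, c1.chromB, c1.regionB,
                 c1.support, 0.0, None)
            )
            continue
        j, c2, kind = mate
        done.update((i, j))
        consumed.update((i, j))
        support = c1.support + c2.support
        if kind == "inversion":
            rA = (min(c1.regionA[0], c2.regionA[0]), max(c1.regionA[1], c2.regionA[1]))
            rB = (min(c1.regionB[0], c2.regionB[0]), max(c1.regionB[1], c2.regionB[1]))
        else:
            spanning = c2 if _near(c1.regionA, c1.regionB, 0) else c1
            rA, rB = spanning.regionA, spanning.regionB
        calls.append((kind, c1.chromA, rA, c1.chromB, rB, support, 0.0, None))

    # 3a. short-insert clusters absorbed by co-located everted clusters
    for i, c in alive("short_insert"):
        for j, ev in alive("everted"):
            if c.chromA == ev.chromA and _near(c.regionA, ev.regionA, W) \
                    and _near(c.regionB, ev.regionB, W):
                ev.members.extend(c.members)
                consumed.add(i)
                break

    # 3b. transpositions: an excision (deletion-signature) cluster joined by
    # distant-mate "link" clusters to a common re-insertion point; a
    # co-located insertion-signature cluster at that point is absorbed. Link
    # clusters have their two sides far apart (pairs bridging the insertion
    # site and the excised copy), which stray far-tail pairs never do.
    link_pool = [
        (k, lc) for k, lc in alive()
        if lc.sig in ("large_insert", "everted")
        and abs(lc.mid("A") - lc.mid("B")) >= 2 * W
    ]
    if link_pool:
        for j, dele in sorted(alive("large_insert"),
                              key=lambda jc: (-jc[1].support, jc[0])):
            if j in consumed or dele.support < min_support:
                continue
            span = (dele.regionA[0] - W, dele.regionB[1] + W)
            links = []
            t_points = []
            for k, lc in link_pool:
                if k in consumed or k == j or lc.chromA != dele.chromA:
                    continue
                for near_side, far_side in (("A", "B"), ("B", "A")):
                    far_mid = lc.mid(far_side)
                    near_mid = lc.mid(near_side)
                    if span[0] < far_mid < span[1] and not span[0] < near_mid < span[1]:
                        links.append(k)
                        t_points.append(near_mid)
                        break
            if not links:
                continue
            # all link far ends must agree on one re-insertion locus
            if max(t_points) - min(t_points) > 2 * W:
                continue
            t_hat = int(np.median(t_points))
            support = dele.support + sum(clusters[k].support for k in links)
            consumed.add(j)
            consumed.update(links)
            for k, ic in alive("short_insert"):
                if ic.chromA == dele.chromA and abs(ic.mid("A") - t_hat) < W \
                        and abs(ic.mid("B") - t_hat) < W:
                    consumed.add(k)
                    support += ic.support
            calls.append(
                ("transposition", dele.chromA, dele.regionA, dele.chromB,
                 dele.regionB, support,
                 dele.mean_observed() - lib.insert_mean, t_hat),
            )

    # 3c. undefined: contradictory co-located insert-size clusters (both with
    # real support; lone far-tail pairs are just dropped by the threshold)
    for i, c in alive("short_insert"):
        if c.support < 2:
            continue
        for j, d in alive("large_insert"):
            if d.support < 2:
                continue
            if 3 * min(c.support, d.support) < max(c.support, d.support):
                continue  # a stray tail-pair clump next to a real cluster
            if c.chromA == d.chromA and _near(c.regionA, d.regionA, W) \
                    and _near(c.regionB, d.regionB, W):
                consumed.update((i, j))
                calls.append(
                    ("undefined", c.chromA, c.regionA, c.chromB, c.regionB,
                     c.support + d.support, 0.0, None)
                )
                break

    # 4. everted clusters: tandem / small duplications and co-amplicons
    ev = alive("everted")
    done = set()
    for i, c1 in ev:
        if i in done:
            continue
        span1 = (c1.mid("A"), c1.mid("B"))
        co = None
        for j, c2 in ev:
            if j <= i or j in done or c1.chromA != c2.chromA:
                continue
            span2 = (c2.mid("A"), c2.mid("B"))
            overlap = min(span1[1], span2[1]) - max(span1[0], span2[0])
            if overlap <= 0:
                continue
            shareA = abs(span1[0] - span2[0]) <= W
            shareB = abs(span1[1] - span2[1]) <= W
            if shareA != shareB:  # exactly one shared margin
                co = (j, c2)
                break
        if co is not None:
            j, c2 = co
            done.update((i, j))
            consumed.update((i, j))
            rA = (min(c1.regionA[0], c2.regionA[0]), max(c1.regionA[1], c2.regionA[1]))
            rB = (min(c1.regionB[0], c2.regionB[0]), max(c1.regionB[1], c2.regionB[1]))
            calls.append(("co_amplicon", c1.chromA, rA, c1.chromB, rB,
                          c1.support + c2.support, 0.0, None))
            continue
        done.add(i)
        consumed.add(i)
        # junction estimates: the duplication start is bounded by the reverse
        # mates' smallest start, its end by the forward mates' largest end
        dup_span = c1.regionB[0] - c1.regionA[1]
        kind = "small_duplication" if dup_span < 100 else "tandem_duplication"
        calls.append((kind, c1.chromA, c1.regionA, c1.chromB, c1.regionB,
                      c1.support, dup_span, None))

    # 5. remaining insert-size clusters
    for i, c in alive("large_insert"):
        consumed.add(i)
        calls.append(("deletion", c.chromA, c.regionA, c.chromB, c.regionB,
                      c.support, c.mean_observed() - lib.insert_mean, None))
    for i, c in alive("short_insert"):
        consumed.add(i)
        calls.append(("insertion", c.chromA, c.regionA, c.chromB, c.regionB,
                      c.support, lib.insert_mean - c.mean_observed(), None))

    out: list[SVCall] = []
    calls.sort(key=lambda c: (c[1], c[2][0], c[3], c[4][0], c[0]))
    n = 0
    for svt, cA, rA, cB, rB, support, size_est, target in calls:
        if support < min_support:
            continue
        n += 1
        out.append(
            SVCall(
                call_id=f"{sample_id}:{n:04d}", sv_type=svt,
                chromA=cA, startA=rA[0], endA=rA[1],
                chromB=cB, startB=rB[0], endB=rB[1],
                support=support, sample_id=sample_id,
                size_estimate=float(size_est),
                target_chrom=cA if target is not None else "",
                target_pos=target if target is not None else -1,
            )
        )
    return out
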