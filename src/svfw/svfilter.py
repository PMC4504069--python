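"""The filtering cascade applied to candidate SV calls.

Rules fire in a fixed order and each call is counted against the first rule
that removes it, so removal counts are reproducible and sum with the retained
set to the input size:

1. artifact classes (small_duplication, co_amplicon, undefined);
2. more than half of the call footprint overlaps low-complexity sequence
   (footprint = both regions plus the spanned interval for intra-chromosomal
   calls);
3. either region within 100 kb of a centromere/telomere tract or assembly gap;
4. either region on an excluded-name chromosome (mitochondrial / Y /
   unlocalized).
"""

from __future__ import annotations

from .models import DISCARD_CLASSES, ReferenceGenome, SVCall

LOW_COMPLEXITY_MAX_FRACTION = 0.5
EXCLUSION_DISTANCE = 100_000

RULES = ("artifact_class", "low_complexity", "near_gap_or_centromere", "excluded_chrom")


def _footprint(call: SVCall) -> list[tuple[str, int, int]]:
    if call.chromA == call.chromB:
        lo = min(call.startA, call.startB)
        hi = max(call.endA, call.endB)
        return [(call.chromA, lo, hi)]
    return [(call.chromA, call.startA, call.endA), (call.chromB, call.startB, call.endB)]


def _overlap(lo: int, hi: int, ivs: list[tuple[int, int]]) -> int:
    return sum(max(0, min(hi, e) - max(lo, s)) for s, e in ivs)


def _rule_for(call: SVCall, genome: ReferenceGenome) -> str | None:
    for chrom in (call.chromA, call.chromB):
        if chrom not in genome.chromosomes:
            raise ValueError(f"call {call.call_id} on unknown chromosome {chrom}")
    if call.sv_type in DISCARD_CLASSES:
        return "artifact_class"
    total = masked = 0
    for chrom, lo, hi in _footprint(call):
        total += hi - lo
        masked += _overlap(lo, hi, genome.mask_intervals("low_complexity", chrom))
    if total > 0 and masked / total > LOW_COMPLEXITY_MAX_FRACTION:
        return "low_complexity"
    for chrom, lo, hi in (
        (call.chromA, call.startA, call.endA),
        (call.chromB, call.startB, call.endB),
    ):
        for mask in ("centromere_telomere", "assembly_gap"):
            for s, e in genome.mask_intervals(mask, chrom):
                if lo - EXCLUSION_DISTANCE < e and s - EXCLUSION_DISTANCE < hi:
                    return "near_gap_or_centromere"
    if genome.is_excluded(call.chromA) or genome.is_excluded(call.chromB):
        return "excluded_chrom"
    return None


def apply_filters(
    calls: list[SVCall], genome: ReferenceGenome
) -> tuple[list[SVCall], dict[str, int]]:
    """Apply the cascade; returns (retained calls in input order, per-rule
    removal counts)."""
    removals = {rule: 0 for rule in RULES}
    retained: list[SVCall] = []
    for call in calls:
        rule = _rule_for(call, genome)
        if rule is None:
            retained.append(call)
        else:
            removals[rule] += 1
    return retained, removals
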