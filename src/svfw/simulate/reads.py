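"""Paired-end read simulation from a donor genome.

Fragments are sampled uniformly per chromosome; insert length is drawn from a
normal distribution truncated at twice the read length; mate 1 is the forward
strand of the fragment start and mate 2 the reverse complement of its end.
Reads are error-free unless a substitution rate is given.
"""

from __future__ import annotations

import numpy as np

from .._seq import mutate_uniform, revcomp
from ..models import LibraryStats


def simulate_reads(
    chrom_seqs: dict[str, str],
    lib: LibraryStats,
    coverage: float,
    seed: int,
    error_rate: float = 0.0,
    id_prefix: str = "r",
) -> list[tuple[str, str, str]]:
    """Return (read_id, mate1, mate2) tuples at the requested coverage.

    Pair count per chromosome is round(coverage * length / (2 * read_length)).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    L = lib.read_length
    out: list[tuple[str, str, str]] = []
    for chrom, seq in chrom_seqs.items():
        n = len(seq)
        n_pairs = int(round(coverage * n / (2 * L)))
        if n_pairs < 1:
            raise ValueError(f"coverage yields no pairs on {chrom}")
        inserts = np.clip(
            np.rint(rng.normal(lib.insert_mean, lib.insert_sd, n_pairs)).astype(int),
            2 * L,
            None,
        )
        inserts = np.minimum(inserts, n)
        starts = rng.integers(0, np.maximum(1, n - inserts + 1))
        for i in range(n_pairs):
            f, ins = int(starts[i]), int(inserts[i])
            m1 = seq[f : f + L]
            m2 = revcomp(seq[f + ins - L : f + ins])
            if error_rate > 0:
                m1 = mutate_uniform(rng, m1, error_rate)
                m2 = mutate_uniform(rng, m2, error_rate)
            out.append((f"{id_prefix}:{chrom}:{i}", m1, m2))
    return out
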