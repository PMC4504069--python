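"""Low-level sequence helpers shared across the pipeline.

Hot paths (read mapping, k-mer indexing) live here so the rest of the code
can stay expressive. Sequences are plain upper-case ``str`` over A,C,G,T,N.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def random_dna(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA of length ``n`` (no N)."""
    return _BASES[rng.integers(0, 4, n)].tobytes().decode("ascii")


def mutate_uniform(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply uniform substitutions at the given per-base rate."""
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    # substitute with a uniformly chosen *different* base
    for i in hits:
        cur = arr[i]
        choices = _BASES[_BASES != cur]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii")


class KmerIndex:
    """Exact k-mer location index over a set of named sequences.

    Maps every k-mer to its (sequence-index, offset) occurrences. Used both by
    the read mapper (long seeds) and the contig split-mapper (short seeds).
    """

    def __init__(self, sequences: dict[str, str], k: int):
        self.k = k
        self.names: list[str] = list(sequences)
        self.seqs: list[str] = [sequences[n] for n in self.names]
        index: dict[str, list[tuple[int, int]]] = {}
        for si, seq in enumerate(self.seqs):
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((si, i))
        self._index = index

    def candidates(self, kmer: str) -> list[tuple[int, int]]:
        return self._index.get(kmer, ())

    def extend_match(self, si: int, pos: int, query: str, qpos: int) -> tuple[int, int]:
        """Maximally extend an exact match anchored at query[qpos] == seq[pos].

        Returns (qstart, qend) of the maximal exact run around the anchor.
        """
        seq = self.seqs[si]
        qs, ps = qpos, pos
        while qs > 0 and ps > 0 and query[qs - 1] == seq[ps - 1]:
            qs -= 1
            ps -= 1
        qe, pe = qpos, pos
        n, m = len(query), len(seq)
        while qe < n and pe < m and query[qe] == seq[pe]:
            qe += 1
            pe += 1
        return qs, qe
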