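"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised code paths:
mapping is checked against a per-window Hamming loop in pure Python, and the
ping-pong signature against exhaustive pair enumeration.
"""

from __future__ import annotations

import numpy as np
import pytest

from pirnakit.aligner import Region, ReferenceSet
from pirnakit.sequence_io import TrimmedRead

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def py_revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def oracle_map(read_seq: str, regions: dict[str, str], max_mm: int):
    """All-window Hamming scan, pure Python: the mapping semantics."""
    hits = []
    for name, ref in regions.items():
        for query, strand in ((read_seq, "+"), (py_revcomp(read_seq), "-")):
            n = len(query)
            for start in range(len(ref) - n + 1):
                mm = sum(1 for a, b in zip(query, ref[start : start + n]) if a != b)
                if mm <= max_mm:
                    hits.append((name, start, strand, mm))
    hits.sort(key=lambda h: (h[0], h[1], h[2]))
    return hits


def oracle_pair_counts(
    sense_reads: list[tuple[int, float]],
    antisense_reads: list[tuple[int, float]],
    K: int,
) -> np.ndarray:
    """Exhaustive enumeration over all sense/antisense read pairs.

    Each read is (five_prime_position, weight); a pair with the antisense 5'
    end at sense 5' + k - 1 overlaps by k bases and contributes the product
    of weights at register k.
    """
    counts = np.zeros(K)
    for s5, ws in sense_reads:
        for a5, wa in antisense_reads:
            k = a5 - s5 + 1
            if 1 <= k <= K:
                counts[k - 1] += ws * wa
    return counts


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def tiny_refs(rng) -> ReferenceSet:
    """Two analysis regions plus one of each normalization category."""
    return ReferenceSet(
        [
            Region("T3", random_seq(rng, 900), "analysis"),
            Region("PlArB", random_seq(rng, 2000), "analysis"),
            Region("genome", random_seq(rng, 3000), "normalization_genome"),
            Region("miscRNA", random_seq(rng, 300), "miscRNA"),
            Region("tRNA", random_seq(rng, 200), "tRNA"),
            Region("miRNA", random_seq(rng, 300), "miRNA"),
        ]
    )


def read_from(refs: ReferenceSet, region: str, start: int, length: int,
              strand: str = "+", rid: str = "r") -> TrimmedRead:
    window = refs[region].seq[start : start + length]
    return TrimmedRead(id=rid, seq=window if strand == "+" else py_revcomp(window))
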