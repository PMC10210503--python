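"""Library annotation and depth normalization.

Small-RNA libraries are compared after scaling raw counts by a per-million
normalization factor.  The primary denominator is the number of reads mapping
to the genome-role references minus those mapping to miscRNA (rRNA, snoRNA)
or tRNA references.  Two alternative denominators (miRNA reads, all genome
reads) are provided to check that conclusions are normalization-robust.

Category membership is not exclusive: a read matching both a miRNA and a
genome region counts in both tallies; the subtraction happens only in the
denominator formula.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .aligner import ReferenceSet, map_read
from .sequence_io import TrimmedRead

#: normalization modes -> denominator
MODES = ("genome_minus_misc", "per_million_miRNA", "per_million_genome")


class NormalizationError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryAnnotation:
    """Per-category read tallies and the per-million normalization factor."""

    total_reads: int
    genome: int
    miscRNA: int
    tRNA: int
    miRNA: int
    unmatched: int

    @property
    def norm_denominator(self) -> int:
        return self.genome - self.miscRNA - self.tRNA

    @property
    def norm_factor(self) -> float:
        """Per-million scaling: 1e6 / (genome − miscRNA − tRNA)."""
        d = self.norm_denominator
        if d <= 0:
            raise NormalizationError("empty normalization denominator")
        return 1e6 / d

    def denominator(self, mode: str) -> int:
        if mode == "genome_minus_misc":
            return self.norm_denominator
        if mode == "per_million_miRNA":
            return self.miRNA
        if mode == "per_million_genome":
            return self.genome
        raise ValueError(f"unknown normalization mode {mode!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("total", self.total_reads),
            ("genome", self.genome),
            ("miscRNA", self.miscRNA),
            ("tRNA", self.tRNA),
            ("miRNA", self.miRNA),
            ("unmatched", self.unmatched),
            ("norm_denominator", self.norm_denominator),
        ]
        return pd.DataFrame(rows, columns=["category", "count"])


_CATEGORY_ROLES = {
    "genome": "normalization_genome",
    "miscRNA": "miscRNA",
    "tRNA": "tRNA",
    "miRNA": "miRNA",
}


def annotate_library(
    reads: Sequence[TrimmedRead],
    refs: ReferenceSet,
    multiplicities: Sequence[int] | None = None,
) -> LibraryAnnotation:
    """Tally reads per normalization category by exact (0-mismatch) mapping.

    A read belongs to a category when it maps to any region of that role;
    categories overlap freely.  Reads matching no region at all are tallied
    as unmatched.  Raises :class:`NormalizationError` when the denominator
    genome − miscRNA − tRNA is not positive.
    """
    role_regions = {
        cat: set(refs.names(role)) for cat, role in _CATEGORY_ROLES.items()
    }
    counts = {cat: 0 for cat in _CATEGORY_ROLES}
    total = unmatched = 0
    # collapse identical sequences once; mapping is sequence-determined
    from collections import Counter

    mult: Counter[str] = Counter()
    for i, r in enumerate(reads):
        w = 1 if multiplicities is None else int(multiplicities[i])
        mult[r.seq] += w

    for seq, w in mult.items():
        total += w
        if "N" in seq:
            unmatched += w
            continue
        hits = map_read(TrimmedRead(id="q", seq=seq), refs, max_mm=0)
        if not hits:
            unmatched += w
            continue
        hit_regions = {h.region for h in hits}
        matched_any = False
        for cat, regions in role_regions.items():
            if hit_regions & regions:
                counts[cat] += w
                matched_any = True
        if not matched_any:
            # maps only to analysis/flanking regions; not a category read
            pass

    ann = LibraryAnnotation(
        total_reads=total,
        genome=counts["genome"],
        miscRNA=counts["miscRNA"],
        tRNA=counts["tRNA"],
        miRNA=counts["miRNA"],
        unmatched=unmatched,
    )
    if ann.norm_denominator <= 0:
        raise NormalizationError("empty normalization denominator")
    return ann


def normalize(
    count: float, ann: LibraryAnnotation, mode: str = "genome_minus_misc"
) -> float:
    """Scale a raw count to reads per million of the chosen denominator."""
    d = ann.denominator(mode)
    if d <= 0:
        raise NormalizationError(f"zero denominator for mode {mode!r}")
    return count * 1e6 / d
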