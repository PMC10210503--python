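"""Ungapped, strand-aware, mismatch-tolerant short-read mapping.

Reads of 18-30 nt are matched end-to-end against a small reference set
(transgene constructs, repeat units, normalization categories), reporting
every placement whose Hamming distance is at most ``max_mm`` (0-3).  This is
exhaustive mapping at desk scale: correctness is defined by the all-window
Hamming scan, implemented here with a vectorised sliding-window comparison.

Coordinates are 0-based half-open.  A "+" hit means the read is sense to the
reference as written; a "-" hit means the read's reverse complement matches
the window (the read's 5' end then sits at ``end - 1``).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .sequence_io import TrimmedRead

#: Region roles. "analysis" regions are the mapping universe for the piRNA
#: metrics; the remaining roles feed library annotation and normalization.
ROLES = ("analysis", "normalization_genome", "miscRNA", "tRNA", "miRNA", "flanking")

_COMP = str.maketrans("ACGTN", "TGCAN")
_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class Region:
    name: str
    seq: str
    role: str = "analysis"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for region {self.name!r}")
        if len(self.seq) < 1:
            raise ValueError(f"region {self.name!r}: empty sequence")

    @property
    def length_kb(self) -> float:
        return len(self.seq) / 1000.0


class ReferenceSet:
    """Named reference sequences with a role per region; the mapping universe."""

    def __init__(self, regions: Iterable[Region]):
        self.regions: dict[str, Region] = {}
        for r in regions:
            if r.name in self.regions:
                raise ValueError(f"duplicate region name {r.name!r}")
            self.regions[r.name] = r
        # cached byte arrays for the vectorised scan
        self._enc: dict[str, np.ndarray] = {
            name: _encode(r.seq) for name, r in self.regions.items()
        }

    def __getitem__(self, name: str) -> Region:
        return self.regions[name]

    def __contains__(self, name: str) -> bool:
        return name in self.regions

    def __iter__(self):
        return iter(self.regions.values())

    def names(self, role: str | None = None) -> list[str]:
        return [
            r.name for r in self.regions.values() if role is None or r.role == role
        ]

    @classmethod
    def from_fasta(
        cls, entries: dict[str, str], roles: dict[str, str] | None = None
    ) -> "ReferenceSet":
        roles = roles or {}
        return cls(
            Region(name, seq, roles.get(name, "analysis"))
            for name, seq in entries.items()
        )


@dataclass(frozen=True, order=True)
class AlignmentHit:
    region: str
    start: int
    strand: str  # '+' or '-'
    read_id: str = field(compare=False)
    length: int = field(compare=False)
    mismatches: int = field(compare=False)
    multiplicity: int = field(compare=False, default=1)
    first_nt: str = field(compare=False, default="N")  # read's own 5' base, DNA space

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


def _scan(region_enc: np.ndarray, read_enc: np.ndarray, max_mm: int) -> np.ndarray:
    """Start positions where the encoded read matches with <= max_mm mismatches."""
    n = read_enc.size
    if n > region_enc.size:
        return np.empty(0, dtype=np.intp)
    windows = np.lib.stride_tricks.sliding_window_view(region_enc, n)
    mm = (windows != read_enc).sum(axis=1)
    return np.flatnonzero(mm <= max_mm)


def _find_exact(region_seq: str, query: str) -> list[int]:
    """All start positions of exact occurrences (fast path for max_mm = 0)."""
    out: list[int] = []
    pos = region_seq.find(query)
    while pos != -1:
        out.append(pos)
        pos = region_seq.find(query, pos + 1)
    return out


def map_read(
    read: TrimmedRead, refs: ReferenceSet, max_mm: int = 0
) -> list[AlignmentHit]:
    """All ungapped placements of ``read`` on either strand of every region.

    Precondition: the read contains no N (mismatch counting with N is
    ill-defined) and ``0 <= max_mm <= 3``.
    """
    if "N" in read.seq:
        raise ValueError(f"read {read.id!r} contains N; exclude from mapping")
    if not 0 <= max_mm <= 3:
        raise ValueError("max_mm must be within 0..3")
    rc = revcomp(read.seq)
    n = len(read.seq)
    hits: list[AlignmentHit] = []
    for name, region in refs.regions.items():
        for strand, query in (("+", read.seq), ("-", rc)):
            if max_mm == 0:
                placements = [(s, 0) for s in _find_exact(region.seq, query)]
            else:
                enc = refs._enc[name]
                arr = _encode(query)
                starts = _scan(enc, arr, max_mm)
                if starts.size == 0:
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(enc, n)[starts]
                mms = (windows != arr).sum(axis=1)
                placements = list(zip(starts.tolist(), mms.tolist()))
            for s, mm in placements:
                hits.append(
                    AlignmentHit(
                        region=name,
                        start=s,
                        strand=strand,
                        read_id=read.id,
                        length=n,
                        mismatches=int(mm),
                        first_nt=read.seq[0],
                    )
                )
    hits.sort()
    return hits


@dataclass
class MappingResult:
    hits: list[AlignmentHit]
    n_species: int
    n_unique: int
    n_multi: int
    n_unmapped: int


def map_library(
    reads: Sequence[TrimmedRead],
    refs: ReferenceSet,
    max_mm: int = 0,
    unique_only: bool = True,
    multiplicities: Sequence[int] | None = None,
) -> MappingResult:
    """Map a library, collapsing identical sequences and tracking uniqueness.

    Identical read sequences are collapsed to one species carrying the summed
    multiplicity.  With ``unique_only``, species hitting more than one
    (region, start, strand) placement across the *analysis*-role regions are
    excluded from the retained hits and tallied as multi-mappers; placements
    on normalization-category regions do not affect uniqueness.
    """
    mult = Counter()
    rep_id: dict[str, str] = {}
    for i, r in enumerate(reads):
        w = 1 if multiplicities is None else int(multiplicities[i])
        mult[r.seq] += w
        rep_id.setdefault(r.seq, r.id)

    analysis = set(refs.names("analysis"))
    retained: list[AlignmentHit] = []
    n_unique = n_multi = n_unmapped = 0
    for seq, w in mult.items():
        if "N" in seq:
            n_unmapped += 1
            continue
        hits = map_read(TrimmedRead(id=rep_id[seq], seq=seq), refs, max_mm)
        if not hits:
            n_unmapped += 1
            continue
        analysis_hits = [h for h in hits if h.region in analysis]
        if unique_only and len(analysis_hits) > 1:
            n_multi += 1
            hits = [h for h in hits if h.region not in analysis]
        else:
            n_unique += 1 if analysis_hits else 0
        retained.extend(
            AlignmentHit(
                region=h.region,
                start=h.start,
                strand=h.strand,
                read_id=h.read_id,
                length=h.length,
                mismatches=h.mismatches,
                multiplicity=w,
                first_nt=h.first_nt,
            )
            for h in hits
        )
    retained.sort()
    return MappingResult(
        hits=retained,
        n_species=len(mult),
        n_unique=n_unique,
        n_multi=n_multi,
        n_unmapped=n_unmapped,
    )


def hits_to_frame(hits: Iterable[AlignmentHit]) -> pd.DataFrame:
    """Hits as a TSV-ready table."""
    return pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "region": h.region,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "mismatches": h.mismatches,
                "multiplicity": h.multiplicity,
            }
            for h in hits
        ],
        columns=[
            "read_id",
            "region",
            "start",
            "end",
            "strand",
            "mismatches",
            "multiplicity",
        ],
    )


def hits_to_sam(hits: Iterable[AlignmentHit], refs: ReferenceSet) -> str:
    """SAM-flavoured export: flag 0/16 for strand, NM tag for mismatches."""
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for r in refs:
        lines.append(f"@SQ\tSN:{r.name}\tLN:{len(r.seq)}")
    for h in hits:
        flag = 0 if h.strand == "+" else 16
        lines.append(
            f"{h.read_id}\t{flag}\t{h.region}\t{h.start + 1}\t255\t{h.length}M"
            f"\t*\t0\t0\t*\t*\tNM:i:{h.mismatches}"
        )
    return "\n".join(lines) + "\n"
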