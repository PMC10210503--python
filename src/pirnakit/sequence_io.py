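"""Sequence I/O: FASTA/FASTQ reading, 3' adapter trimming, tabular output.

Small-RNA libraries arrive as 3'-adapter-ligated FASTQ; the insert (the
small RNA itself) is recovered by locating the adapter and keeping the
prefix.  Trimming here is exact-prefix, leftmost-occurrence matching with
a partial-adapter allowance at the read end, which keeps the operation
deterministic.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

# Default 3' adapter ligated to the small RNAs.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAG"
# Insert-length window applied after trimming (nt).
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
# Minimum number of adapter bases that must match when the adapter runs off
# the 3' end of the read.
MIN_PARTIAL_ADAPTER = 8

IUPAC_STRICT = set("ACGTN")


class FormatError(ValueError):
    """Malformed input file (duplicate names, bad characters, ...)."""


@dataclass(frozen=True)
class RawRead:
    """An untrimmed sequencer read."""

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")


@dataclass(frozen=True)
class TrimmedRead:
    """An adapter-trimmed insert within the accepted length window."""

    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)

    @property
    def first_nt(self) -> str:
        """5' nucleotide in DNA space (T stands for the RNA's 5' uridine)."""
        return self.seq[0]


@dataclass(frozen=True)
class TrimRejection:
    """A read that failed trimming, with a coded reason."""

    id: str
    reason: str  # one of: empty, no_adapter, too_short, too_long


def _open_text(path: str | Path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercased sequence mapping.

    Raises :class:`FormatError` on duplicate names, empty sequences or
    non-IUPAC characters, naming the offending record.
    """
    entries: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in entries:
                raise FormatError(f"duplicate FASTA header: {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise FormatError(f"empty sequence for record {rec.id!r}")
            bad = set(seq) - IUPAC_STRICT
            if bad:
                raise FormatError(
                    f"record {rec.id!r} contains non-IUPAC characters: {sorted(bad)}"
                )
            entries[rec.id] = seq
    return entries


def write_fasta(entries: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "wt") as fh:
        for name, seq in entries.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> Iterator[RawRead]:
    """Stream reads from a 4-line FASTQ file (Phred+33 qualities kept but unused)."""
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            yield RawRead(id=rec.id, seq=str(rec.seq).upper(), qual=None)


def write_fastq(reads: Iterable[RawRead], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


def find_adapter(seq: str, adapter: str, min_partial: int = MIN_PARTIAL_ADAPTER) -> int:
    """Position of the leftmost adapter occurrence in ``seq``, or -1.

    A full-adapter match anywhere wins; otherwise a prefix of the adapter of
    at least ``min_partial`` bases flush with the 3' end of the read counts.
    """
    pos = seq.find(adapter)
    if pos != -1:
        return pos
    # partial adapter hanging off the 3' end
    max_k = min(len(adapter) - 1, len(seq))
    for k in range(max_k, min_partial - 1, -1):
        if seq.endswith(adapter[:k]):
            return len(seq) - k
    return -1


def trim_adapter(
    read: RawRead,
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> TrimmedRead | TrimRejection:
    """Trim the 3' adapter off ``read`` and length-filter the insert.

    Returns a :class:`TrimmedRead` on success, or a :class:`TrimRejection`
    with reason ``empty``/``no_adapter``/``too_short``/``too_long``.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    if not read.seq:
        return TrimRejection(read.id, "empty")
    pos = find_adapter(read.seq, adapter)
    if pos == -1:
        return TrimRejection(read.id, "no_adapter")
    insert = read.seq[:pos]
    if len(insert) < min_len:
        return TrimRejection(read.id, "too_short")
    if len(insert) > max_len:
        return TrimRejection(read.id, "too_long")
    return TrimmedRead(id=read.id, seq=insert)


def trim_library(
    reads: Iterable[RawRead],
    adapter: str = DEFAULT_ADAPTER,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> tuple[list[TrimmedRead], dict[str, int]]:
    """Trim every read; failures are tallied by reason, never dropped silently."""
    kept: list[TrimmedRead] = []
    rejected: dict[str, int] = {"empty": 0, "no_adapter": 0, "too_short": 0, "too_long": 0}
    for r in reads:
        out = trim_adapter(r, adapter, min_len, max_len)
        if isinstance(out, TrimmedRead):
            kept.append(out)
        else:
            rejected[out.reason] += 1
    return kept, rejected


def write_table(
    rows: pd.DataFrame | Sequence[dict],
    path: str | Path,
    comment: str | None = None,
    allow_nan: bool = False,
) -> None:
    """Write rows as TSV with a deterministic column order; finite values only.

    ``comment`` becomes a leading ``# ...`` line (used to embed the seed in
    generated artifacts); ``allow_nan`` permits NaN for flagged-undefined
    fields while still rejecting infinities.
    """
    import numpy as np

    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    num = df.select_dtypes("number")
    if not num.empty:
        vals = num.to_numpy(dtype=float)
        ok = np.isfinite(vals) | (allow_nan & np.isnan(vals))
        if not ok.all():
            raise ValueError("non-finite value in table")
    with open(path, "wt") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_coverage(profile, path: str | Path) -> None:
    """Write a strand-resolved coverage profile as bedGraph-style lines.

    Four columns (region, start, end, value), 0-based half-open, with runs of
    equal value merged; the antisense track is written with negated values
    after the sense track.
    """
    import numpy as np

    lines: list[str] = []
    for vec, sign in ((profile.sense, 1.0), (profile.antisense, -1.0)):
        arr = np.asarray(vec, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError("non-finite coverage value")
        start = 0
        for i in range(1, len(arr) + 1):
            if i == len(arr) or arr[i] != arr[start]:
                if arr[start] != 0.0:
                    lines.append(
                        f"{profile.region}\t{start}\t{i}\t{sign * arr[start]:g}"
                    )
                start = i
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
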