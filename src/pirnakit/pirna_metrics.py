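"""piRNA/siRNA metrics: size distributions, coverage, densities, conversion
kinetics, 1U bias, ping-pong overlap signature, strand asymmetry,
dinucleotide content and the density~length regression.

Conventions
-----------
* All coordinates are 0-based half-open internally.
* A read's 5' end sits at ``start`` on the sense strand and ``end - 1`` on
  the antisense strand.
* The ping-pong register: two reads on opposite strands whose 5' ends
  overlap by k bases have the antisense 5' end at (sense 5' end) + k - 1;
  the canonical signature is an excess at k = 10.
* "1U" is evaluated on the read's own strand in DNA space (a leading T).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .aligner import AlignmentHit
from .library_annotation import LibraryAnnotation, normalize

PIRNA_WINDOW = (23, 29)
SIRNA_LENGTH = 21
#: overlap registers 1..K forming the z-score background (k=10 included)
DEFAULT_K = 25
#: minority-strand fraction thresholds for dual-strand classification
SYMMETRIC_MIN_MINORITY = 0.25
UNISTRAND_MAX_MINORITY = 0.02


def _region_hits(
    hits: Iterable[AlignmentHit], region: str, window: tuple[int, int] | None = None
) -> list[AlignmentHit]:
    out = [h for h in hits if h.region == region]
    if window is not None:
        lo, hi = window
        out = [h for h in out if lo <= h.length <= hi]
    return out


# ---------------------------------------------------------------------------
# size distribution


@dataclass
class SizeDistribution:
    """Normalized read counts per length and strand for one region."""

    region: str
    lengths: np.ndarray  # (n,) int
    sense: np.ndarray  # (n,) normalized counts
    antisense: np.ndarray

    @property
    def total(self) -> float:
        return float(self.sense.sum() + self.antisense.sum())

    def mode_length(self) -> int:
        combined = self.sense + self.antisense
        return int(self.lengths[int(np.argmax(combined))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "region": self.region,
                "length": self.lengths,
                "sense": self.sense,
                "antisense": self.antisense,
            }
        )


def size_distribution(
    hits: Iterable[AlignmentHit],
    ann: LibraryAnnotation,
    region: str,
    lo: int = 18,
    hi: int = 30,
    mode: str = "genome_minus_misc",
) -> SizeDistribution:
    """Strand-split, normalized length histogram of reads mapping to ``region``."""
    sub = _region_hits(hits, region)
    lengths = np.arange(lo, hi + 1)
    sense = np.zeros(lengths.size)
    anti = np.zeros(lengths.size)
    for h in sub:
        if not lo <= h.length <= hi:
            continue
        i = h.length - lo
        if h.strand == "+":
            sense[i] += h.multiplicity
        else:
            anti[i] += h.multiplicity
    factor = normalize(1.0, ann, mode)
    return SizeDistribution(region, lengths, sense * factor, anti * factor)


# ---------------------------------------------------------------------------
# coverage


@dataclass
class CoverageProfile:
    """Per-position normalized 5'-end counts, strand-resolved, one region."""

    region: str
    window: tuple[int, int]
    sense: np.ndarray
    antisense: np.ndarray

    @property
    def total(self) -> float:
        return float(self.sense.sum() + self.antisense.sum())


def coverage_profile(
    hits: Iterable[AlignmentHit],
    ann: LibraryAnnotation,
    region: str,
    region_length: int,
    window: tuple[int, int] = PIRNA_WINDOW,
    mode: str = "genome_minus_misc",
) -> CoverageProfile:
    """5'-end coverage of the length-selected reads on one region.

    Each retained hit adds its normalized multiplicity at its 5'-end
    position: ``start`` for sense hits, ``end - 1`` for antisense hits.
    """
    sense = np.zeros(region_length)
    anti = np.zeros(region_length)
    factor = normalize(1.0, ann, mode)
    for h in _region_hits(hits, region, window):
        if h.strand == "+":
            sense[h.start] += h.multiplicity * factor
        else:
            anti[h.end - 1] += h.multiplicity * factor
    return CoverageProfile(region, window, sense, anti)


# ---------------------------------------------------------------------------
# densities and conversion kinetics


@dataclass(frozen=True)
class RegionDensity:
    """Normalized read density (reads/kb) and 1U bias for one region."""

    region: str
    length_kb: float
    normalized_count: float
    one_u_fraction: float | None  # None when no reads fall in the window

    @property
    def density(self) -> float:
        return self.normalized_count / self.length_kb


def density_per_kb(
    hits: Iterable[AlignmentHit],
    ann: LibraryAnnotation,
    region: str,
    length_kb: float,
    window: tuple[int, int] = PIRNA_WINDOW,
    mode: str = "genome_minus_misc",
) -> RegionDensity:
    """Normalized windowed count per kb, plus the 1U fraction of that subset."""
    if length_kb <= 0:
        raise ValueError(f"region {region!r}: non-positive length")
    sub = _region_hits(hits, region, window)
    raw = sum(h.multiplicity for h in sub)
    one_u = sum(h.multiplicity for h in sub if h.first_nt == "T")
    norm = normalize(raw, ann, mode) if raw else 0.0
    return RegionDensity(
        region=region,
        length_kb=length_kb,
        normalized_count=norm,
        one_u_fraction=(one_u / raw) if raw else None,
    )


@dataclass
class ConversionSeries:
    """Per-generation densities for one region along one lineage."""

    lineage: str  # "maternal" | "paternal"
    region: str
    densities: dict[int, RegionDensity] = field(default_factory=dict)
    sirna_pirna_ratio: dict[int, float | None] = field(default_factory=dict)

    def add(self, generation: int, d: RegionDensity,
            sirna_pirna: float | None = None) -> None:
        self.densities[generation] = d
        if sirna_pirna is not None:
            self.sirna_pirna_ratio[generation] = sirna_pirna

    @property
    def generations(self) -> list[int]:
        return sorted(self.densities)


def generation_ratio(series: ConversionSeries, g_from: int, g_to: int) -> float:
    """Fold change in density between two generations (reported to 2 d.p.)."""
    for g in (g_from, g_to):
        if g not in series.densities:
            raise KeyError(f"generation G{g} missing from series")
    d_from = series.densities[g_from].density
    if d_from <= 0:
        raise ValueError(f"zero density at G{g_from}")
    return series.densities[g_to].density / d_from


def fit_conversion_rate(series: ConversionSeries) -> float:
    """Per-generation conversion probability from a paternal-lineage series.

    Fits D(g) = D_max * (1 - (1-c)^g) by least squares over the observed
    generations, with D_max profiled on a grid around the last observed
    density.  Returns c in [0, 1].
    """
    gens = np.array(series.generations, dtype=float)
    dens = np.array([series.densities[g].density for g in series.generations])
    if gens.size < 2:
        raise ValueError("need at least two generations")
    from scipy.optimize import minimize_scalar

    def sse(c: float) -> float:
        pred_shape = 1.0 - (1.0 - c) ** gens
        # profile D_max analytically given c
        denom = (pred_shape**2).sum()
        if denom == 0:
            return float((dens**2).sum())
        dmax = (pred_shape * dens).sum() / denom
        return float(((dmax * pred_shape - dens) ** 2).sum())

    res = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# ping-pong overlap signature


@dataclass
class OverlapSignature:
    """Sense/antisense 5'-overlap pair counts and z-scores over registers 1..K."""

    pair_counts: np.ndarray  # index 0 -> k=1
    zscores: np.ndarray | None  # None when the background sd is zero
    K: int

    @property
    def degenerate(self) -> bool:
        return self.zscores is None

    def z(self, k: int) -> float:
        if self.zscores is None:
            raise ValueError("degenerate signature: zero variance background")
        return float(self.zscores[k - 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "overlap": np.arange(1, self.K + 1),
                "pair_count": self.pair_counts,
                "zscore": np.full(self.K, np.nan) if self.zscores is None else self.zscores,
            }
        )


def overlap_signature_from_profiles(
    sense5: np.ndarray, antisense5: np.ndarray, K: int = DEFAULT_K
) -> OverlapSignature:
    """Ping-pong signature from strand-resolved 5'-end count vectors.

    pair_counts[k] = sum_p sense5[p] * antisense5[p + k - 1]: the product of
    5'-end weights for every pair of opposite-strand reads whose 5' ends
    overlap by k bases; z-scores are taken against the k = 1..K background.
    """
    if K < 10:
        raise ValueError("K must be >= 10 to include the ping-pong register")
    s = np.asarray(sense5, dtype=float)
    a = np.asarray(antisense5, dtype=float)
    if s.sum() <= 0 or a.sum() <= 0:
        raise ValueError("both strands need at least one read")
    counts = np.zeros(K)
    L = s.size
    for k in range(1, K + 1):
        shift = k - 1
        if shift < L:
            counts[k - 1] = float(np.dot(s[: L - shift], a[shift:]))
    sd = counts.std(ddof=0)
    if sd == 0:
        return OverlapSignature(pair_counts=counts, zscores=None, K=K)
    z = (counts - counts.mean()) / sd
    return OverlapSignature(pair_counts=counts, zscores=z, K=K)


def overlap_signature(
    source: CoverageProfile | Iterable[AlignmentHit],
    K: int = DEFAULT_K,
    *,
    ann: LibraryAnnotation | None = None,
    region: str | None = None,
    region_length: int | None = None,
    window: tuple[int, int] = PIRNA_WINDOW,
) -> OverlapSignature:
    """Ping-pong signature from a coverage profile, or directly from hits."""
    if isinstance(source, CoverageProfile):
        return overlap_signature_from_profiles(source.sense, source.antisense, K)
    if ann is None or region is None or region_length is None:
        raise ValueError("hit-based signature needs ann, region and region_length")
    prof = coverage_profile(source, ann, region, region_length, window)
    return overlap_signature_from_profiles(prof.sense, prof.antisense, K)


# ---------------------------------------------------------------------------
# strand asymmetry


def strand_asymmetry(profile: CoverageProfile) -> tuple[float, str]:
    """Sense fraction and dual-strand class of a coverage profile.

    Classes by minority-strand fraction m: m >= 0.25 symmetric_dual,
    0.02 <= m < 0.25 asymmetric_dual, m < 0.02 uni_strand.  The thresholds
    are this package's operational definitions of the qualitative classes.
    """
    s, a = float(profile.sense.sum()), float(profile.antisense.sum())
    total = s + a
    if total <= 0:
        raise ValueError("zero coverage")
    sense_fraction = s / total
    minority = min(sense_fraction, 1.0 - sense_fraction)
    if minority >= SYMMETRIC_MIN_MINORITY:
        cls = "symmetric_dual"
    elif minority >= UNISTRAND_MAX_MINORITY:
        cls = "asymmetric_dual"
    else:
        cls = "uni_strand"
    return sense_fraction, cls


# ---------------------------------------------------------------------------
# siRNA / piRNA partition


def sirna_pirna_ratio(
    hits: Iterable[AlignmentHit],
    ann: LibraryAnnotation,
    region: str,
    pirna_window: tuple[int, int] = PIRNA_WINDOW,
    sirna_length: int = SIRNA_LENGTH,
    mode: str = "genome_minus_misc",
) -> float | None:
    """Normalized 23-29-nt count over normalized 21-nt count for one region.

    Returns None (undefined) when the region has no 21-nt reads.
    """
    sub = _region_hits(hits, region)
    pirna = sum(h.multiplicity for h in sub if pirna_window[0] <= h.length <= pirna_window[1])
    sirna = sum(h.multiplicity for h in sub if h.length == sirna_length)
    if sirna == 0:
        return None
    return normalize(pirna, ann, mode) / normalize(sirna, ann, mode)


# ---------------------------------------------------------------------------
# sequence composition


DINUCLEOTIDES = ["".join(p) for p in itertools.product("ACGT", repeat=2)]


@dataclass
class DinucleotideProfile:
    region: str
    frequencies: dict[str, float]

    def __getitem__(self, dinuc: str) -> float:
        return self.frequencies[dinuc]


def dinucleotide_content(seq: str, region: str = "") -> DinucleotideProfile:
    """Frequencies of the 16 dinucleotides over overlapping windows.

    Windows containing N are skipped and the denominator adjusted.
    """
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 nt")
    seq = seq.upper()
    counts = dict.fromkeys(DINUCLEOTIDES, 0)
    n_valid = 0
    for i in range(len(seq) - 1):
        d = seq[i : i + 2]
        if "N" in d:
            continue
        counts[d] += 1
        n_valid += 1
    if n_valid == 0:
        raise ValueError("no N-free dinucleotide window in sequence")
    return DinucleotideProfile(
        region=region, frequencies={d: c / n_valid for d, c in counts.items()}
    )


def fit_density_model(
    table: pd.DataFrame,
    response: str = "density",
    predictors: Sequence[str] = ("length_kb",),
):
    """OLS of piRNA density on sequence length and composition predictors.

    Returns the fitted statsmodels results object (``.params``,
    ``.pvalues``).  Raises on fewer than 3 rows or a rank-deficient design,
    naming the offending predictor.
    """
    import statsmodels.api as sm

    if len(table) < 3:
        raise ValueError("need at least 3 rows to fit")
    X = table.loc[:, list(predictors)].astype(float)
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        # identify a predictor that adds no rank
        base = design.to_numpy()[:, :1]
        for col in X.columns:
            cand = np.column_stack([base, X[col].to_numpy()])
            if np.linalg.matrix_rank(cand) == np.linalg.matrix_rank(base):
                raise ValueError(f"rank-deficient design: predictor {col!r}")
        raise ValueError("rank-deficient design: collinear predictors")
    model = sm.OLS(table[response].astype(float), design)
    return model.fit()
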