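"""Synthetic small-RNA study generator.

Every input the pipeline consumes can be generated here with the statistical
structure the analyses assume: adapter-ligated small-RNA libraries with a
23-29-nt piRNA mode and a 21-nt siRNA mode, tunable 1U bias, per-region
strand ratios, a tunable fraction of ping-pong pairs (sense/antisense 5' ends
overlapping by exactly 10 nt), background reads for the normalization
categories, per-generation density growth toward a plateau, egg-chamber
ON/OFF silencing counts, and qPCR plate tables built by inverting the
quantification formulas.

Conversion model
----------------
A paternally inherited locus produces piRNAs at density

    D(g) = D_max * (1 - (1 - c)**g)

at generation g, where c is the per-generation conversion probability; a
maternally inherited locus sits at D_max throughout.  The same c drives the
egg-chamber repression probability p_g = 1 - (1 - c)**g.  This geometric
approach to plateau is the minimal model consistent with all-or-none chamber
states and saturation within about four generations at c ~ 0.45.

All draws are reproducible: each artifact derives its RNG stream from the
config seed plus a fixed stream label.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .aligner import Region, ReferenceSet
from .qpcr_stats import ChipSample, RtQpcrSample
from .repression_assay import EggChamberCount
from .sequence_io import DEFAULT_ADAPTER, RawRead

_BASES = np.array(list("ACGT"))

# stream labels so independent artifacts never share an RNG stream
_STREAM_REFS = 1
_STREAM_LIBRARY = 2
_STREAM_CHAMBERS = 3
_STREAM_QPCR = 4
_LINEAGE_CODE = {"maternal": 1, "paternal": 2}


@dataclass(frozen=True)
class RegionSpec:
    """One reference region to synthesize."""

    name: str
    length: int
    role: str = "analysis"
    # (name, start, end) sub-domains, 0-based half-open, within the parent
    subregions: tuple[tuple[str, int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError(f"region {self.name!r}: length must be >= 2")
        last_end = None
        for sub, start, end in self.subregions:
            if not 0 <= start < end <= self.length:
                raise ValueError(f"sub-region {sub!r} outside parent {self.name!r}")
            if last_end is not None and start < last_end:
                raise ValueError(f"sub-region {sub!r} overlaps its predecessor")
            last_end = end


def _default_length_distribution() -> dict[int, float]:
    # unimodal piRNA length profile peaking at 25-26 nt
    return {23: 0.08, 24: 0.14, 25: 0.24, 26: 0.24, 27: 0.16, 28: 0.09, 29: 0.05}


def _default_references() -> tuple[RegionSpec, ...]:
    return (
        # 18-kb multi-domain construct: P-element ends, reporter, plasmid backbone
        RegionSpec(
            "PlArB",
            18000,
            "analysis",
            subregions=(
                ("P5", 0, 580),
                ("lacZ", 580, 4080),
                ("plasmid", 4080, 5880),
                ("P3", 17770, 18000),
            ),
        ),
        # 0.9-kb unique subtelomeric domain
        RegionSpec("T3", 900, "analysis"),
        # 4.1-kb eye-colour gene carried by the recipient construct
        RegionSpec("white", 4100, "analysis"),
        # flanking gene at the insertion site
        RegionSpec("flank_gene", 2000, "flanking"),
        # normalization categories; miscRNA/tRNA/miRNA are carved out of the
        # genome region so those reads also count as genome-matching
        RegionSpec("genome", 20000, "normalization_genome"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one synthetic study."""

    seed: int = 0
    references: tuple[RegionSpec, ...] = field(default_factory=_default_references)
    # plateau densities D_max in normalized reads/kb per analysis region
    plateau_density: dict[str, float] = field(
        default_factory=lambda: {"PlArB": 1000.0, "T3": 3000.0, "white": 1630.0}
    )
    # sense-strand fraction per region (dual-strand symmetric vs asymmetric)
    strand_ratio: dict[str, float] = field(
        default_factory=lambda: {"PlArB": 0.5, "T3": 0.88, "white": 0.5}
    )
    one_u_bias: float = 0.75
    pingpong_fraction: float = 0.3
    # 21-nt siRNA output as a fraction of the piRNA plateau, constant per
    # generation in the paternal lineage, absent in the maternal lineage
    sirna_fraction_21nt: float = 0.2
    length_distribution: dict[int, float] = field(
        default_factory=_default_length_distribution
    )
    # total read multiplicity and number of distinct species per category
    background_counts: dict[str, int] = field(
        default_factory=lambda: {
            "genome": 200_000,
            "miscRNA": 20_000,
            "tRNA": 10_000,
            "miRNA": 40_000,
        }
    )
    background_species: dict[str, int] = field(
        default_factory=lambda: {
            "genome": 2_000,
            "miscRNA": 200,
            "tRNA": 100,
            "miRNA": 400,
        }
    )
    mismatch_read_fraction: float = 0.05
    mismatch_count: int = 3
    # conversion kinetics
    conversion_probability: float = 0.45
    # optional length dependence c(L) = clamp(c0 * L0 / L); off by default
    length_dependent_conversion: bool = False
    conversion_ref_length_kb: float = 1.0
    # egg-chamber model
    chambers_per_subline: int = 150
    n_sublines: int = 4
    maternal_repression: float = 0.95
    # qPCR model
    true_rt_ratios: dict[str, float] = field(
        default_factory=lambda: {"PlArB": 0.8, "T3": 1.6}
    )
    true_enrichments: dict[str, float] = field(
        default_factory=lambda: {"42AB": 8.0, "PlArB": 4.0, "T3": 6.0}
    )
    ct_noise_sd: float = 0.1
    input_fraction: float = 0.05
    n_bio_replicates: int = 3
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        for p in (self.one_u_bias, self.pingpong_fraction, self.maternal_repression):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0.0 <= self.conversion_probability <= 1.0:
            raise ValueError("conversion_probability must be in [0, 1]")
        if any(d < 0 for d in self.plateau_density.values()):
            raise ValueError("densities must be >= 0")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def scaled(self, factor: float) -> "SimulationConfig":
        """Scale sequencing depth down for quick runs.

        Normalized densities are depth-invariant by construction (raw counts
        and the normalization denominator shrink together), so the configured
        reads/kb targets still hold at any scale; only sampling noise grows.
        """
        return replace(
            self,
            background_counts={
                k: max(1, int(v * factor)) for k, v in self.background_counts.items()
            },
            background_species={
                k: max(1, int(v * factor)) for k, v in self.background_species.items()
            },
        )

    def region_conversion(self, region: str, length_kb: float) -> float:
        if not self.length_dependent_conversion:
            return self.conversion_probability
        c = self.conversion_probability * self.conversion_ref_length_kb / length_kb
        return min(1.0, max(0.0, c))


def expected_density(cfg: SimulationConfig, region: str, generation: int,
                     lineage: str, length_kb: float) -> float:
    """Closed-form D(g) the sampler targets (normalized reads/kb)."""
    d_max = cfg.plateau_density[region]
    if lineage == "maternal":
        return d_max
    c = cfg.region_conversion(region, length_kb)
    return d_max * (1.0 - (1.0 - c) ** generation)


def _rng(cfg: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, *stream])


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


# carved layout of the normalization categories inside the genome region
_CARVED = {"miscRNA": (0, 600), "tRNA": (600, 900), "miRNA": (900, 1300)}


def make_references(cfg: SimulationConfig) -> tuple[ReferenceSet, pd.DataFrame]:
    """Random reference sequences at the configured lengths, plus a BED table.

    The miscRNA/tRNA/miRNA category regions are substrings of the genome
    region, so reads from those categories also map to the genome — the
    structure the normalization denominator (genome − miscRNA − tRNA)
    assumes.  Reproducible: the same seed yields identical sequences.
    """
    rng = _rng(cfg, _STREAM_REFS)
    regions: list[Region] = []
    bed_rows: list[dict] = []
    genome_seq = None
    for spec in cfg.references:
        seq = _random_seq(rng, spec.length)
        regions.append(Region(spec.name, seq, spec.role))
        if spec.role == "normalization_genome":
            genome_seq = seq
        for sub, start, end in spec.subregions:
            bed_rows.append(
                {"region": spec.name, "start": start, "end": end, "name": sub}
            )
    if genome_seq is not None:
        for name, (start, end) in _CARVED.items():
            regions.append(Region(name, genome_seq[start:end], name))
            bed_rows.append(
                {"region": "genome", "start": start, "end": end, "name": name}
            )
    bed = pd.DataFrame(bed_rows, columns=["region", "start", "end", "name"])
    return ReferenceSet(regions), bed


def _norm_denominator(cfg: SimulationConfig) -> int:
    # reads counted as genome minus misc/tRNA = genome-only species + miRNA
    return cfg.background_counts["genome"] + cfg.background_counts["miRNA"]


def _sample_five_prime(
    rng: np.random.Generator,
    region_seq: str,
    strand: str,
    length: int,
    want_t: bool,
    max_tries: int = 200,
) -> int:
    """A 5'-end coordinate whose read-space first base is (or is not) T.

    Sense reads start at their 5' coordinate (first base = reference base);
    antisense reads end there (first base = complement of the reference
    base, so a 5' U corresponds to reference A).
    """
    L = len(region_seq)
    lo, hi = (0, L - length) if strand == "+" else (length - 1, L - 1)
    target = ("T" if strand == "+" else "A") if want_t else None
    for _ in range(max_tries):
        p5 = int(rng.integers(lo, hi + 1))
        base = region_seq[p5]
        is_t = base == ("T" if strand == "+" else "A")
        if is_t == want_t:
            return p5
    return int(rng.integers(lo, hi + 1))  # composition degenerate; give up on bias


def _read_from_placement(region_seq: str, strand: str, p5: int, length: int) -> str:
    from .aligner import revcomp

    if strand == "+":
        return region_seq[p5 : p5 + length]
    return revcomp(region_seq[p5 - length + 1 : p5 + 1])


def _mutate(rng: np.random.Generator, seq: str, n_sub: int) -> str:
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_sub, len(chars)), replace=False)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def simulate_library(
    cfg: SimulationConfig, generation: int, lineage: str
) -> tuple[list[RawRead], pd.DataFrame, ReferenceSet]:
    """One adapter-ligated small-RNA library plus its per-read truth table.

    piRNA reads (23-29 nt) are placed per analysis region at the conversion
    model's density for (generation, lineage); a ``pingpong_fraction`` of
    antisense reads is paired to a sense read with 5' ends overlapping by
    exactly 10 nt; every read's 5' base is U (DNA T) with probability
    ``one_u_bias`` (paired reads satisfy the bias through partner choice).
    21-nt siRNA reads are emitted on both strands in the paternal lineage.
    Background species for the normalization categories carry multiplicities
    so the library totals match the configured counts.  The 3' adapter is
    appended to every read.
    """
    if lineage not in _LINEAGE_CODE:
        raise ValueError("lineage must be 'maternal' or 'paternal'")
    refs, _ = make_references(cfg)
    rng = _rng(cfg, _STREAM_LIBRARY, generation, _LINEAGE_CODE[lineage])
    denom = _norm_denominator(cfg)
    raw_per_normalized = denom / 1e6  # raw count per 1 normalized count

    lengths = np.array(sorted(cfg.length_distribution))
    probs = np.array([cfg.length_distribution[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()

    reads: list[RawRead] = []
    truth: list[dict] = []
    serial = 0

    def emit(seq: str, *, region: str, kind: str, strand: str, p5: int,
             paired: bool, n_mm: int, multiplicity: int) -> None:
        nonlocal serial
        rid = f"{lineage[:2]}_g{generation}_{serial:07d}"
        serial += 1
        reads.append(RawRead(id=rid, seq=seq + cfg.adapter))
        truth.append(
            {
                "read_id": rid,
                "region": region,
                "kind": kind,
                "length": len(seq),
                "strand": strand,
                "five_prime": p5,
                "first_nt": seq[0] if seq else "",
                "paired": paired,
                "n_mismatches": n_mm,
                "multiplicity": multiplicity,
            }
        )

    for region in refs:
        if region.role != "analysis" or region.name not in cfg.plateau_density:
            continue
        seq = region.seq
        kb = region.length_kb
        target = expected_density(cfg, region.name, generation, lineage, kb)
        n_pirna = int(rng.poisson(target * kb * raw_per_normalized))
        s_ratio = cfg.strand_ratio.get(region.name, 0.5)
        n_sense = int(rng.binomial(n_pirna, s_ratio)) if n_pirna else 0
        n_anti = n_pirna - n_sense

        sense_p5: list[int] = []
        for _ in range(n_sense):
            length = int(rng.choice(lengths, p=probs))
            want_t = rng.random() < cfg.one_u_bias
            p5 = _sample_five_prime(rng, seq, "+", length, want_t)
            sense_p5.append(p5)
            read_seq = _read_from_placement(seq, "+", p5, length)
            n_mm = 0
            if rng.random() < cfg.mismatch_read_fraction:
                read_seq = _mutate(rng, read_seq, cfg.mismatch_count)
                n_mm = cfg.mismatch_count
            emit(read_seq, region=region.name, kind="piRNA", strand="+", p5=p5,
                 paired=False, n_mm=n_mm, multiplicity=1)

        n_paired = int(rng.binomial(n_anti, cfg.pingpong_fraction)) if n_anti else 0
        L = len(seq)
        for i in range(n_anti):
            length = int(rng.choice(lengths, p=probs))
            want_t = rng.random() < cfg.one_u_bias
            paired = i < n_paired and sense_p5
            p5 = None
            if paired:
                # antisense 5' end 9 bp downstream of a sense partner's 5' end
                # (10-nt overlap register); honour the 1U draw via partner choice
                candidates = [
                    ps + 9
                    for ps in sense_p5
                    if length - 1 <= ps + 9 <= L - 1
                    and (seq[ps + 9] == "A") == want_t
                ]
                if not candidates:
                    candidates = [
                        ps + 9 for ps in sense_p5 if length - 1 <= ps + 9 <= L - 1
                    ]
                if candidates:
                    p5 = candidates[int(rng.integers(0, len(candidates)))]
            if p5 is None:
                paired = False
                p5 = _sample_five_prime(rng, seq, "-", length, want_t)
            read_seq = _read_from_placement(seq, "-", p5, length)
            n_mm = 0
            if rng.random() < cfg.mismatch_read_fraction:
                read_seq = _mutate(rng, read_seq, cfg.mismatch_count)
                n_mm = cfg.mismatch_count
            emit(read_seq, region=region.name, kind="piRNA", strand="-", p5=p5,
                 paired=bool(paired), n_mm=n_mm, multiplicity=1)

        # constant 21-nt siRNA output in the paternal lineage only
        if lineage == "paternal" and cfg.sirna_fraction_21nt > 0:
            d_max = cfg.plateau_density[region.name]
            n_sirna = int(
                rng.poisson(cfg.sirna_fraction_21nt * d_max * kb * raw_per_normalized)
            )
            for _ in range(n_sirna):
                strand = "+" if rng.random() < 0.5 else "-"
                lo, hi = (0, L - 21) if strand == "+" else (20, L - 1)
                p5 = int(rng.integers(lo, hi + 1))
                read_seq = _read_from_placement(seq, strand, p5, 21)
                emit(read_seq, region=region.name, kind="siRNA", strand=strand,
                     p5=p5, paired=False, n_mm=0, multiplicity=1)

    # background species with multiplicities for the normalization categories
    for category, total in cfg.background_counts.items():
        n_species = cfg.background_species[category]
        source = refs[category if category != "genome" else "genome"]
        seq = source.seq
        lo_pos = _CARVED["miRNA"][1] if category == "genome" else 0
        base_mult, remainder = divmod(total, n_species)
        for j in range(n_species):
            length = int(rng.choice(lengths, p=probs))
            strand = "+" if rng.random() < 0.5 else "-"
            L = len(seq)
            lo, hi = (lo_pos, L - length) if strand == "+" else (lo_pos + length - 1, L - 1)
            p5 = int(rng.integers(lo, hi + 1))
            read_seq = _read_from_placement(seq, strand, p5, length)
            mult = base_mult + (1 if j < remainder else 0)
            emit(read_seq, region=category, kind=f"background_{category}",
                 strand=strand, p5=p5, paired=False, n_mm=0, multiplicity=mult)

    truth_df = pd.DataFrame(truth)
    return reads, truth_df, refs


def expand_multiplicities(
    reads: Sequence[RawRead], truth: pd.DataFrame
) -> list[RawRead]:
    """Expand species-level reads into per-read records (for FASTQ realism)."""
    mult = dict(zip(truth["read_id"], truth["multiplicity"]))
    out: list[RawRead] = []
    for r in reads:
        m = int(mult.get(r.id, 1))
        if m == 1:
            out.append(r)
        else:
            out.extend(RawRead(id=f"{r.id}.{i}", seq=r.seq) for i in range(m))
    return out


def simulate_egg_chambers(
    cfg: SimulationConfig, generation: int, lineage: str, region: str = "PlArB"
) -> list[EggChamberCount]:
    """ON/OFF chamber counts for each subline at one generation.

    Each chamber is repressed with probability p_g = 1 - (1-c)^g in the
    paternal lineage and with the maternal plateau probability otherwise.
    """
    if lineage not in _LINEAGE_CODE:
        raise ValueError("lineage must be 'maternal' or 'paternal'")
    rng = _rng(cfg, _STREAM_CHAMBERS, generation, _LINEAGE_CODE[lineage])
    if lineage == "maternal":
        p = cfg.maternal_repression
    else:
        p = 1.0 - (1.0 - cfg.conversion_probability) ** generation
    out = []
    for s in range(cfg.n_sublines):
        n = cfg.chambers_per_subline
        k = int(rng.binomial(n, p))
        out.append(
            EggChamberCount(
                lineage=lineage,
                generation=generation,
                subline=chr(ord("A") + s),
                n_total=n,
                n_repressed=k,
            )
        )
    return out


def simulate_qpcr(
    cfg: SimulationConfig,
) -> tuple[list[RtQpcrSample], list[ChipSample]]:
    """RT-qPCR and ChIP-qPCR sample tables built by inverting the formulas.

    With ct_noise_sd = 0, running the quantification on these tables returns
    the configured expression ratios and fold enrichments exactly.
    """
    rng = _rng(cfg, _STREAM_QPCR)
    sd = cfg.ct_noise_sd
    rt: list[RtQpcrSample] = []
    for rep in range(1, cfg.n_bio_replicates + 1):
        sid = f"bio{rep}"
        base_sq = 2.0  # arbitrary reference-scale quantity
        ref_triplicate = tuple(base_sq * 2.0 ** rng.normal(0.0, sd) for _ in range(3))
        rt.append(RtQpcrSample(sample_id=sid, gene="RpL32", sq=ref_triplicate))
        for gene, ratio in cfg.true_rt_ratios.items():
            trip = tuple(
                ratio * base_sq * 2.0 ** rng.normal(0.0, sd) for _ in range(3)
            )
            rt.append(RtQpcrSample(sample_id=sid, gene=gene, sq=trip))

    chip: list[ChipSample] = []
    dilution = 1.0 / cfg.input_fraction
    dct_ns = 8.0  # arbitrary nonspecific pulldown offset
    for rep in range(1, cfg.n_bio_replicates + 1):
        sid = f"bio{rep}"
        for region, enrichment in cfg.true_enrichments.items():
            ct_input = 20.0 + rng.normal(0.0, sd)
            offset = ct_input - np.log2(dilution)
            dct_chip = dct_ns - np.log2(enrichment)
            chip.append(
                ChipSample(
                    sample_id=sid,
                    target_region=region,
                    mean_ct_chip=float(dct_chip + offset + rng.normal(0.0, sd)),
                    mean_ct_input=float(ct_input),
                    mean_ct_ns=float(dct_ns + offset + rng.normal(0.0, sd)),
                    input_fraction=cfg.input_fraction,
                )
            )
    return rt, chip
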