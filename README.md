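# pirnakit

Analysis toolkit for quantifying how a naïve sequence embedded in (or
flanked by) a piRNA cluster is *converted* into a piRNA-producing locus
across generations — the situation of a paternally inherited transgene whose
homologous maternal piRNAs are absent in the first generation.

piRNAs are 23–29-nt germline small RNAs that silence transposable elements
in *Drosophila*; 21-nt siRNAs arise as a by-product of dual-stranded cluster
transcripts. `pirnakit` implements the small-RNA sequencing analyses that
diagnose genuine piRNA production and follow its transgenerational kinetics,
together with the companion qPCR and egg-chamber silencing statistics, and a
synthetic-data generator so the whole pipeline is testable without any
sequencing download.

## What it computes

**Small-RNA metrics** (per reference region, strand-resolved, length-selected):

- Ungapped, mismatch-tolerant (0–3 mm) mapping of 18–30-nt reads to a small
  reference set, on both strands, reporting *all* placements; uniqueness is
  evaluated within the analysis regions.
- Depth normalization: counts are scaled to reads per million
  `genome − miscRNA − tRNA` mapped reads (alternatives: per million miRNA
  reads, per million genome reads).
- Size distributions (18–30 nt, sense/antisense), 5′-end coverage profiles,
  and density in normalized reads/kb, e.g. 2698 normalized reads on a
  4.1-kb gene → 658.05 reads/kb.
- 1U bias: the fraction of reads whose 5′ base is uridine (T in DNA space).
- Ping-pong signature: pair counts of sense/antisense reads whose 5′ ends
  overlap by *k* bases,
  `pair_counts[k] = Σ_p sense5(p) · antisense5(p + k − 1)`, with
  `z(k) = (pair_counts[k] − mean) / sd` over registers k = 1..25; an excess
  at k = 10 is the signature of the piRNA amplification loop.
- Strand asymmetry classes by minority-strand fraction *m*: symmetric dual
  (m ≥ 0.25), asymmetric dual (0.02 ≤ m < 0.25), uni-strand (m < 0.02).
- siRNA/piRNA partition: normalized 23–29-nt over 21-nt counts.
- Conversion kinetics: per-generation densities, generation ratios
  (e.g. 658 → 1480 reads/kb is a G4/G1 ratio of 2.25), and the
  per-generation conversion probability *c* fitted from
  `D(g) = D_max · (1 − (1 − c)^g)`.
- Dinucleotide composition and the OLS model
  `density ~ length + dinucleotide frequency`.

**qPCR** — RT-qPCR expression ratios `meanSq(gene)/meanSq(RpL32)`; ChIP-qPCR
`ΔCt = meanCt[ChIP] − (meanCt[Input] − log2(dilution factor))` with the
dilution factor the reciprocal of the input chromatin fraction (5% → 20),
fold enrichment `2^(ΔCt_NS − ΔCt_ChIP)` over the nonspecific antibody, and
rescaling to the 42AB control region; Welch t-test and one-way ANOVA + Tukey
HSD group comparisons.

**Repression assay** — percent silenced (OFF) egg chambers with Wilson 95%
intervals and per-generation mean ± SD across sublines.

**Synthetic data** — seeded generator for reference sets (an 18-kb
multi-domain construct, a 0.9-kb unique domain, a 4.1-kb gene), adapter-
ligated libraries with tunable 1U bias, strand ratio, ping-pong fraction,
siRNA content and background categories, plus egg-chamber counts and qPCR
plates built by inverting the quantification formulas.

## Worked example

Simulate a paternal-inheritance series at 20% sequencing depth, run the
stack, and follow the conversion of the 18-kb construct:

```python
from pirnakit import (SimulationConfig, simulate_library, map_library,
                      annotate_library, density_per_kb, coverage_profile,
                      strand_asymmetry, overlap_signature, generation_ratio,
                      fit_conversion_rate)
from pirnakit.pirna_metrics import ConversionSeries
from pirnakit.sequence_io import trim_library

cfg = SimulationConfig(seed=1).scaled(0.2)
series = ConversionSeries("paternal", "PlArB")
for g in (1, 2, 3, 4):
    reads, truth, refs = simulate_library(cfg, g, "paternal")
    trimmed, rejected = trim_library(reads, cfg.adapter)
    mult = [int(m) for m in truth["multiplicity"]]
    hits = map_library(trimmed, refs, max_mm=0, multiplicities=mult).hits
    ann = annotate_library(trimmed, refs, multiplicities=mult)
    dens = density_per_kb(hits, ann, "PlArB", refs["PlArB"].length_kb)
    series.add(g, dens)
    prof = coverage_profile(hits, ann, "PlArB", len(refs["PlArB"].seq))
    frac, cls = strand_asymmetry(prof)
    sig = overlap_signature(prof)
    print(f"G{g}: {dens.density:7.1f} reads/kb  1U={dens.one_u_fraction:.2f}  "
          f"sense={frac:.2f} ({cls})  z(10)={sig.z(10):.1f}")

print(f"G4/G1 density ratio: {generation_ratio(series, 1, 4):.2f}")
print(f"fitted conversion rate c: {fit_conversion_rate(series):.2f}")
```

Output:

```
G1:   401.6 reads/kb  1U=0.76  sense=0.46 (symmetric_dual)  z(10)=4.8
G2:   644.7 reads/kb  1U=0.75  sense=0.48 (symmetric_dual)  z(10)=4.8
G3:   803.2 reads/kb  1U=0.74  sense=0.49 (symmetric_dual)  z(10)=4.8
G4:   884.3 reads/kb  1U=0.74  sense=0.48 (symmetric_dual)  z(10)=4.8
G4/G1 density ratio: 2.20
fitted conversion rate c: 0.39
```

The density climbs toward the plateau (1000 reads/kb configured) over four
generations; the high 1U fraction, balanced strand usage and the strong
z-score at the 10-nt overlap register mark the reads as dual-strand-cluster
piRNAs; the fitted *c* approaches the generating conversion probability
(0.45) — low here because a single 20%-depth series is noisy.

## Command line

```bash
pirnakit run --outdir out --seed 1          # simulate → ... → report
pirnakit metrics --outdir out --window 23 29 --region T3
pirnakit map --outdir out --max-mm 3
```

`run` executes all stages, writes TSV/bedGraph/JSON artifacts plus a
`manifest.json` of input checksums, and skips unchanged stages on re-runs.

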