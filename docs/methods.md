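# Methods

## Scope and model

`pirnakit` analyses small-RNA libraries mapped to a *user-supplied* reference
set — transgene constructs, repeat units and category references — rather
than to a full genome assembly. This is deliberate: the questions it answers
(is this region producing piRNAs? from which strand? how fast does
production grow across generations?) are region-local, and desk-scale
references keep every algorithm exhaustively checkable against brute-force
oracles.

The central biological quantity is the normalized density of 23–29-nt reads
per kb of a region, followed over generations after paternal inheritance.
Conversion is modelled as a per-generation Bernoulli event with probability
*c*: a locus that has not yet converted produces no piRNAs, so the expected
population-level density is

    D(g) = D_max · (1 − (1 − c)^g)

and a maternally inherited locus sits at `D_max` throughout. The same *c*
drives the probability that an egg chamber is silenced,
`p_g = 1 − (1 − c)^g`. This geometric approach to a plateau is the minimal
model consistent with all-or-none (ON/OFF) chamber states and saturation
within about four generations at c ≈ 0.45; the data motivating it show the
empirical shape but no functional form, so the form is this package's
choice. `fit_conversion_rate` estimates *c* by least squares on the observed
densities with `D_max` profiled analytically for each candidate *c* (bounded
scalar minimisation on [0, 1]).

## Trimming and mapping

Reads arrive 3′-adapter-ligated (default adapter
`TGGAATTCTCGGGTGCCAAG`). Trimming keeps the prefix before the leftmost exact
adapter occurrence; a partial adapter flush with the read's 3′ end counts if
at least 8 bases match. Inserts outside 18–30 nt are rejected with coded
reasons and tallied, never silently dropped. The 18–30 window is this
package's default pre-filter ahead of the 23–29 (piRNA) and 21-nt (siRNA)
selections; it is exposed in the run configuration. No quality-based
trimming is performed — small-RNA analyses here use only the sequence.

Mapping is ungapped, end-to-end, strand-aware Hamming matching with 0–3
mismatches, reporting **all** placements; correctness is defined by the
naive all-window scan and the implementation (an exact substring fast path
for 0 mm, a vectorised sliding-window comparison otherwise) is tested for
exact hit-set equality against a pure-Python oracle on randomized cases.
Reads containing N are excluded from mapping — mismatch counting with N is
ill-defined — but pass through trimming. Identical read sequences are
collapsed to one species carrying the summed multiplicity. With
`unique_only` (the default for all headline metrics), species with more than
one placement across analysis-role regions are excluded from retained hits
and tallied as multi-mappers; placements on normalization-category regions
do not affect uniqueness, since each analysis maps to specific reference
sequences. Ordering of hits is deterministic (region, start, strand); no
random hit selection anywhere.

## Normalization

Counts are scaled to reads per million of `genome − miscRNA − tRNA`
mapped reads, taking the stated formula literally: a read is assigned to a
category when it maps (0 mm) to any region of that role, categories may
overlap, and the subtraction happens only in the denominator. Two
alternative denominators (miRNA reads; all genome reads) are provided to
verify that within-library ratios — which every mode preserves exactly —
and between-library conclusions are normalization-robust. A non-positive
denominator is an error, not a silent fallback.

## piRNA metrics

- **Coordinates** are 0-based half-open internally; human-readable reports
  are 1-based. A read's 5′ end is `start` (sense) or `end − 1` (antisense).
- **1U bias** is the fraction of windowed reads whose own first base is T in
  DNA space (5′ uridine of the RNA).
- **Ping-pong signature**: `pair_counts[k] = Σ_p s(p) · a(p + k − 1)` over
  5′-end count vectors, i.e. the total weight of opposite-strand read pairs
  whose 5′ ends overlap by k bases; z-scores are computed against the
  k = 1..K background with K = 25 by default and k = 10 **included** in the
  background. Including the signal register shrinks z slightly and is the
  conservative choice; K and the window are configurable. Weighting by
  normalized 5′-count products (rather than distinct read species) matches
  the coverage-based computation and makes the exhaustive pair-enumeration
  oracle exact. If the background standard deviation is zero the signature
  is flagged degenerate instead of emitting z-scores.
- **Strand classes**: the minority-strand fraction thresholds 0.25
  (symmetric dual) and 0.02 (uni-strand) are operational definitions chosen
  here for qualitative labels the literature leaves verbal; they are
  configurable and documented wherever reported.
- **Dinucleotide content** uses overlapping windows; windows containing N
  are skipped with the denominator adjusted.
- **density ~ length + composition** is ordinary least squares with an
  intercept (statsmodels); a rank-deficient design raises an error naming
  the offending predictor. With fewer than 3 rows there is no fit.

## qPCR

RT-qPCR uses standard-curve quantities: technical triplicates are averaged
(meanSq) and expressed relative to the RpL32 reference within the same
biological replicate; group summaries are means of per-sample ratios.
ChIP-qPCR normalizes the pulldown to a diluted input,
`ΔCt = meanCt[ChIP] − (meanCt[Input] − log2(dilution factor))`, with the
dilution factor the reciprocal of the input fraction (5% → 20). Fold
enrichment is implemented as `2^(ΔCt_NS − ΔCt_ChIP)`: this is the only
algebraic reading that yields 1 for no enrichment and > 1 for specific
signal, and it round-trips exactly with the generator (Ct tables constructed
from a known enrichment return it to machine precision at zero noise).
Enrichments are rescaled to the 42AB control region when requested. The
two-group comparison is a Welch (unequal-variance) two-sided t-test —
biological triplicates rarely justify pooled variance; the multi-group
design is one-way ANOVA followed by Tukey HSD. Degenerate all-identical
groups report statistic 0 and p = 1 rather than 0/0.

## Repression assay

Percent OFF egg chambers per subline with Wilson score intervals — chosen
over Wald because 0% and 100% both genuinely occur — and per-generation
unweighted mean ± sample SD across sublines. Stage filtering (stages 8–10
for RFP assays) is the caller's responsibility; counts entering the
summaries are already stage-filtered. With a single subline the SD is
reported as undefined (NaN), not zero.

## Synthetic data

The generator emulates the statistical structure the analyses assume:

- **References**: random sequences at the study-like lengths — an 18-kb
  construct with 0.58/3.5/1.8/0.23-kb sub-domains, a 0.9-kb unique domain, a
  4.1-kb gene, a flanking gene, and a 20-kb genome-role region out of which
  the miscRNA/tRNA/miRNA category regions are carved as substrings so that
  category reads also count as genome-mapping (the structure the
  normalization denominator assumes).
- **piRNA reads**: Poisson counts targeting `D(g)` per region, lengths from
  a unimodal 23–29 distribution peaking at 25–26 nt, strand by the region's
  sense ratio (0.5 for the 18-kb construct, 0.88 for the 0.9-kb domain —
  symmetric vs asymmetric dual-strand), default plateau densities 1000 /
  3000 / 1630 reads/kb for the 18-kb, 0.9-kb and 4.1-kb regions. The 1U
  bias (default 0.75) is realised by *placing* 5′ ends on reference
  positions whose base is T with the configured probability — substituting
  the first base would break 0-mismatch mapping. A configurable fraction of
  antisense reads (default 0.3) is paired to a sense read with 5′ ends
  exactly 10 nt apart in overlap (the ping-pong register); paired reads
  honour the 1U draw through partner choice rather than position bias.
- **siRNAs**: 21-nt reads on both strands at a constant fraction (default
  0.2 of the plateau) in the paternal lineage only, so the 23–29/21-nt ratio
  rises as piRNAs accumulate.
- **Mismatched reads**: a 5% fraction carries 3 random substitutions; these
  fail 0-mm mapping, which is why pipeline densities sit ~5% below the
  generating target — the same relationship real libraries have to their
  0-mm-filtered subset. Tests of estimator calibration therefore use
  configs with this fraction at 0.
- **Backgrounds**: fixed totals (200k genome, 20k miscRNA, 10k tRNA, 40k
  miRNA at full depth) distributed over a smaller number of species carrying
  multiplicities. `scaled(f)` reduces depth for fast runs; normalized
  densities are depth-invariant by construction, only sampling noise grows.
- **qPCR and egg chambers**: plate tables are built by inverting the
  quantification formulas (exact round-trip at zero Ct noise, σ = 0.1
  cycles by default); chamber counts are binomial draws at `p_g`.
- Determinism: every artifact derives its RNG stream from the config seed
  plus a fixed stream label, so identical seeds give identical bytes.

What the generator does **not** emulate: real genome sequence and its
repeat structure, sequencing error beyond the configured substitutions,
ligation biases, phasing-distance structure beyond the 10-nt overlap
register, or length-dependent conversion (available as
`c(L) = clamp(c0 · L0/L)`, off by default). Passing tests therefore show
that the estimators recover the generating parameters under the assumed
structure, not that the structure captures every property of real
libraries.

## Problem sizes and numerical choices

The test suite and the acceptance script run the simulator at reduced depth
(5% for unit tests; single-region configs sized to ~3000–8000 reads for
calibration checks; full default depth for the 4-generation conversion-rate
recovery), sizes at which every check completes quickly while the binomial
error bounds used by the tests remain meaningful. Oracle-equivalence checks
use ≥ 1000 randomized mapping cases and 500-read libraries for exhaustive
pair enumeration. Ties and orderings are everywhere deterministic;
tolerances on statistical checks are pre-registered binomial/normal bounds
(99% CI for 1U, 3σ for strand fraction, ±0.1 for *c*), not post-hoc
margins.

## Known limitations

- Ungapped matching only; indels and quality-aware scoring are out of scope
  (reads are 18–30 nt).
- Mapping cost grows with total reference length; the design target is tens
  of kb, not genome scale.
- The miscRNA umbrella is not sub-annotated (rRNA vs snoRNA), and whether
  miscRNA should exclude reads already counted as miRNA is resolved by
  following the denominator formula literally.
- The ANOVA/Tukey path assumes approximately normal within-group errors, as
  in the assays it mirrors (n = 3 biological replicates).
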