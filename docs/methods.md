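# Methods

This note documents the models, defaults and design choices behind
`plasmacnv`, and what the synthetic-data tests do and do not establish
about real plasma data.

## Admixture model

All stages share one forward model. Plasma cfDNA from a cancer patient
is a two-component mixture with tumor fraction TF ∈ [0, 1]; a region
with tumor total copy number c has expected relative read depth

    R(TF, c) = 1 − TF + TF·c/2,

linear in both TF and c, with R(TF, 2) ≡ 1. Its exact inverse is the
absolute-copy-number transform

    ACN(log2R, TF) = 2·(2^log2R + TF − 1)/TF,

which round-trips every integer copy state (the pair TF = 1, c = 0 is
the one singular point: zero expected coverage has no finite log2).
Negative ACN, which noise can produce at low TF, is clipped to 0 and
flagged rather than raised.

## Genome scaffolding

Coordinates are 0-based half-open internally and BED-style on disk.
The bundled build is an hg19-like table of 24 chromosomes with
approximate centromere positions; arms are the two centromere-split
halves and bins tile each chromosome at 1 Mb (terminal bins may be
short). The short arms of the acrocentric chromosomes (13p, 14p, 15p,
21p, 22p) are flagged and excluded from arm-level analysis. Sex
chromosomes are excluded by default from both the z-score and the
log2-ratio stages (female-only study population; copy-neutral
interpretation of X is ambiguous) — both exclusions are configurable.
Read counting accepts SAM/BAM, keeps primary, non-duplicate alignments
with mapping quality strictly above 15 (default), and assigns each read
to the region containing its leftmost aligned base.

## Synthetic cfDNA generator

The generator emulates the two assay layers the pipeline consumes:

- **Arm stage** (LINE-1-amplicon-like): total depth 100,000 reads,
  baseline arm weights proportional to arm length. True LINE-1 density
  is not modeled; a weights file can override the default. chrY is
  omitted (female donors).
- **sWGS stage**: total depth 6.43 million reads (the study-scale
  default; tests that need many replicates use the same depth since a
  full-genome draw is cheap).

Expected counts are proportional to region length × R(TF, c) × an
optional GC factor, normalized to the configured total. Observed
counts are negative-binomial with size (dispersion) parameter k = 200
(variance m + m²/k, i.e. a ~7% coefficient-of-variation floor at high
depth); k = ∞ gives Poisson, and `noise=False` returns rounded
expectations for noise-free constructions. Draws use inverse-CDF
sampling of per-region uniforms, so same-seed simulations at different
tumor fractions are quantile-coupled (common random numbers) — this is
what lets monotonicity tests compare tf ladders tightly. The optional
GC bias is a quadratic multiplicative factor in GC fraction, unity at
GC 0.45, used to exercise the correction stage.

The default tumor genotype is a breast-cancer-like arm-level profile:
1q gain (3 copies), 8q gain (3), 11q high-level gain (6, a CCND1-like
amplicon), 17q gain (4), and 13q/16q losses (1), plus either an 8p loss
or, in the focal variant, a 16-copy 1 Mb FGFR1 amplicon with neutral
8p. The 11q event is deliberately above the halving image of the
copy-state cap (2 + 2·(6−2) > 8): a genotype whose deviations all halve
onto integer states ≤ 8 is fit equally well at TF/2, so at least one
such event is required for the tumor fraction to be identifiable at
all. Single-event genotypes remain inherently TF/copy-degenerate and
are excluded from accuracy contracts.

Patient cohorts draw TF log-normally (median 4.6%, log-SD 1.0, the
scale reported for metastatic breast cancer), give 20% of patients the
focal amplicon, and link survival to ctDNA burden through an
exponential model: hazard λ = ln2/44 months × exp(0.5·(ln TF − ln
0.046)), with administrative right-censoring at 72 months (the study's
median follow-up). Under these defaults a median split on TF rejects
the log-rank null in ≈ 99% of n = 200 cohorts, and the type-I error at
slope 0 is nominal (0.0525 over 400 seeded replicates).

## Arm-level aneuploidy score

Arm fractions are standardized per arm against the control cohort
(mean and SD with the n−1 denominator), squared and summed into S over
the 39 retained arms. S itself has expectation ≈ 39 for a null sample,
not 0 — so a raw "sum of squared z-scores" is not on the z scale that
the conventional >3 threshold or the reported patient range (≈1 to
≈30) implies. The genome-wide score is therefore standardized a
second time against the leave-one-out control distribution of S: each
control is scored against the reference built from the other n−1
(avoiding self-inclusion bias), and gw_z = (S − mean S_LOO)/SD S_LOO.
This reconstruction reproduces the expected dynamic range (null
samples within ±3 in >95% of seeded replicates) and is isolated behind
`mode="raw"` for pipelines that work on S directly. Samples below
100,000 reads are flagged in QC output, not rejected.

Sensitivity under the default noise floor: an arm-level event shifts
an arm fraction by TF·(c−2)/2 relative, against a ≈7.3% arm CV, so a
3-copy arm gain needs TF ≳ 0.45 for a single-arm z > 3, while a 4-copy
gain crosses it near TF 0.3. The genome-wide score aggregates over
all arms and rises much earlier (clearly separated from null by
TF ≈ 0.1 with the default genotype).

## sWGS log2-ratio profiling

GC correction fits count rate (count per bp, robust to short terminal
bins) against GC with LOWESS (span 0.3) and rescales by median rate /
fitted rate; bins with GC outside [0.30, 0.60] are excluded and
flagged, and GC must be present for ≥ 90% of bins. On bias-free
simulations the correction is a no-op to within 1% median absolute
relative difference; an injected quadratic bias is removed to
|ρ(corrected, GC)| < 0.05.

Log2 ratios divide the sample's per-bin fraction by the control
panel's median fraction. The profile is then re-centered by its
median: library-size normalization scales every fraction by the
genome-mean relative coverage, so an aneuploid sample's copy-neutral
bins would otherwise sit systematically below zero. Re-centering
assumes the majority of the genome is copy-neutral — true for the
intended use but violated by extreme genome-doubled profiles. Panel
size matters: accuracy was validated with a 10-control panel, and
panels of ≤ 5 measurably degrade segment means and downstream
tumor-fraction estimates.

Segmentation is recursive binary splitting on the two-sample t
statistic (split accepted at p < 1e-4 with ≥ 3 bins per side) — a
deliberate simplification of circular binary segmentation that is
deterministic and adequate at 1 Mb resolution. The pipeline pre-splits
each chromosome at its centromere and segments arms independently:
somatic events essentially never cross centromeres, and the pre-split
preserves an undiluted mean for whole-arm events too subtle for the t
test (which matters below TF ≈ 0.1). A noiseless step is found
exactly; a 4-copy interior step at TF 0.2 and default depth is
localized within ±2 bins in ≥ 90% of replicates (a 3-copy step's
localization is noise-limited below that bar — the signal-to-noise at
the breakpoint is ≈ 1.2). Segments are labeled gain/loss/balanced at
±0.1 log2 (configurable).

### Focal amplification calling

The exact criteria used by the original tissue-validated callers are
not restated in the source material; the three-part rule here is a
documented reconstruction, fully configurable:

1. gene-window mean log2 ≥ 0.1 (`min_log2`),
2. gene-window mean ≥ arm median + 0.1 (`min_delta`, arm median
   computed excluding the gene bins),
3. the contiguous run of bins ≥ `min_log2` containing the gene spans
   ≤ 20 Mb (`max_len`) — the focality criterion that rejects arm-level
   gains.

The run-length form of criterion 3 is used instead of the covering
segment's length because a 1 Mb amplicon can never be its own segment
under the ≥ 3-bin splitting rule; the covering segment is still
reported. The 0.1 thresholds are set by the detection regime the
method is known for: a 24-copy amplicon at TF 0.86% produces a
gene-bin log2 of 0.130 and must be callable, while a 7-copy amplicon
at TF 0.35% (log2 0.013) and a 24-copy amplicon at TF 0.35% (log2
0.055) must not be. With per-bin log2 noise ≈ 0.11 at default depth,
calls near the floor are noise-sensitive; the detection-limit tests
therefore run noise-free, characterizing the criteria rather than
per-replicate sensitivity.

## Tumor-fraction estimation

A grid search over TF ∈ {0.0025, 0.005, …, 0.8}: each segment gets the
integer copy state c ∈ {0..8} whose R(TF, c) best matches its mean
depth ratio, and the fit score is

    Σ n_bins·(2^mean_log2 − R(TF, c*))²
      + 0.5 · (bin fraction assigned non-neutral)
      + 0.2 · (bin-weighted mean |c* − 2|).

Ties break toward the smallest TF (the conventional resolution of the
TF/ploidy ambiguity). The non-neutral-fraction penalty discourages
explaining noise with aberrant states at very small TF, where the
copy-state lattice becomes arbitrarily fine; the state-magnitude term
is a parsimony prior that breaks the halving degeneracy (TF/2 with
doubled deviations), without which the smallest-TF tie-break
systematically undercalls by a factor ≈ 2. Segments within ±3 Mb of a
called focal amplification are masked out of the fit so a single high
amplicon cannot drive TF. Profiles with < 5% aberrant genome are
flagged low-confidence — TF is unidentifiable without copy-number
signal, and the all-balanced profile returns the grid minimum by
construction. This estimator is an intentionally simple substitute
for full HMM approaches (no subclonal states, no ploidy search) and
is not expected to reproduce their numeric outputs.

Measured recovery under default noise (10-control panel, default
genotype, 10 seeded replicates per level): median |error| ≤ 0.0125 at
TF ∈ {0.05, 0.1, 0.2, 0.4}; a noise-free TF = 0.20 profile is
recovered exactly (on-grid).

## Tissue classification and cohort statistics

FISH status is two-tier with inclusive thresholds throughout
(ratio ≥ 2.0 or average gene signals ≥ 6.0 → amplified; else
q5 ≥ 0.50 or q15 ≥ 0.10 → low-amplified; else balanced), and the main
criteria take precedence over the additional ones — both choices are
required to reproduce the bundled cohort's printed per-case calls
(17/3 split). The classifier is monotone in every field, and the
centromere count is informational given the ratio. Array status is
gain at copy number ≥ 3 (the smallest printed gain; configurable).
Concordance counts FISH-positive (either tier) against array gain over
the joined cases.

Threshold counts use strict inequality ("greater than 3"), medians are
the standard even-n midpoint, and R² is the squared Pearson
correlation on raw values. Survival wraps lifelines: product-limit
curves with exponential-Greenwood log-log 95% CIs, two-group log-rank
with the asymptotic χ²(1) reference (no permutation option in this
version). The median split sends values equal to the median to the
low group — the bundled plasma cohort has two samples exactly at its
tumor-fraction median, so this choice changes group sizes and is
surfaced in the stratification result.

## What the synthetic tests do and do not show

The generator reproduces admixture dilution, overdispersed counting
noise, GC bias, arm- and focal-level events, and a TF-linked survival
process; passing tests therefore establish the internal consistency of
the pipeline and its behavior under those mechanisms at the study's
depths and cohort sizes (35 arm-stage controls, 10-sample sWGS panel,
6.43 M / 100 k reads). The generator does not model fragment-length
biology, mappability or replication-timing coverage waves, real LINE-1
primer density, sequencing error, or subclonal heterogeneity — so test
results bound what to expect on real data from above, and panel- or
protocol-specific recalibration of thresholds should be expected.

## Problem sizes in the test suite

Simulation-backed tests use the full default read depths and genome
(3,113 bins, 48 arms) with modest replicate counts chosen for a
single-CPU run: 10–25 replicates for recovery and localization checks,
200 null replicates for z-score calibration, and 100–400 cohort
replicates for log-rank power and type-I calibration.
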