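# plasmacnv

Copy-number analysis of plasma cell-free DNA (cfDNA) for liquid-biopsy
studies: genome-wide aneuploidy scoring from chromosome-arm read
counts, shallow whole-genome sequencing (sWGS) log2-ratio profiling
with focal-amplification calling (FGFR1 by default), tumor-fraction
estimation, FISH/array tissue classification and concordance, and
cohort-level survival statistics. A synthetic cfDNA generator with
known ground truth backs the whole pipeline, so every stage is testable
without access to patient sequencing data.

The package is aimed at translational-oncology analysts who want to
screen plasma samples for a target gene amplification (e.g. to select
patients for FGFR-inhibitor trials) and to stratify patients by
circulating tumor DNA (ctDNA) burden.

## The model

Plasma cfDNA is a mixture: a fraction *TF* (the tumor fraction) of
fragments derives from tumor cells, the rest from diploid normal cells.
A genomic region whose tumor total copy number is *c* then has expected
relative read depth

```
R(TF, c) = 1 − TF + TF·c/2
```

so a copy-neutral region has R = 1 and log2 R = 0. Everything in the
package flows from this admixture model:

- **Arm-level aneuploidy score.** Reads are counted per chromosome arm
  (39 autosomal arms; acrocentric short arms omitted), normalized to
  fractions, and standardized against a healthy control cohort
  (default n = 35): `z_a = (f_a − μ_a)/σ_a`. The squared arm z-scores
  are summed into S and standardized a second time against the
  leave-one-out control distribution of S, giving a genome-wide z-score
  on the familiar scale (null ≈ 0, decision threshold 3).
- **sWGS profiling.** 1 Mb bin counts are GC-corrected (LOWESS),
  divided by a healthy control panel's per-bin median, log2-transformed
  and median-re-centered, then segmented by recursive binary
  change-point splitting (per arm). A focal amplification of the
  target gene is called when the gene window's log2 ratio clears an
  absolute floor, exceeds its arm median by a margin, and the amplified
  run of bins is short (focal, not an arm-level gain).
- **Tumor fraction and absolute copy number.** A grid search assigns
  each segment an integer copy state in {0..8} under R(TF, c) and
  returns the TF minimizing a penalized fit score (a deliberately
  simple stand-in for HMM approaches such as ichorCNA). Given a log2
  ratio and a tumor fraction, the absolute copy number is
  `ACN = 2·(2^log2R + TF − 1)/TF`, the exact inverse of the admixture
  model.
- **Tissue truth and cohort statistics.** FISH scoring follows the
  standard two-tier rules (amplified if FGFR1/CEN8 ratio ≥ 2.0 or ≥ 6
  average gene signals per nucleus; low-amplified on the percentage
  criteria), array copy-number status is consumed as printed, and the
  cohort layer provides concordance, threshold counts, medians, Pearson
  R², Kaplan–Meier curves and log-rank tests for median-split survival
  stratification.

A reference cohort from a published 100-patient metastatic breast
cancer study ships as packaged CSVs (FISH scores of the 20
FGFR1-amplified tumors, the 11-case array confirmation subset, and the
20-patient plasma cohort with genome-wide z-scores and tumor
fractions); the cohort statistics reproduce that study's headline
numbers exactly.

## Worked example

Simulate a patient (tumor fraction 12%, 16-copy FGFR1 amplicon on a
typical breast-cancer arm-level background) plus healthy controls, and
run all three plasma stages:

```python
import plasmacnv as pc
from plasmacnv.mfastseq import build_reference, score_sample
from plasmacnv.swgs_cnv import profile_pipeline, call_focal_amplification
from plasmacnv.tumor_fraction import (
    absolute_copy_number, estimate_tumor_fraction, mask_segments)

build = pc.default_build()
arms = pc.make_arms(build)
bins = pc.make_bins(build)                     # 1 Mb bins
gene = pc.load_gene_annotations()["FGFR1"]

genotype = pc.default_tumor_genotype(build, focal_amp=True, focal_copies=16)
patient_arm = pc.simulate_arm_counts(
    genotype, pc.SimulationConfig(tumor_fraction=0.12, total_reads=100_000, seed=7), arms)
patient_bin = pc.simulate_bin_counts(
    genotype, pc.SimulationConfig(tumor_fraction=0.12, seed=7), bins)

controls = pc.simulate_control_cohort(
    35, pc.SimulationConfig(total_reads=100_000, seed=1), arms, kind="arm")
panel = pc.simulate_control_cohort(10, pc.SimulationConfig(seed=2), bins, kind="bin")

score = score_sample(patient_arm, build_reference(controls))
print(f"genome-wide z-score: {score.gw_z:.1f}")

profile, segments = profile_pipeline(patient_bin, panel)
call = call_focal_amplification(profile, gene, segments)
print(f"FGFR1 focal amplification called: {call.called} (gene-bin log2 {call.gene_log2:.3f})")

est = estimate_tumor_fraction(mask_segments(segments, [gene]))
print(f"estimated tumor fraction: {est.itf:.3f}")
print(f"absolute FGFR1 copy number: {absolute_copy_number(call.gene_log2, est.itf).acn:.1f}")
```

Output:

```
genome-wide z-score: 2.9
FGFR1 focal amplification called: True (gene-bin log2 0.862)
estimated tumor fraction: 0.120
absolute FGFR1 copy number: 15.6
```

The arm-level score sits just below the conventional threshold of 3 —
realistic for a ~12% tumor fraction — while sWGS both detects the focal
amplification and recovers the simulated tumor fraction exactly; the
ACN transform returns ≈ 16 copies, the simulated truth (the small
deficit is count-noise attenuation of the gene-bin log2 ratio).

The same stages are available from the shell:

```
plasmacnv fish --classify --out fish.json
plasmacnv cohort --out report.json
plasmacnv count sample.bam --bins --out counts.tsv
plasmacnv cnv counts.tsv --panel controls.tsv --out-prefix cnv
plasmacnv tf cnv_sample.segments.tsv --out tf.json
plasmacnv acn --log2 0.13 --itf 0.0086
```

`plasmacnv cohort` prints, among other fields, the bundled cohort's
FISH split (17 amplified / 3 low-amplified), the 91% tissue
concordance, the plasma threshold counts (8 samples with z > 3, 12 with
tumor fraction > 3%) and the z-vs-tumor-fraction R² of 0.81.

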