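"""Synthetic plasma cfDNA read-count generator with known ground truth.

Plasma of a cancer patient is a mixture: a fraction ``tf`` (the tumor
fraction) of fragments derives from tumor cells carrying copy-number
events, the rest from diploid normal cells.  A region with tumor total
copy number ``c`` therefore has expected relative read depth

    R(tf, c) = 1 - tf + tf * c / 2,

which is 1 for copy-neutral regions and linear in both tf and c.  The
generator turns a tumor genotype (a set of non-overlapping copy-number
events on a diploid background) plus a tumor fraction into per-region
expected read counts, and draws observed counts from a negative-binomial
noise model (gamma-Poisson overdispersion; dispersion parameter ``k``
gives variance ``m + m^2/k``).

Draws are made by inverse-CDF sampling of per-region uniforms, so two
simulations with the same seed but different tumor fractions are
quantile-coupled (common random numbers) — useful for monotonicity
checks.  An optional quadratic GC-bias factor (unity at GC 0.45)
exercises the GC-correction stage.

Defaults mirror the study conditions this package emulates: ~6.43 M
reads per shallow-WGS sample, >=100,000 reads for the arm-level
(LINE-1 amplicon) stage, a 35-sample healthy control cohort, a patient
tumor-fraction distribution with median 4.6%, and a 20% prevalence of
focal FGFR1 amplification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .genome_model import (
    ArmCountProfile,
    BinCountProfile,
    ChromosomeArm,
    GenomeBuild,
    GenomicBin,
    Region,
    default_build,
    load_gene_annotations,
    make_arms,
)

__all__ = [
    "CnaEvent",
    "TumorGenotype",
    "SimulationConfig",
    "expected_relative_coverage",
    "expected_region_rates",
    "simulate_bin_counts",
    "simulate_arm_counts",
    "simulate_control_cohort",
    "simulate_patient_cohort",
    "default_tumor_genotype",
    "assign_gc_fractions",
    "write_profile_sam",
]


@dataclass(frozen=True)
class CnaEvent:
    """One somatic copy-number event on an otherwise diploid genome."""

    chrom: str
    start: int
    end: int
    total_copies: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        if self.total_copies == 2:
            raise ValueError("total_copies == 2 is the implicit background")


@dataclass(frozen=True)
class TumorGenotype:
    """Non-overlapping copy-number events; background ploidy is 2."""

    events: tuple[CnaEvent, ...] = ()
    background_ploidy: int = 2

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[CnaEvent]] = {}
        for e in self.events:
            by_chrom.setdefault(e.chrom, []).append(e)
        for evs in by_chrom.values():
            evs.sort(key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping events: {a} / {b}")

    def copies_in(self, chrom: str, start: int, end: int) -> int:
        """Total copy number of [start, end); error if it straddles an event edge."""
        for e in self.events:
            if e.chrom != chrom:
                continue
            if start >= e.end or end <= e.start:
                continue
            if start >= e.start and end <= e.end:
                return e.total_copies
            raise ValueError(
                f"region {chrom}:{start}-{end} straddles event boundary "
                f"{e.chrom}:{e.start}-{e.end}; pre-split the region"
            )
        return self.background_ploidy

    def mean_copies_in(self, chrom: str, start: int, end: int) -> float:
        """Length-weighted mean copy number over [start, end)."""
        length = end - start
        acc = 0.0
        covered = 0
        for e in self.events:
            if e.chrom != chrom or start >= e.end or end <= e.start:
                continue
            ov = min(end, e.end) - max(start, e.start)
            acc += ov * e.total_copies
            covered += ov
        return (acc + (length - covered) * self.background_ploidy) / length


@dataclass(frozen=True)
class SimulationConfig:
    """Noise and depth settings for one simulated sample.

    dispersion is the negative-binomial size parameter k (variance
    m + m^2/k); ``math.inf`` gives Poisson noise and ``noise=False``
    returns rounded expected counts.  gc_bias_coeffs (a, b) multiply
    expected depth by 1 + a*(gc-0.45) + b*(gc-0.45)^2.
    """

    tumor_fraction: float = 0.0
    total_reads: int = 6_430_000
    dispersion: float = 200.0
    gc_bias_coeffs: tuple[float, float] | None = None
    seed: int = 0
    noise: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor_fraction must be in [0, 1]")
        if self.total_reads <= 0:
            raise ValueError("total_reads must be > 0")
        if not self.dispersion > 0:
            raise ValueError("dispersion must be > 0")


ARM_STAGE_TOTAL_READS = 100_000  # arm-level (LINE-1) stage depth floor
DEFAULT_CONTROL_N = 35


def expected_relative_coverage(
    genotype: TumorGenotype, tf: float, region: Union[Region, tuple[str, int, int]]
) -> float:
    """R(tf, c) = 1 - tf + tf*c/2 for the region's tumor copy number.

    The region must lie fully inside or outside each event; a region
    straddling an event boundary raises (callers pre-split).
    """
    if not 0.0 <= tf <= 1.0:
        raise ValueError("tf must be in [0, 1]")
    chrom, start, end = (
        (region.chrom, region.start, region.end)
        if not isinstance(region, tuple)
        else region
    )
    c = genotype.copies_in(chrom, start, end)
    return 1.0 - tf + tf * c / 2.0


def _gc_factor(gc: np.ndarray, coeffs: tuple[float, float] | None) -> np.ndarray:
    if coeffs is None:
        return np.ones_like(gc, dtype=float)
    a, b = coeffs
    x = np.where(np.isfinite(gc), gc, 0.45) - 0.45
    return np.clip(1.0 + a * x + b * x * x, 0.05, None)


def expected_region_rates(
    genotype: TumorGenotype,
    config: SimulationConfig,
    regions: Sequence[Region],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Expected count per region, normalized to sum to total_reads.

    Baseline weight defaults to region length; regions straddling event
    boundaries get the length-weighted mean copy number.
    """
    tf = config.tumor_fraction
    w = (
        np.asarray([r.length for r in regions], dtype=float)
        if weights is None
        else np.asarray(weights, dtype=float)
    )
    if len(w) != len(regions) or np.any(w < 0):
        raise ValueError("weights must be non-negative, one per region")
    cov = np.array(
        [
            1.0 - tf + tf * genotype.mean_copies_in(r.chrom, r.start, r.end) / 2.0
            for r in regions
        ]
    )
    gc = np.array(
        [getattr(r, "gc_fraction", None) or np.nan for r in regions], dtype=float
    )
    lam = w * cov * _gc_factor(gc, config.gc_bias_coeffs)
    s = lam.sum()
    if s <= 0:
        raise ValueError("all expected rates are zero")
    return lam * (config.total_reads / s)


def _draw_counts(lam: np.ndarray, config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if not config.noise:
        return np.rint(lam).astype(np.int64)
    u = rng.random(len(lam))
    # inverse-CDF draws: quantile-coupled across same-seed simulations
    if math.isinf(config.dispersion):
        return stats.poisson.ppf(u, mu=lam).astype(np.int64)
    k = config.dispersion
    return stats.nbinom.ppf(u, n=k, p=k / (k + lam)).astype(np.int64)


def simulate_bin_counts(
    genotype: TumorGenotype,
    config: SimulationConfig,
    bins: Sequence[GenomicBin],
) -> BinCountProfile:
    """Draw a genome-wide per-bin count profile for one sample."""
    lam = expected_region_rates(genotype, config, bins)
    rng = np.random.default_rng(config.seed)
    counts = _draw_counts(lam, config, rng)
    return BinCountProfile(f"sim_tf{config.tumor_fraction:g}_s{config.seed}", tuple(bins), counts)


def simulate_arm_counts(
    genotype: TumorGenotype,
    config: SimulationConfig,
    arms: Sequence[ChromosomeArm],
    weights: Sequence[float] | None = None,
) -> ArmCountProfile:
    """Draw an arm-level count profile (LINE-1 amplicon stage emulation).

    Acrocentric short arms and chrY are dropped (no usable signal / female
    cohort); baseline weights default to arm length.
    """
    kept = [
        (i, a)
        for i, a in enumerate(arms)
        if not a.acrocentric_short and a.chrom != "chrY"
    ]
    idx = [i for i, _ in kept]
    regions = [a for _, a in kept]
    w = None if weights is None else [weights[i] for i in idx]
    lam = expected_region_rates(genotype, config, regions, weights=w)
    rng = np.random.default_rng(config.seed)
    counts = _draw_counts(lam, config, rng)
    return ArmCountProfile(
        f"sim_tf{config.tumor_fraction:g}_s{config.seed}",
        {a.name: int(c) for a, c in zip(regions, counts)},
        total_reads=int(counts.sum()),
    )


def simulate_control_cohort(
    n: int,
    config: SimulationConfig,
    regions: Sequence[Region],
    kind: Literal["arm", "bin"] = "arm",
    weights: Sequence[float] | None = None,
) -> list[Union[ArmCountProfile, BinCountProfile]]:
    """n independent tumor-free profiles with distinct derived seeds."""
    if n < 2:
        raise ValueError("need n >= 2 controls (SD undefined otherwise)")
    none = TumorGenotype()
    out = []
    seeds = np.random.SeedSequence(config.seed).generate_state(n) % (2**31)
    for i, s in enumerate(seeds):
        cfg = replace(config, tumor_fraction=0.0, seed=int(s))
        if kind == "arm":
            p = simulate_arm_counts(none, cfg, regions, weights=weights)
        else:
            p = simulate_bin_counts(none, cfg, regions)
        p.sample_id = f"control_{i:03d}"
        out.append(p)
    return out


# ---------------------------------------------------------------------------
# Default tumor genotype and patient cohorts


def default_tumor_genotype(
    build: GenomeBuild | None = None,
    focal_amp: bool = False,
    focal_copies: int = 16,
    gene: str = "FGFR1",
) -> TumorGenotype:
    """A breast-cancer-like arm-level genotype, optionally with a focal amp.

    Arm events: 1q gain (3), 8q gain (3), 11q high-level gain (6, the
    CCND1-like amplicon), 17q gain (4), 8p/13q/16q losses (1).  The 11q
    event is deliberately above the halving image of the copy-state cap
    so the genome-wide tumor-fraction fit is identifiable (a genotype
    whose deviations all halve onto integer states <= 8 fits equally well
    at tf/2).  With ``focal_amp`` the 1 Mb window harboring the target
    gene gets ``focal_copies`` and the surrounding 8p stays neutral.
    """
    build = build or default_build()
    arms = {a.name: a for a in make_arms(build)}
    events = [
        CnaEvent("chr1", arms["1q"].start, arms["1q"].end, 3),
        CnaEvent("chr8", arms["8q"].start, arms["8q"].end, 3),
        CnaEvent("chr11", arms["11q"].start, arms["11q"].end, 6),
        CnaEvent("chr17", arms["17q"].start, arms["17q"].end, 4),
        CnaEvent("chr13", arms["13q"].start, arms["13q"].end, 1),
        CnaEvent("chr16", arms["16q"].start, arms["16q"].end, 1),
    ]
    if focal_amp:
        chrom, gstart, _ = load_gene_annotations()[gene]
        wstart = (gstart // 1_000_000) * 1_000_000
        events.append(CnaEvent(chrom, wstart, wstart + 1_000_000, focal_copies))
    else:
        events.append(CnaEvent("chr8", arms["8p"].start, arms["8p"].end, 1))
    return TumorGenotype(tuple(events))


def simulate_patient_cohort(
    n: int,
    seed: int,
    tf_median: float = 0.046,
    tf_sigma: float = 1.0,
    focal_prevalence: float = 0.2,
    hazard_slope: float = 0.5,
    baseline_median_os: float = 44.0,
    censor_horizon: float = 72.0,
    build: GenomeBuild | None = None,
    config: SimulationConfig | None = None,
    profiles: Literal["none", "arm", "bin"] = "none",
) -> tuple[pd.DataFrame, dict[str, Union[ArmCountProfile, BinCountProfile]]]:
    """Simulate a patient cohort with tumor-fraction-linked survival.

    Tumor fractions are log-normal (median ``tf_median``, log-SD
    ``tf_sigma``, clipped to [0, 0.95]); a fraction ``focal_prevalence``
    of patients carries the focal amplification.  Survival is exponential
    with log-hazard linear in log tumor fraction (slope ``hazard_slope``,
    baseline median ``baseline_median_os`` months at the median tf) and
    administrative right-censoring at ``censor_horizon`` months.

    Returns the sample sheet (case_id, true_tf, focal_amp, os_months,
    event) and, if requested, per-patient count profiles.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < tf_median < 1 or tf_sigma <= 0:
        raise ValueError("invalid tumor-fraction distribution parameters")
    if not 0 <= focal_prevalence <= 1:
        raise ValueError("focal_prevalence must be in [0, 1]")
    rng = np.random.default_rng(seed)
    build = build or default_build()
    tf = np.clip(np.exp(np.log(tf_median) + tf_sigma * rng.standard_normal(n)), 0.0, 0.95)
    focal = rng.random(n) < focal_prevalence
    lam0 = math.log(2.0) / baseline_median_os
    hazard = lam0 * np.exp(hazard_slope * (np.log(tf) - math.log(tf_median)))
    t_event = rng.exponential(1.0 / hazard)
    os_months = np.minimum(t_event, censor_horizon)
    event = t_event <= censor_horizon

    sheet = pd.DataFrame(
        {
            "case_id": [f"P{i:04d}" for i in range(n)],
            "true_tf": tf,
            "focal_amp": focal,
            "os_months": os_months,
            "event": event,
        }
    )

    out_profiles: dict[str, Union[ArmCountProfile, BinCountProfile]] = {}
    if profiles != "none":
        base = config or SimulationConfig()
        if profiles == "arm":
            regions: Sequence[Region] = make_arms(build)
        else:
            from .genome_model import make_bins

            regions = make_bins(build)
        seeds = np.random.SeedSequence(seed + 1).generate_state(n) % (2**31)
        for i in range(n):
            geno = default_tumor_genotype(build, focal_amp=bool(focal[i]))
            cfg = replace(base, tumor_fraction=float(tf[i]), seed=int(seeds[i]))
            if profiles == "arm":
                p = simulate_arm_counts(geno, cfg, regions)
            else:
                p = simulate_bin_counts(geno, cfg, regions)
            p.sample_id = sheet.case_id[i]
            out_profiles[sheet.case_id[i]] = p
    return sheet, out_profiles


# ---------------------------------------------------------------------------
# Utilities


def assign_gc_fractions(
    bins: Sequence[GenomicBin], seed: int = 0, spread: float = 0.06
) -> list[GenomicBin]:
    """Attach plausible GC fractions (mean 0.41, clipped to [0.25, 0.65]).

    Real builds would take these from the reference sequence; the
    synthetic values just give the GC-correction stage something to fit.
    """
    rng = np.random.default_rng(seed)
    gc = np.clip(0.41 + spread * rng.standard_normal(len(bins)), 0.25, 0.65)
    return [
        GenomicBin(b.chrom, b.start, b.end, float(g)) for b, g in zip(bins, gc)
    ]


def write_profile_sam(
    profile: Union[ArmCountProfile, BinCountProfile],
    regions: Sequence[Region],
    build: GenomeBuild,
    path: Union[str, Path],
    mapq: int = 60,
    read_length: int = 50,
) -> None:
    """Write one synthetic read per counted fragment to a SAM file.

    Reads are placed at the start of their region, so re-counting the SAM
    reproduces the profile exactly.  Intended for small fixtures.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c.name, "LN": c.length} for c in build.chromosomes],
    }
    if isinstance(profile, ArmCountProfile):
        counts = [profile.counts.get(r.name, 0) for r in regions]  # type: ignore[union-attr]
    else:
        counts = [int(c) for c in profile.counts]
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {c.name: i for i, c in enumerate(build.chromosomes)}
        serial = 0
        for region, c in zip(regions, counts):
            for _ in range(int(c)):
                a = pysam.AlignedSegment()
                a.query_name = f"read{serial}"
                serial += 1
                a.reference_id = tid[region.chrom]
                a.reference_start = region.start
                a.mapping_quality = mapq
                a.query_sequence = "A" * read_length
                a.cigarstring = f"{read_length}M"
                a.flag = 0
                out.write(a)
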