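"""Shallow-WGS copy-number profiling: GC correction, log2 ratios,
segmentation, and focal-amplification calling.

Per-bin read counts from a low-coverage plasma library are corrected
for GC bias (local weighted regression of count rate on GC), normalized
against a panel of healthy-control samples to per-bin log2 ratios,
segmented by recursive binary change-point splitting, and finally
screened for focal amplification of a target gene window.

Under the admixture model R(tf, c) = 1 - tf + tf*c/2, a copy-neutral
bin has log2 ratio 0 and a focally amplified bin stands out both in
absolute level and against its own arm's background; the caller
requires (i) gene-window log2 ratio above an absolute floor, (ii) the
gene window above the arm median by a margin, and (iii) the amplified
run of bins around the gene to be short (focal, not an arm-level gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genome_model import (
    BinCountProfile,
    GenomicBin,
    bins_overlapping,
    default_build,
)

__all__ = [
    "Log2RatioProfile",
    "Segment",
    "FocalAmpCall",
    "gc_correct",
    "log2_ratio",
    "segment",
    "call_focal_amplification",
    "profile_pipeline",
]

GAIN_THRESHOLD = 0.1
LOSS_THRESHOLD = -0.1


@dataclass
class Log2RatioProfile:
    """Per-bin log2 ratios; NaN marks excluded bins (reason recorded)."""

    sample_id: str
    bins: tuple[GenomicBin, ...]
    log2: np.ndarray = field(repr=False)
    exclusion_reasons: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.log2 = np.asarray(self.log2, dtype=float)
        if len(self.log2) != len(self.bins):
            raise ValueError("log2 and bins length mismatch")


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int
    end: int
    mean_log2: float
    n_bins: int
    state_label: str  # gain | loss | balanced


@dataclass(frozen=True)
class FocalAmpCall:
    gene: str
    gene_log2: float
    arm_median_log2: float
    called: bool
    criteria: dict


# ---------------------------------------------------------------------------
# GC correction


def gc_correct(
    profile: BinCountProfile,
    bins: Sequence[GenomicBin] | None = None,
    span: float = 0.3,
    gc_range: tuple[float, float] = (0.3, 0.6),
) -> tuple[np.ndarray, dict[int, str]]:
    """LOWESS-correct per-bin counts for GC bias.

    Fits count rate (count per bp, robust to short terminal bins) against
    GC with a local weighted regression of span ``span``, then rescales
    each count by median rate / fitted rate.  Bins with GC outside
    ``gc_range`` are excluded (NaN) and flagged.  Requires GC for >= 90%
    of bins.
    """
    bins = tuple(bins) if bins is not None else profile.bins
    gc = np.array(
        [b.gc_fraction if b.gc_fraction is not None else np.nan for b in bins]
    )
    have = np.isfinite(gc)
    if have.mean() < 0.9:
        raise ValueError(
            f"GC fraction present for only {have.mean():.0%} of bins (< 90%)"
        )
    lengths = np.array([b.length for b in bins], dtype=float)
    rate = profile.counts / lengths

    reasons: dict[int, str] = {}
    usable = have & (gc >= gc_range[0]) & (gc <= gc_range[1])
    for i in np.flatnonzero(~usable):
        reasons[i] = "gc-outlier" if have[i] else "no-gc"

    fitted = lowess(
        rate[usable], gc[usable], frac=span, return_sorted=False, xvals=gc[usable]
    )
    corrected = np.full(len(bins), np.nan)
    med = np.median(rate[usable])
    ok = fitted > 0
    idx = np.flatnonzero(usable)
    corrected[idx[ok]] = profile.counts[idx[ok]] * med / fitted[ok]
    for i in idx[~ok]:
        reasons[i] = "gc-fit-nonpositive"
    return corrected, reasons


# ---------------------------------------------------------------------------
# Log2 ratios against a control panel


def log2_ratio(
    sample_counts: np.ndarray,
    panel_counts: Sequence[np.ndarray],
    bins: Sequence[GenomicBin],
    sample_id: str = "sample",
    exclusion_reasons: dict[int, str] | None = None,
    recenter: bool = True,
) -> Log2RatioProfile:
    """Per-bin log2 of sample fraction over the panel median fraction.

    ``sample_counts`` and each panel array may contain NaN for excluded
    bins (e.g. from GC correction); bins whose panel median is zero or
    not finite are excluded and flagged "zero-control".

    With ``recenter`` (default) the genome-wide median log2 is subtracted:
    library-size normalization scales fractions by the genome-mean
    relative coverage, so an aneuploid sample's copy-neutral bins would
    otherwise sit off zero.  Re-centering assumes the majority of the
    genome is copy-neutral.
    """
    if len(panel_counts) == 0:
        raise ValueError("control panel is empty")
    bins = tuple(bins)
    s = np.asarray(sample_counts, dtype=float)
    panel = np.vstack([np.asarray(c, dtype=float) for c in panel_counts])
    if s.shape[0] != len(bins) or panel.shape[1] != len(bins):
        raise ValueError("bin count mismatch between sample, panel and bins")

    reasons = dict(exclusion_reasons or {})
    s_frac = s / np.nansum(s)
    p_frac = panel / np.nansum(panel, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        ref = np.nanmedian(p_frac, axis=0)
    r = np.full(len(bins), np.nan)
    valid = np.isfinite(s_frac) & np.isfinite(ref) & (ref > 0) & (s_frac > 0)
    r[valid] = np.log2(s_frac[valid] / ref[valid])
    if recenter and valid.any():
        r[valid] -= np.median(r[valid])
    for i in np.flatnonzero(np.isfinite(s_frac) & ~(np.isfinite(ref) & (ref > 0))):
        reasons.setdefault(int(i), "zero-control")
    return Log2RatioProfile(sample_id, bins, r, reasons)


# ---------------------------------------------------------------------------
# Segmentation


def _label(mean: float, gain: float = GAIN_THRESHOLD, loss: float = LOSS_THRESHOLD) -> str:
    if mean >= gain:
        return "gain"
    if mean <= loss:
        return "loss"
    return "balanced"


def _best_split(x: np.ndarray, min_bins: int) -> tuple[int, float]:
    """Best breakpoint position and its p-value for one segment.

    Scans every split leaving >= min_bins on each side and returns the
    one maximizing the pooled two-sample t statistic (computed from
    cumulative sums).  A noiseless step (zero within-group variance,
    different means) gets p = 0.
    """
    n = len(x)
    if n < 2 * min_bins:
        return -1, 1.0
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    k = np.arange(min_bins, n - min_bins + 1)  # left side sizes
    lsum = csum[k - 1]
    rsum = csum[-1] - lsum
    lmean = lsum / k
    rmean = rsum / (n - k)
    lss = csq[k - 1] - lsum**2 / k
    rss = (csq[-1] - csq[k - 1]) - rsum**2 / (n - k)
    df = n - 2
    pooled = (lss + rss) / df
    se2 = pooled * (1.0 / k + 1.0 / (n - k))
    diff = lmean - rmean
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = diff**2 / se2
    t2 = np.where(se2 > 0, t2, np.where(np.abs(diff) > 1e-12, np.inf, 0.0))
    j = int(np.argmax(t2))
    if not np.isfinite(t2[j]):
        return int(k[j]), 0.0
    p = 2.0 * stats.t.sf(np.sqrt(t2[j]), df)
    return int(k[j]), float(p)


def _split_recursive(
    x: np.ndarray, lo: int, alpha: float, min_bins: int, out: list[tuple[int, int]]
) -> None:
    cut, p = _best_split(x, min_bins)
    if cut > 0 and p < alpha:
        _split_recursive(x[:cut], lo, alpha, min_bins, out)
        _split_recursive(x[cut:], lo + cut, alpha, min_bins, out)
    else:
        out.append((lo, lo + len(x)))


def segment(
    profile: Log2RatioProfile,
    alpha: float = 1e-4,
    min_bins: int = 3,
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
    build=None,
) -> list[Segment]:
    """Recursive binary change-point segmentation, per chromosome.

    At each step the breakpoint maximizing the two-sample t statistic is
    accepted if its p-value is below ``alpha`` and both sides retain at
    least ``min_bins`` non-excluded bins.  Segments are labeled gain /
    loss / balanced by their mean log2 ratio.  Chromosomes (or arms)
    with fewer than ``min_bins`` usable bins are skipped.

    With ``build`` given, each chromosome is pre-split at its centromere
    and the arms are segmented independently: somatic copy-number events
    essentially never cross centromeres, and the pre-split lets weak
    whole-arm events keep an undiluted segment mean even when they are
    too subtle for the t test on their own.
    """
    segments: list[Segment] = []
    chroms = []
    for b in profile.bins:
        if b.chrom not in chroms:
            chroms.append(b.chrom)
    for chrom in chroms:
        idx_all = np.array(
            [
                i
                for i, b in enumerate(profile.bins)
                if b.chrom == chrom and np.isfinite(profile.log2[i])
            ]
        )
        pieces_of_chrom: list[np.ndarray] = [idx_all]
        if build is not None:
            try:
                cen = build.chromosome(chrom).centromere
            except KeyError:
                cen = None
            if cen is not None:
                p = idx_all[[profile.bins[i].start < cen for i in idx_all]]
                q = idx_all[[profile.bins[i].start >= cen for i in idx_all]]
                pieces_of_chrom = [p, q]
        for idx in pieces_of_chrom:
            if len(idx) < min_bins:
                continue
            x = profile.log2[idx]
            pieces: list[tuple[int, int]] = []
            _split_recursive(x, 0, alpha, min_bins, pieces)
            for lo, hi in sorted(pieces):
                sub = idx[lo:hi]
                mean = float(x[lo:hi].mean())
                segments.append(
                    Segment(
                        chrom,
                        profile.bins[sub[0]].start,
                        profile.bins[sub[-1]].end,
                        mean,
                        hi - lo,
                        _label(mean, gain_threshold, loss_threshold),
                    )
                )
    return segments


# ---------------------------------------------------------------------------
# Focal amplification calling


def call_focal_amplification(
    profile: Log2RatioProfile,
    gene_region: tuple[str, int, int],
    segments: Sequence[Segment] | None = None,
    gene: str = "FGFR1",
    min_log2: float = 0.1,
    min_delta: float = 0.1,
    max_len: float = 20e6,
    build=None,
) -> FocalAmpCall:
    """Three-part focal amplification call for a target gene window.

    called = gene-window mean log2 >= min_log2
         AND gene-window mean >= arm median + min_delta
         AND the contiguous run of bins >= min_log2 containing the gene
             spans <= max_len  (focality: an arm-level gain fails here).

    The arm median is taken over the gene's chromosome arm excluding the
    gene bins.  If ``segments`` is provided, the segment covering the
    gene is reported in the criteria record (informational).
    """
    chrom, gstart, gend = gene_region
    build = build or default_build()
    try:
        chromosome = build.chromosome(chrom)
    except KeyError:
        raise ValueError(f"gene chromosome {chrom} not in build {build.name}")
    gene_idx = bins_overlapping(profile.bins, chrom, gstart, gend)
    if not gene_idx:
        raise ValueError(f"gene region {gene_region} maps to no bin")

    vals = profile.log2[gene_idx]
    gene_log2 = float(np.nanmean(vals)) if np.isfinite(vals).any() else float("nan")

    cen = chromosome.centromere
    arm_lo, arm_hi = (0, cen) if gstart < cen else (cen, chromosome.length)
    arm_idx = [
        i
        for i in bins_overlapping(profile.bins, chrom, arm_lo, arm_hi)
        if i not in set(gene_idx) and np.isfinite(profile.log2[i])
    ]
    arm_median = float(np.median(profile.log2[arm_idx])) if arm_idx else float("nan")

    # amplified run: contiguous bins on the chromosome at/above min_log2
    chrom_idx = [i for i, b in enumerate(profile.bins) if b.chrom == chrom]
    pos = {i: j for j, i in enumerate(chrom_idx)}
    above = [np.isfinite(profile.log2[i]) and profile.log2[i] >= min_log2 for i in chrom_idx]
    run_len = 0.0
    g0 = pos[gene_idx[0]]
    if np.isfinite(gene_log2) and gene_log2 >= min_log2:
        lo = g0
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = pos[gene_idx[-1]]
        while hi + 1 < len(chrom_idx) and above[hi + 1]:
            hi += 1
        run_len = float(
            profile.bins[chrom_idx[hi]].end - profile.bins[chrom_idx[lo]].start
        )

    covering = None
    if segments:
        mid = (gstart + gend) // 2
        for s in segments:
            if s.chrom == chrom and s.start <= mid < s.end:
                covering = s
                break

    meets_level = bool(np.isfinite(gene_log2) and gene_log2 >= min_log2)
    meets_delta = bool(
        np.isfinite(gene_log2)
        and np.isfinite(arm_median)
        and gene_log2 >= arm_median + min_delta
    )
    meets_focal = bool(meets_level and 0 < run_len <= max_len)
    called = meets_level and meets_delta and meets_focal
    return FocalAmpCall(
        gene,
        gene_log2,
        arm_median,
        called,
        {
            "min_log2": min_log2,
            "min_delta": min_delta,
            "max_len": max_len,
            "meets_level": meets_level,
            "meets_delta": meets_delta,
            "meets_focality": meets_focal,
            "amplified_run_bp": run_len,
            "n_gene_bins": len(gene_idx),
            "covering_segment": (
                None
                if covering is None
                else {
                    "start": covering.start,
                    "end": covering.end,
                    "mean_log2": covering.mean_log2,
                    "label": covering.state_label,
                }
            ),
        },
    )


def profile_pipeline(
    sample: BinCountProfile,
    panel: Sequence[BinCountProfile],
    bins: Sequence[GenomicBin] | None = None,
    gc_correction: bool | None = None,
    alpha: float = 1e-4,
    min_bins: int = 3,
    exclude_chroms: Sequence[str] = ("chrX", "chrY"),
    build=None,
) -> tuple[Log2RatioProfile, list[Segment]]:
    """Convenience: (GC-correct ->) log2-ratio -> segment (per arm).

    GC correction is applied when GC fractions are available for >= 90%
    of bins (or forced on/off with ``gc_correction``).  Sex chromosomes
    are excluded by default (copy-neutral interpretation ambiguous) and
    segmentation is pre-split at centromeres of ``build`` (defaults to
    the bundled build).
    """
    build = build or default_build()
    bins = tuple(bins) if bins is not None else sample.bins
    have_gc = np.mean([b.gc_fraction is not None for b in bins]) >= 0.9
    use_gc = have_gc if gc_correction is None else gc_correction
    if use_gc:
        s_counts, reasons = gc_correct(sample, bins)
        p_counts = [gc_correct(p, bins)[0] for p in panel]
    else:
        s_counts = sample.counts.astype(float)
        p_counts = [p.counts.astype(float) for p in panel]
        reasons = {}
    excl = set(exclude_chroms)
    if excl:
        s_counts = s_counts.copy()
        for i, b in enumerate(bins):
            if b.chrom in excl:
                s_counts[i] = np.nan
                reasons[i] = "sex-chrom"
    prof = log2_ratio(s_counts, p_counts, bins, sample.sample_id, reasons)
    return prof, segment(prof, alpha=alpha, min_bins=min_bins, build=build)
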