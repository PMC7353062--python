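"""Tumor-fraction estimation from segmented log2 ratios and the
absolute-copy-number transform.

Under the admixture model a segment with tumor total copy number c at
tumor fraction tf has relative depth R(tf, c) = 1 - tf + tf*c/2.
Inverting at an observed log2 ratio gives the absolute copy number

    ACN = 2 * (2^log2Ratio + tf - 1) / tf,

exact for noise-free input (round-trips every integer c).

The genome-wide tumor fraction is estimated by a deliberately simple
grid search (a stand-in for full HMM approaches): for each candidate tf
on a fine grid, every segment is assigned the integer copy state in
{0..8} whose R(tf, c) best matches its mean depth ratio; the fit score
is the bin-weighted squared residual plus a small penalty on the
fraction of the genome called non-neutral (discouraging degenerate
low-tf solutions that explain noise with extreme states).  Ties break
toward the smallest tf, mirroring the usual tumor-fraction/ploidy
ambiguity convention.  Profiles with almost no aberrant genome are
flagged low-confidence: tf is unidentifiable without SCNAs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .swgs_cnv import Segment

__all__ = [
    "AcnResult",
    "TumorFractionEstimate",
    "absolute_copy_number",
    "estimate_tumor_fraction",
    "mask_segments",
]

TF_GRID = np.round(np.arange(0.0025, 0.8 + 1e-9, 0.0025), 6)
MAX_COPIES = 8


@dataclass(frozen=True)
class AcnResult:
    log2_ratio: float
    itf: float
    acn: float
    clipped: bool = False


@dataclass(frozen=True)
class TumorFractionEstimate:
    itf: float
    fit_score: float
    segment_states: tuple[int, ...]
    low_confidence: bool


def absolute_copy_number(log2_ratio: float, itf: float) -> AcnResult:
    """ACN = 2*(2^log2Ratio + itf - 1)/itf; negatives clip to 0 with a flag."""
    if not 0.0 < itf <= 1.0:
        raise ValueError(f"itf must be in (0, 1], got {itf}")
    acn = 2.0 * (2.0**log2_ratio + itf - 1.0) / itf
    if acn < 0:
        return AcnResult(log2_ratio, itf, 0.0, clipped=True)
    return AcnResult(log2_ratio, itf, acn)


def mask_segments(
    segments: Sequence[Segment],
    exclude_regions: Sequence[tuple[str, int, int]],
    pad: int = 3_000_000,
) -> list[Segment]:
    """Drop segments overlapping any excluded region (padded ±pad bp).

    Used to keep called focal amplifications out of the genome-wide
    tumor-fraction fit, so a single high amplicon cannot drive tf.
    """
    out = []
    for s in segments:
        hit = any(
            s.chrom == chrom and s.start < end + pad and s.end > start - pad
            for chrom, start, end in exclude_regions
        )
        if not hit:
            out.append(s)
    return out


def estimate_tumor_fraction(
    segments: Sequence[Segment],
    grid: np.ndarray = TF_GRID,
    max_copies: int = MAX_COPIES,
    penalty: float = 0.5,
    state_penalty: float = 0.2,
    min_aberrant_fraction: float = 0.05,
) -> TumorFractionEstimate:
    """Grid-search tumor fraction over integer copy-state assignments.

    For each tf on the grid each segment gets the integer c in
    {0..max_copies} minimizing |2^mean_log2 - R(tf, c)|;
    fit_score(tf) = sum n_bins * residual^2
                    + penalty * (bin fraction assigned non-neutral)
                    + state_penalty * (bin-weighted mean |c - 2|).
    The state-magnitude term is a parsimony prior: without it, halving
    tf and doubling every copy deviation fits arm-level genotypes almost
    equally well (the classic tf/ploidy degeneracy), and the smallest-tf
    tie-break would systematically undercall.  The smallest tf within
    numerical tolerance of the best score wins.
    """
    if not segments:
        raise ValueError("no segments to fit")
    ratios = np.array([2.0 ** s.mean_log2 for s in segments])
    weights = np.array([s.n_bins for s in segments], dtype=float)
    wtot = weights.sum()
    states = np.arange(0, max_copies + 1)

    scores = np.empty(len(grid))
    assignments = np.empty((len(grid), len(segments)), dtype=int)
    for gi, tf in enumerate(grid):
        r = 1.0 - tf + tf * states / 2.0  # R for each copy state
        resid = ratios[:, None] - r[None, :]
        best = np.argmin(np.abs(resid), axis=1)
        assignments[gi] = states[best]
        sse = float(np.sum(weights * resid[np.arange(len(segments)), best] ** 2))
        frac_aberrant = float(weights[states[best] != 2].sum() / wtot)
        mean_dev = float(np.sum(weights * np.abs(states[best] - 2)) / wtot)
        scores[gi] = sse + penalty * frac_aberrant + state_penalty * mean_dev

    best_score = scores.min()
    tol = 1e-9 * max(1.0, best_score)
    gi = int(np.flatnonzero(scores <= best_score + tol)[0])  # smallest tf wins ties
    chosen = assignments[gi]
    frac_aberrant = float(weights[chosen != 2].sum() / wtot)
    return TumorFractionEstimate(
        float(grid[gi]),
        float(scores[gi]),
        tuple(int(c) for c in chosen),
        frac_aberrant < min_aberrant_fraction,
    )
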