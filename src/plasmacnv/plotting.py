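"""Minimal plots: tricolor log2-ratio profiles and Kaplan-Meier curves."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .cohort_stats import KMCurve
from .swgs_cnv import Log2RatioProfile, Segment

STATE_COLORS = {"gain": "#c0392b", "loss": "#27ae60", "balanced": "#2980b9"}


def plot_log2(
    profile: Log2RatioProfile,
    segments: Sequence[Segment],
    path: Union[str, Path],
    chrom: str | None = None,
) -> None:
    """Scatter of per-bin log2 ratios colored by covering-segment state."""
    fig, ax = plt.subplots(figsize=(12, 3))
    seg_by_chrom: dict[str, list[Segment]] = {}
    for s in segments:
        seg_by_chrom.setdefault(s.chrom, []).append(s)
    offset = 0
    ticks, labels = [], []
    chroms = [chrom] if chrom else list(dict.fromkeys(b.chrom for b in profile.bins))
    for c in chroms:
        idx = [i for i, b in enumerate(profile.bins) if b.chrom == c]
        if not idx:
            continue
        for i in idx:
            b, y = profile.bins[i], profile.log2[i]
            if not np.isfinite(y):
                continue
            color = STATE_COLORS["balanced"]
            for s in seg_by_chrom.get(c, []):
                if s.start <= b.start < s.end:
                    color = STATE_COLORS[s.state_label]
                    break
            ax.plot(offset + b.start / 1e6, y, ".", ms=2, color=color)
        span = profile.bins[idx[-1]].end / 1e6
        ticks.append(offset + span / 2)
        labels.append(c.removeprefix("chr"))
        offset += span
        ax.axvline(offset, color="0.85", lw=0.5)
    ax.axhline(0, color="0.4", lw=0.5)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_ylabel("log2 ratio")
    ax.set_title(profile.sample_id)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_km(
    curves: dict[str, KMCurve], path: Union[str, Path], title: str = ""
) -> None:
    """Step plot of one or more KM curves with their confidence bands."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for label, km in curves.items():
        ax.step(km.times, km.survival, where="post", label=f"{label} (n={km.n})")
        ax.fill_between(
            km.times, km.ci_lower, km.ci_upper, step="post", alpha=0.15
        )
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
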