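"""Genome-wide aneuploidy z-scores from chromosome-arm read counts.

The arm-level (LINE-1 amplicon) stage quantifies aneuploidy without
genome-wide sequencing: arm read counts are normalized to fractions,
each arm is standardized against a healthy control cohort
(z_a = (f_a - mu_a) / sigma_a), and the squared arm z-scores are summed
into a single statistic S.

S itself has expectation ~ number of retained arms for a copy-neutral
sample, so its raw value is not on the familiar z scale.  The
genome-wide score reported here is therefore standardized a second
time against the leave-one-out distribution of S over the controls:
gw_z = (S - mean(S_controls)) / sd(S_controls).  This reproduces the
usual dynamic range (null samples near 0, the conventional >3 decision
threshold) while the raw S is also kept; ``mode="raw"`` disables the
second stage for compatibility with pipelines that work on S directly.

Retained arms default to the 39 autosomal arms minus the acrocentric
short arms; sex chromosomes are excluded by default (configurable).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence, Union

import numpy as np

from .genome_model import (
    ACROCENTRIC_SHORT_ARMS,
    ArmCountProfile,
    GenomeBuild,
    default_build,
    make_arms,
)

__all__ = [
    "ControlReference",
    "ArmZScores",
    "GenomeWideZScore",
    "retained_arm_names",
    "normalize_arm_counts",
    "build_reference",
    "arm_zscores",
    "genome_wide_zscore",
    "score_sample",
]

MIN_RECOMMENDED_READS = 100_000


def retained_arm_names(
    build: GenomeBuild | None = None, include_sex: bool = False
) -> list[str]:
    """Arm names entering the z-score: non-acrocentric-short, autosomal by default."""
    build = build or default_build()
    names = []
    for a in make_arms(build):
        if a.acrocentric_short:
            continue
        if not include_sex and a.chrom in ("chrX", "chrY"):
            continue
        names.append(a.name)
    return names


def normalize_arm_counts(
    profile: ArmCountProfile, arms: Sequence[str] | None = None
) -> dict[str, float]:
    """Arm count fractions over the retained arm set (sums to 1)."""
    arms = list(arms) if arms is not None else retained_arm_names()
    missing = [a for a in arms if a not in profile.counts]
    if missing:
        raise ValueError(f"profile {profile.sample_id} lacks arms: {missing}")
    counts = np.array([profile.counts[a] for a in arms], dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"profile {profile.sample_id}: zero total retained-arm count")
    if profile.total_reads < MIN_RECOMMENDED_READS:
        warnings.warn(
            f"{profile.sample_id}: {profile.total_reads} reads "
            f"(< {MIN_RECOMMENDED_READS} recommended)",
            stacklevel=2,
        )
    return {a: c / total for a, c in zip(arms, counts)}


@dataclass(frozen=True)
class ControlReference:
    """Per-arm mean/SD of control fractions plus the control S distribution."""

    arms: tuple[str, ...]
    mean: np.ndarray
    sd: np.ndarray
    n_controls: int
    control_s_mean: float
    control_s_sd: float

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("need >= 2 controls")
        zero = [a for a, s in zip(self.arms, self.sd) if not s > 0]
        if zero:
            raise ValueError(f"zero control SD on arms: {zero}")

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "arms": list(self.arms),
                    "mean": self.mean.tolist(),
                    "sd": self.sd.tolist(),
                    "n_controls": self.n_controls,
                    "control_s_mean": self.control_s_mean,
                    "control_s_sd": self.control_s_sd,
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ControlReference":
        d = json.loads(Path(path).read_text())
        return cls(
            tuple(d["arms"]),
            np.asarray(d["mean"], dtype=float),
            np.asarray(d["sd"], dtype=float),
            int(d["n_controls"]),
            float(d["control_s_mean"]),
            float(d["control_s_sd"]),
        )


@dataclass(frozen=True)
class ArmZScores:
    sample_id: str
    z: dict[str, float]


@dataclass(frozen=True)
class GenomeWideZScore:
    sample_id: str
    s: float  # sum of squared arm z-scores
    gw_z: float
    qc_flags: tuple[str, ...] = ()


def _fraction_matrix(
    controls: Sequence[ArmCountProfile], arms: Sequence[str]
) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # depth QC is reported per sample, not here
        return np.array(
            [[normalize_arm_counts(p, arms)[a] for a in arms] for p in controls]
        )


def build_reference(
    controls: Sequence[ArmCountProfile], arms: Sequence[str] | None = None
) -> ControlReference:
    """Per-arm mean/SD over the control cohort, plus leave-one-out S stats.

    Each control's S is computed against the reference built from the
    other n-1 controls, avoiding self-inclusion bias; the mean/SD of
    those S values define the second-stage standardization.
    """
    if len(controls) < 2:
        raise ValueError("need >= 2 control profiles")
    arms = list(arms) if arms is not None else retained_arm_names()
    f = _fraction_matrix(controls, arms)
    mean = f.mean(axis=0)
    sd = f.std(axis=0, ddof=1)

    n = len(controls)
    s_values = np.empty(n)
    for i in range(n):
        rest = np.delete(f, i, axis=0)
        mu = rest.mean(axis=0)
        sig = rest.std(axis=0, ddof=1)
        if not np.all(sig > 0):
            bad = [a for a, s in zip(arms, sig) if not s > 0]
            raise ValueError(f"zero leave-one-out SD on arms: {bad}")
        s_values[i] = float(np.sum(((f[i] - mu) / sig) ** 2))
    return ControlReference(
        tuple(arms),
        mean,
        sd,
        n,
        float(s_values.mean()),
        float(s_values.std(ddof=1)),
    )


def arm_zscores(sample: ArmCountProfile, ref: ControlReference) -> ArmZScores:
    """Standardize each retained arm fraction against the control cohort."""
    frac = normalize_arm_counts(sample, ref.arms)
    f = np.array([frac[a] for a in ref.arms])
    z = (f - ref.mean) / ref.sd
    return ArmZScores(sample.sample_id, {a: float(v) for a, v in zip(ref.arms, z)})


def genome_wide_zscore(
    z: ArmZScores,
    ref: ControlReference,
    mode: Literal["standardized", "raw"] = "standardized",
) -> GenomeWideZScore:
    """Sum of squared arm z-scores, standardized against the control S.

    ``mode="raw"`` reports S itself as the genome-wide score.
    """
    extra = set(z.z) - set(ref.arms)
    if extra or set(ref.arms) - set(z.z):
        raise ValueError("arm set mismatch between z-scores and reference")
    s = float(sum(v * v for v in z.z.values()))
    if mode == "raw":
        return GenomeWideZScore(z.sample_id, s, s)
    if not ref.control_s_sd > 0:
        raise ValueError("control S SD is zero; cannot standardize")
    return GenomeWideZScore(
        z.sample_id, s, (s - ref.control_s_mean) / ref.control_s_sd
    )


def score_sample(
    sample: ArmCountProfile,
    ref: ControlReference,
    mode: Literal["standardized", "raw"] = "standardized",
) -> GenomeWideZScore:
    """normalize -> arm z-scores -> genome-wide score, with read-depth QC flag."""
    flags = []
    if sample.total_reads < MIN_RECOMMENDED_READS:
        flags.append("low_read_count")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z = arm_zscores(sample, ref)
    g = genome_wide_zscore(z, ref, mode=mode)
    return GenomeWideZScore(g.sample_id, g.s, g.gw_z, tuple(flags))
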