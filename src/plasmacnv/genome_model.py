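"""Genome coordinate scaffolding shared by every stage of the pipeline.

Chromosomes, centromere-split arms and fixed-width bins are the three
coordinate systems used downstream: arm-level read counts feed the
aneuploidy z-score stage, 1 Mb bin counts feed the shallow-WGS
log2-ratio stage.  All coordinates are 0-based half-open internally and
BED-style on disk.

A bundled hg19-like chromosome/centromere table is the default build;
any build can be loaded from a two-column-plus TSV.  The short arms of
the acrocentric chromosomes (13p, 14p, 15p, 21p, 22p) carry essentially
no usable sequence for arm-level counting and are flagged so the
z-score stage can drop them.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "Chromosome",
    "GenomeBuild",
    "ChromosomeArm",
    "GenomicBin",
    "ArmCountProfile",
    "BinCountProfile",
    "ACROCENTRIC_SHORT_ARMS",
    "default_build",
    "load_build",
    "load_gene_annotations",
    "make_arms",
    "make_bins",
    "count_reads",
    "read_count_table",
    "write_count_table",
]

ACROCENTRIC_SHORT_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})


class ConfigurationError(ValueError):
    """Malformed genome build or region definition."""


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    centromere: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigurationError(f"{self.name}: length must be > 0")
        if not 0 < self.centromere < self.length:
            raise ConfigurationError(
                f"{self.name}: centromere {self.centromere} not inside (0, {self.length})"
            )


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with centromere positions."""

    name: str
    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate chromosome names in build")
        if not names:
            raise ConfigurationError("build has no chromosomes")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)


@dataclass(frozen=True)
class ChromosomeArm:
    chrom: str
    arm: str  # "p" or "q"
    start: int
    end: int
    acrocentric_short: bool = False

    @property
    def name(self) -> str:
        return f"{self.chrom.removeprefix('chr')}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GenomicBin:
    chrom: str
    start: int
    end: int
    gc_fraction: float | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ArmCountProfile:
    """Per-chromosome-arm read counts for one sample."""

    sample_id: str
    counts: dict[str, int]  # arm name ("8q") -> count
    total_reads: int

    def __post_init__(self) -> None:
        bad = {a: c for a, c in self.counts.items() if c < 0}
        if bad:
            raise ValueError(f"negative arm counts: {bad}")
        if self.total_reads < sum(self.counts.values()):
            raise ValueError("total_reads smaller than sum of arm counts")


@dataclass
class BinCountProfile:
    """Genome-wide per-bin read counts for one sample."""

    sample_id: str
    bins: tuple[GenomicBin, ...]
    counts: np.ndarray = field(repr=False)
    total_reads: int = 0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if len(self.counts) != len(self.bins):
            raise ValueError("counts and bins length mismatch")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("bin counts must be finite and non-negative")
        if self.total_reads == 0:
            self.total_reads = int(self.counts.sum())


# ---------------------------------------------------------------------------
# Builds and annotations


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("plasmacnv").joinpath("data", filename)))


def load_build(path: Union[str, Path], name: str | None = None) -> GenomeBuild:
    """Load a build from a TSV with columns chrom, length, centromere."""
    df = pd.read_csv(path, sep="\t")
    required = {"chrom", "length", "centromere"}
    if not required.issubset(df.columns):
        raise ConfigurationError(
            f"build table needs columns {sorted(required)}, got {list(df.columns)}"
        )
    chroms = tuple(
        Chromosome(str(r.chrom), int(r.length), int(r.centromere))
        for r in df.itertuples()
    )
    return GenomeBuild(name or Path(path).stem, chroms)


_DEFAULT_BUILD: GenomeBuild | None = None


def default_build() -> GenomeBuild:
    """The bundled hg19-like build (chr1-22, X, Y)."""
    global _DEFAULT_BUILD
    if _DEFAULT_BUILD is None:
        _DEFAULT_BUILD = load_build(_data_path("hg19_chromosomes.tsv"), name="hg19")
    return _DEFAULT_BUILD


def load_gene_annotations(path: Union[str, Path, None] = None) -> dict[str, tuple[str, int, int]]:
    """Bundled gene annotation (currently FGFR1 at 8p11-12), name -> (chrom, start, end)."""
    df = pd.read_csv(path or _data_path("gene_annotations.tsv"), sep="\t")
    return {
        str(r.gene): (str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()
    }


# ---------------------------------------------------------------------------
# Region construction


def make_arms(build: GenomeBuild) -> list[ChromosomeArm]:
    """Split every chromosome at its centromere into a p and a q arm."""
    arms: list[ChromosomeArm] = []
    for c in build.chromosomes:
        for arm, start, end in (("p", 0, c.centromere), ("q", c.centromere, c.length)):
            name = f"{c.name.removeprefix('chr')}{arm}"
            arms.append(
                ChromosomeArm(c.name, arm, start, end, name in ACROCENTRIC_SHORT_ARMS)
            )
    return arms


def make_bins(build: GenomeBuild, bin_size: int = 1_000_000) -> list[GenomicBin]:
    """Tile every chromosome with half-open fixed-width bins.

    The terminal bin of each chromosome may be shorter than ``bin_size``.
    Order is deterministic: build chromosome order, then start position.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be > 0, got {bin_size}")
    bins: list[GenomicBin] = []
    for c in build.chromosomes:
        for start in range(0, c.length, bin_size):
            bins.append(GenomicBin(c.name, start, min(start + bin_size, c.length)))
    return bins


# ---------------------------------------------------------------------------
# Read counting

Region = Union[ChromosomeArm, GenomicBin]


def _region_index(regions: Sequence[Region]) -> dict[str, tuple[list[int], list[int], list[int]]]:
    """chrom -> (sorted starts, ends, region indices) for leftmost-base lookup."""
    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for i, r in enumerate(regions):
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end, i))
    out = {}
    for chrom, triples in by_chrom.items():
        triples.sort()
        out[chrom] = (
            [t[0] for t in triples],
            [t[1] for t in triples],
            [t[2] for t in triples],
        )
    return out


def count_reads(
    alignments: Union[str, Path, pysam.AlignmentFile],
    regions: Sequence[Region],
    min_mapq: int = 15,
    sample_id: str | None = None,
) -> Union[ArmCountProfile, BinCountProfile]:
    """Count primary, non-duplicate alignments per region.

    A read passes if mapped, primary, not duplicate-flagged, and its
    mapping quality is strictly greater than ``min_mapq``; it is assigned
    to the region containing its leftmost aligned base.  ``total_reads``
    is the number of passing reads (including any that fall outside every
    region).  Returns an :class:`ArmCountProfile` if ``regions`` are arms,
    else a :class:`BinCountProfile`.
    """
    close = False
    if isinstance(alignments, (str, Path)):
        alignments = pysam.AlignmentFile(str(alignments), require_index=False)
        close = True
    try:
        # contigs present in the file but absent from the region set are
        # tolerated only if no passing read maps to them
        index = _region_index(regions)
        counts = np.zeros(len(regions), dtype=np.int64)
        total = 0
        offenders: set[str] = set()
        for read in alignments:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality <= min_mapq
            ):
                continue
            total += 1
            chrom = read.reference_name
            if chrom not in index:
                offenders.add(str(chrom))
                continue
            starts, ends, idxs = index[chrom]
            pos = read.reference_start
            j = bisect_right(starts, pos) - 1
            if j >= 0 and pos < ends[j]:
                counts[idxs[j]] += 1
        if offenders:
            raise ValueError(
                "alignments on contigs absent from the region set: "
                + ", ".join(sorted(offenders))
            )
    finally:
        if close:
            alignments.close()

    sid = sample_id or "sample"
    if regions and isinstance(regions[0], ChromosomeArm):
        return ArmCountProfile(
            sid,
            {r.name: int(c) for r, c in zip(regions, counts)},
            total_reads=total,
        )
    return BinCountProfile(sid, tuple(regions), counts, total_reads=total)


# ---------------------------------------------------------------------------
# Count-table I/O (TSV, BED-style coordinates)

_ARM_COLS = ["sample_id", "arm", "count", "total_reads"]
_BIN_COLS = ["sample_id", "chrom", "start", "end", "count", "total_reads"]


def write_count_table(
    profiles: Union[ArmCountProfile, BinCountProfile, Iterable],
    path: Union[str, Path],
) -> None:
    """Write one or more profiles to a TSV count table."""
    if isinstance(profiles, (ArmCountProfile, BinCountProfile)):
        profiles = [profiles]
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to write")
    rows = []
    if isinstance(profiles[0], ArmCountProfile):
        for p in profiles:
            for arm, c in p.counts.items():
                rows.append((p.sample_id, arm, c, p.total_reads))
        pd.DataFrame(rows, columns=_ARM_COLS).to_csv(path, sep="\t", index=False)
    else:
        for p in profiles:
            for b, c in zip(p.bins, p.counts):
                rows.append((p.sample_id, b.chrom, b.start, b.end, int(c), p.total_reads))
        pd.DataFrame(rows, columns=_BIN_COLS).to_csv(path, sep="\t", index=False)


def read_count_table(
    path: Union[str, Path],
    regions: Sequence[Region] | None = None,
) -> list[Union[ArmCountProfile, BinCountProfile]]:
    """Read a TSV count table back into profiles.

    If ``regions`` is given, every row must map onto a known region (by arm
    name, or exact chrom/start/end for bins) and profiles are returned on
    that region set; unknown regions raise a validation error.
    """
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if cols[:3] == _ARM_COLS[:3]:
        kind = "arm"
    elif cols[:5] == _BIN_COLS[:5]:
        kind = "bin"
    else:
        raise ValueError(
            f"unrecognized count-table header {cols}; expected {_ARM_COLS} or {_BIN_COLS}"
        )
    if (df["count"] < 0).any():
        bad = df.loc[df["count"] < 0]
        raise ValueError(f"negative counts in table: rows {bad.index.tolist()}")

    profiles: list[Union[ArmCountProfile, BinCountProfile]] = []
    if kind == "arm":
        known = {r.name for r in regions} if regions is not None else None
        for sid, grp in df.groupby("sample_id", sort=False):
            counts = {str(a): int(c) for a, c in zip(grp["arm"], grp["count"])}
            if known is not None:
                unknown = set(counts) - known
                if unknown:
                    raise ValueError(f"unknown arms in table: {sorted(unknown)}")
            total = int(grp["total_reads"].iloc[0]) if "total_reads" in grp else sum(counts.values())
            profiles.append(ArmCountProfile(str(sid), counts, total))
    else:
        known_bins = (
            {(b.chrom, b.start, b.end): b for b in regions} if regions is not None else None
        )
        for sid, grp in df.groupby("sample_id", sort=False):
            bins = []
            for r in grp.itertuples():
                key = (str(r.chrom), int(r.start), int(r.end))
                if known_bins is not None:
                    if key not in known_bins:
                        raise ValueError(f"unknown bin in table: {key}")
                    bins.append(known_bins[key])
                else:
                    bins.append(GenomicBin(*key))
            total = int(grp["total_reads"].iloc[0]) if "total_reads" in grp else 0
            profiles.append(
                BinCountProfile(
                    str(sid), tuple(bins), grp["count"].to_numpy(np.int64), total
                )
            )
    return profiles


def bins_overlapping(
    bins: Sequence[GenomicBin], chrom: str, start: int, end: int
) -> list[int]:
    """Indices of bins overlapping [start, end) on chrom."""
    return [
        i
        for i, b in enumerate(bins)
        if b.chrom == chrom and b.start < end and b.end > start
    ]
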