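"""FISH amplification scoring and tissue-level concordance with array
copy-number status.

FGFR1 FISH scoring follows the standard two-tier rule set used in
routine pathology: a tumor is *amplified* if the gene-to-centromere
signal ratio is >= 2.0 or the average number of gene signals per tumor
cell nucleus is >= 6.0; failing that, it is *low amplified* if at least
50% of tumor cells carry >= 5 gene signals or at least 10% carry >= 15
signals or signal clusters; otherwise *balanced*.  The main criteria
take precedence: a tumor meeting both tiers is reported as amplified.

The array (Oncoscan-style) side is consumed as printed output: a case
is a copy-number *gain* when its integer copy number is >= 3 (the
threshold is configurable).  Concordance treats both FISH tiers as
positive and compares them against gain / no-gain.

A bundled reference cohort (FISH scores of the 20 FGFR1-amplified
tumors from a published 100-patient metastatic breast cancer study, and
the 11-case array confirmation subset) ships as packaged CSVs.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "FishMeasurement",
    "FishStatus",
    "OncoscanRecord",
    "ConcordanceResult",
    "classify_fish",
    "classify_cohort",
    "concordance",
    "summarize_fish",
    "load_fish_table",
    "load_oncoscan_table",
]

AMPLIFIED = "amplified"
LOW_AMPLIFIED = "low_amplified"
BALANCED = "balanced"
POSITIVE_STATUSES = frozenset({AMPLIFIED, LOW_AMPLIFIED})


@dataclass(frozen=True)
class FishMeasurement:
    """One tumor's FISH scoring values.

    ratio: gene/centromere signal ratio; avg_gene_signals and
    avg_cen_signals: mean signals per tumor cell nucleus; q5 / q15:
    fraction of tumor cells with >= 5 gene signals resp. >= 15 signals
    or large clusters.
    """

    case_id: str
    ratio: float
    avg_gene_signals: float
    avg_cen_signals: float
    q5: float
    q15: float

    def __post_init__(self) -> None:
        vals = (self.ratio, self.avg_gene_signals, self.avg_cen_signals, self.q5, self.q15)
        if any(v is None or not np.isfinite(v) for v in vals):
            raise ValueError(f"{self.case_id}: all FISH fields must be finite")
        if any(v < 0 for v in vals):
            raise ValueError(f"{self.case_id}: FISH fields must be >= 0")
        if not (0 <= self.q5 <= 1 and 0 <= self.q15 <= 1):
            raise ValueError(f"{self.case_id}: q5/q15 must be in [0, 1]")
        if self.avg_cen_signals > 0:
            implied = self.avg_gene_signals / self.avg_cen_signals
            if self.ratio > 0 and abs(implied - self.ratio) / self.ratio > 0.10:
                warnings.warn(
                    f"{self.case_id}: ratio {self.ratio} vs gene/cen "
                    f"{implied:.2f} differ by > 10%",
                    stacklevel=3,
                )


@dataclass(frozen=True)
class FishStatus:
    case_id: str
    status: str  # amplified | low_amplified | balanced
    criterion: str  # which rule fired

    @property
    def positive(self) -> bool:
        return self.status in POSITIVE_STATUSES


@dataclass(frozen=True)
class OncoscanRecord:
    case_id: str
    status: str  # gain | no_gain
    copy_number: int

    def __post_init__(self) -> None:
        if self.status not in ("gain", "no_gain"):
            raise ValueError(f"{self.case_id}: status must be gain/no_gain")
        if self.copy_number < 0:
            raise ValueError(f"{self.case_id}: copy_number must be >= 0")


def classify_fish(
    m: FishMeasurement,
    ratio_threshold: float = 2.0,
    signals_threshold: float = 6.0,
    q5_threshold: float = 0.50,
    q15_threshold: float = 0.10,
) -> FishStatus:
    """Two-tier amplification call; all thresholds inclusive (>=)."""
    if m.ratio >= ratio_threshold:
        return FishStatus(m.case_id, AMPLIFIED, "ratio")
    if m.avg_gene_signals >= signals_threshold:
        return FishStatus(m.case_id, AMPLIFIED, "avg_signals")
    if m.q5 >= q5_threshold:
        return FishStatus(m.case_id, LOW_AMPLIFIED, "q5")
    if m.q15 >= q15_threshold:
        return FishStatus(m.case_id, LOW_AMPLIFIED, "q15")
    return FishStatus(m.case_id, BALANCED, "none")


def classify_cohort(
    measurements: Sequence[FishMeasurement], **thresholds
) -> tuple[Counter, pd.DataFrame]:
    """Classify every case; returns status counts and a per-case table."""
    if not measurements:
        raise ValueError("no measurements")
    ids = [m.case_id for m in measurements]
    dupes = [c for c, k in Counter(ids).items() if k > 1]
    if dupes:
        raise ValueError(f"duplicate case ids: {dupes}")
    statuses = [classify_fish(m, **thresholds) for m in measurements]
    table = pd.DataFrame(
        {
            "case_id": [s.case_id for s in statuses],
            "status": [s.status for s in statuses],
            "criterion": [s.criterion for s in statuses],
        }
    ).sort_values("case_id", ignore_index=True)
    return Counter(s.status for s in statuses), table


@dataclass(frozen=True)
class ConcordanceResult:
    fraction: float
    percent: int  # rounded to nearest integer
    n: int
    discordant: tuple[str, ...]


def concordance(
    fish: Sequence[FishStatus], array: Sequence[OncoscanRecord]
) -> ConcordanceResult:
    """FISH-vs-array agreement over cases present in both.

    FISH positive = amplified or low-amplified; array positive = gain.
    """
    fish_by_id = {s.case_id: s for s in fish}
    joined = [(fish_by_id[r.case_id], r) for r in array if r.case_id in fish_by_id]
    if not joined:
        raise ValueError("no cases shared between FISH and array tables")
    discordant = tuple(
        sorted(s.case_id for s, r in joined if s.positive != (r.status == "gain"))
    )
    n = len(joined)
    frac = (n - len(discordant)) / n
    return ConcordanceResult(frac, round(frac * 100), n, discordant)


def summarize_fish(measurements: Sequence[FishMeasurement]) -> dict[str, float]:
    """Order statistics of the ratio and average-signal columns."""
    if not measurements:
        raise ValueError("no measurements")
    ratio = np.array([m.ratio for m in measurements])
    sig = np.array([m.avg_gene_signals for m in measurements])
    return {
        "ratio_min": float(ratio.min()),
        "ratio_max": float(ratio.max()),
        "ratio_median": float(np.median(ratio)),
        "avg_signals_min": float(sig.min()),
        "avg_signals_max": float(sig.max()),
        "avg_signals_median": float(np.median(sig)),
        "n": len(measurements),
    }


# ---------------------------------------------------------------------------
# Packaged table loaders


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("plasmacnv").joinpath("data", filename)))


def load_fish_table(path: Union[str, Path, None] = None) -> list[FishMeasurement]:
    """Bundled FISH scoring table (20 FGFR1-amplified tumors) or a CSV like it."""
    df = pd.read_csv(path or _data_path("fish_cohort.csv"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # ratio-vs-signals consistency notes
        return [
            FishMeasurement(
                str(r.case_id),
                float(r.ratio),
                float(r.avg_gene_signals),
                float(r.avg_cen_signals),
                float(r.q5),
                float(r.q15),
            )
            for r in df.itertuples()
        ]


def load_oncoscan_table(
    path: Union[str, Path, None] = None, gain_threshold: int = 3
) -> list[OncoscanRecord]:
    """Bundled array copy-number confirmation table (11 cases) or a CSV like it.

    If the status column is absent it is derived from the copy number
    (gain when >= gain_threshold).
    """
    df = pd.read_csv(path or _data_path("oncoscan_concordance.csv"))
    records = []
    for r in df.itertuples():
        cn = int(r.oncoscan_copy_number)
        status = (
            str(r.oncoscan_status)
            if "oncoscan_status" in df.columns
            else ("gain" if cn >= gain_threshold else "no_gain")
        )
        records.append(OncoscanRecord(str(r.case_id), status, cn))
    return records
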