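"""Cohort-level statistics joining plasma and tissue results.

Thresholding and order statistics of the plasma markers (genome-wide
z-score, tumor fraction), their correlation, Kaplan-Meier /log-rank
survival analysis with median-split stratification, and a structured
cohort report.

Survival machinery wraps lifelines (product-limit estimator with
exponential-Greenwood log-log confidence intervals; standard two-group
log-rank with the asymptotic chi-square reference, df = 1).  The median
split assigns values equal to the median to the LOW group — the bundled
plasma cohort has two samples exactly at the tumor-fraction median, so
this choice changes group sizes and is surfaced in the result.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

from .fish_oncoscan import (
    POSITIVE_STATUSES,
    FishMeasurement,
    OncoscanRecord,
    classify_cohort,
    concordance,
    classify_fish,
    summarize_fish,
)

__all__ = [
    "SampleRecord",
    "KMCurve",
    "LogRankResult",
    "StratifiedSurvival",
    "load_plasma_cohort",
    "threshold_count",
    "median_value",
    "r_squared",
    "km_estimate",
    "logrank_test",
    "stratify_and_test",
    "build_report",
]


@dataclass
class SampleRecord:
    """One patient's joined plasma/tissue row."""

    case_id: str
    fish_status: str | None = None
    oncoscan_status: str | None = None
    gw_z: float | None = None
    itf_percent: float | None = None
    plasma_call: str | None = None  # "+" or "-"
    cfdna_ng_per_ml: float | None = None
    os_months: float | None = None
    event: bool | None = None

    def __post_init__(self) -> None:
        if self.itf_percent is not None and not 0 <= self.itf_percent <= 100:
            raise ValueError(f"{self.case_id}: itf_percent outside [0, 100]")
        if self.os_months is not None and self.os_months < 0:
            raise ValueError(f"{self.case_id}: os_months must be >= 0")


def load_plasma_cohort(path: Union[str, Path, None] = None) -> list[SampleRecord]:
    """Bundled 20-patient plasma cohort table (or a CSV with its schema)."""
    if path is None:
        path = Path(str(resources.files("plasmacnv").joinpath("data", "plasma_cohort.csv")))
    df = pd.read_csv(path, dtype={"case_id": str})
    records = []
    for r in df.itertuples():
        records.append(
            SampleRecord(
                case_id=str(r.case_id),
                fish_status=None if pd.isna(r.fish_status) else str(r.fish_status),
                oncoscan_status=(
                    None if pd.isna(r.oncoscan_status) else str(r.oncoscan_status)
                ),
                gw_z=float(r.gw_z),
                itf_percent=float(r.itf_percent),
                plasma_call=None if pd.isna(r.plasma_call) else str(r.plasma_call),
                os_months=float(r.os_months) if hasattr(r, "os_months") else None,
                event=bool(r.event) if hasattr(r, "event") else None,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Scalar statistics


def threshold_count(values: Sequence[float], cutoff: float) -> int:
    """Count of values strictly greater than cutoff."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("values must be finite")
    return int((arr > cutoff).sum())


def median_value(values: Sequence[float]) -> float:
    """Standard median (mean of the central pair for even n)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median of empty list")
    return float(np.median(arr))


def r_squared(x: Sequence[float], y: Sequence[float]) -> float:
    """Square of the Pearson correlation on raw values."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length inputs with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate (zero-variance) input")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


# ---------------------------------------------------------------------------
# Survival


@dataclass(frozen=True)
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_at_risk: np.ndarray
    median: float  # months; inf when never reached
    n: int

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class LogRankResult:
    chi_square: float
    p_value: float
    n1: int
    n2: int


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> KMCurve:
    """Product-limit survival estimate with log-log Greenwood 95% CI."""
    t = np.asarray(list(times), dtype=float)
    e = np.asarray(list(events), dtype=bool)
    if t.size == 0 or t.size != e.size:
        raise ValueError("need equal-length, non-empty times and events")
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_.iloc[:, 0]
    ci = kmf.confidence_interval_
    grid = sf.index.to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    med = kmf.median_survival_time_
    return KMCurve(
        grid,
        sf.to_numpy(dtype=float),
        ci.iloc[:, 0].to_numpy(dtype=float),
        ci.iloc[:, 1].to_numpy(dtype=float),
        at_risk,
        float(med) if np.isfinite(med) else math.inf,
        int(t.size),
    )


def logrank_test(
    times1: Sequence[float],
    events1: Sequence[bool],
    times2: Sequence[float],
    events2: Sequence[bool],
) -> LogRankResult:
    """Two-group log-rank test (chi-square with df = 1)."""
    t1 = np.asarray(list(times1), dtype=float)
    t2 = np.asarray(list(times2), dtype=float)
    e1 = np.asarray(list(events1), dtype=bool)
    e2 = np.asarray(list(events2), dtype=bool)
    if t1.size == 0 or t2.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (e1.any() or e2.any()):
        raise ValueError("no events in either group")
    res = _ll_logrank(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return LogRankResult(
        float(res.test_statistic), float(res.p_value), int(t1.size), int(t2.size)
    )


@dataclass(frozen=True)
class StratifiedSurvival:
    variable: str
    cutoff: float
    low: KMCurve
    high: KMCurve
    test: LogRankResult
    low_median_os: float
    high_median_os: float


def stratify_and_test(
    records: Sequence[SampleRecord], variable: str
) -> StratifiedSurvival:
    """Median-split a cohort on ``variable`` and log-rank the two groups.

    Values equal to the median go to the low group.  Requires >= 4
    records with the variable, survival time and event flag present.
    """
    rows = [
        r
        for r in records
        if getattr(r, variable) is not None
        and r.os_months is not None
        and r.event is not None
    ]
    if len(rows) < 4:
        raise ValueError(f"need >= 4 records with {variable} and survival data")
    vals = np.array([getattr(r, variable) for r in rows], dtype=float)
    cutoff = float(np.median(vals))
    low = [r for r, v in zip(rows, vals) if v <= cutoff]
    high = [r for r, v in zip(rows, vals) if v > cutoff]
    if not high:
        raise ValueError(f"all {variable} values identical; empty high group")
    km_low = km_estimate([r.os_months for r in low], [r.event for r in low])
    km_high = km_estimate([r.os_months for r in high], [r.event for r in high])
    test = logrank_test(
        [r.os_months for r in low],
        [r.event for r in low],
        [r.os_months for r in high],
        [r.event for r in high],
    )
    return StratifiedSurvival(
        variable, cutoff, km_low, km_high, test, km_low.median, km_high.median
    )


# ---------------------------------------------------------------------------
# Report


def build_report(
    fish: Sequence[FishMeasurement] | None = None,
    array: Sequence[OncoscanRecord] | None = None,
    records: Sequence[SampleRecord] | None = None,
    survival_variables: Sequence[str] = (),
    z_cutoff: float = 3.0,
    itf_cutoff_percent: float = 3.0,
) -> dict:
    """Deterministic structured summary of all cohort-level statistics.

    Sections appear for whichever inputs are provided: FISH status
    counts, FISH/array concordance, plasma-marker thresholds, medians and
    correlation, and optional median-split survival tests.
    """
    if fish is None and array is None and records is None:
        raise ValueError("empty cohort: nothing to report")
    report: dict = {}
    statuses = None
    if fish:
        counts, _table = classify_cohort(fish)
        statuses = [classify_fish(m) for m in fish]
        summary = summarize_fish(fish)
        report["fish"] = {
            "n": len(fish),
            "amplified": counts.get("amplified", 0),
            "low_amplified": counts.get("low_amplified", 0),
            "balanced": counts.get("balanced", 0),
            "positive": counts.get("amplified", 0) + counts.get("low_amplified", 0),
            "ratio_range": [summary["ratio_min"], summary["ratio_max"]],
            "avg_signals_range": [
                summary["avg_signals_min"],
                summary["avg_signals_max"],
            ],
        }
    if array and statuses is not None:
        conc = concordance(statuses, array)
        report["concordance"] = {
            "n": conc.n,
            "percent": conc.percent,
            "fraction": conc.fraction,
            "discordant": list(conc.discordant),
        }
    if records:
        z = [r.gw_z for r in records if r.gw_z is not None]
        itf = [r.itf_percent for r in records if r.itf_percent is not None]
        high_itf_positive = sum(
            1
            for r in records
            if r.itf_percent is not None
            and r.itf_percent > itf_cutoff_percent
            and r.fish_status in POSITIVE_STATUSES
        )
        report["plasma"] = {
            "n": len(records),
            "gw_z_median": median_value(z),
            "gw_z_max": max(z),
            "n_gw_z_above_cutoff": threshold_count(z, z_cutoff),
            "z_cutoff": z_cutoff,
            "itf_median_percent": median_value(itf),
            "n_itf_above_cutoff": threshold_count(itf, itf_cutoff_percent),
            "itf_cutoff_percent": itf_cutoff_percent,
            "n_itf_above_cutoff_fish_positive": high_itf_positive,
        }
        if len(z) >= 3 and len(z) == len(itf):
            report["plasma"]["r_squared_z_vs_itf"] = round(r_squared(z, itf), 4)
        for var in survival_variables:
            strat = stratify_and_test(records, var)
            report.setdefault("survival", {})[var] = {
                "cutoff": strat.cutoff,
                "n_low": strat.test.n1,
                "n_high": strat.test.n2,
                "chi_square": strat.test.chi_square,
                "p_value": strat.test.p_value,
                "low_median_os": strat.low_median_os,
                "high_median_os": strat.high_median_os,
            }
    return report


def report_to_json(report: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True, default=float))
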