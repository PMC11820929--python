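"""Hourly activity budgets and baseline-relative normalization.

The activity "level" of an hour is the mean of the numeric state codes
(1 lying, 2 standing, 3 walking) over that hour's records.  To compare
animals with different baseline temperaments, each hour is expressed
relative to the same animal's own all-time mean (a unitless ratio), which
removes inter-individual baseline differences; a ratio above 1 marks an
hour more active than that pig's norm.  By construction the record-weighted
mean of the ratios over all hours is exactly 1.

Records taken while a keeper is in the pen reflect human-driven activity
(feeding, handling); the keeper filter can exclude them, pass them, or pass
them flagged for downstream stratification.  Records with no detected pig
(UNKNOWN state) are always dropped before averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .activity import ActivityRecord

__all__ = [
    "HourlyActivity",
    "KeeperPolicy",
    "filter_keeper",
    "hourly_mean",
    "overall_mean",
    "baseline_relative",
    "hourly_to_csv",
    "plot_hourly_curve",
]

KeeperPolicy = Literal["exclude", "keep", "flag_only"]


@dataclass(frozen=True)
class HourlyActivity:
    pig_id: str
    hour_of_day: int  # 0-23
    mean_state: float  # in [1, 3]
    n_records: int
    relative_activity: float | None = None  # mean_state / pig's overall mean


def _hour_of_day(timestamp_s: float) -> int:
    return int(timestamp_s // 3600) % 24


def filter_keeper(
    records: Sequence[ActivityRecord], policy: KeeperPolicy = "exclude"
) -> list[ActivityRecord]:
    """Apply the keeper policy and drop UNKNOWN records.

    ``exclude`` removes keeper-present records; ``keep`` and ``flag_only``
    pass everything (the flag stays on each record either way — flag_only
    exists so callers can state the stratify-downstream intent explicitly).
    """
    if policy not in ("exclude", "keep", "flag_only"):
        raise ValueError(f"unknown keeper policy {policy!r}")
    out = [r for r in records if not r.is_unknown]
    if policy == "exclude":
        out = [r for r in out if not r.keeper_present]
    if records and not out:
        warnings.warn("no usable records after filtering", stacklevel=2)
    return out


def hourly_mean(records: Sequence[ActivityRecord], pig_id: str) -> list[HourlyActivity]:
    """Mean state code per hour of day; hours with no records are omitted.

    Records from different days that share an hour of day pool into one
    bin — the diurnal pattern, not a timeline.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for r in records:
        if r.is_unknown:
            continue
        h = _hour_of_day(r.timestamp_s)
        sums[h] = sums.get(h, 0.0) + r.state
        counts[h] = counts.get(h, 0) + 1
    return [
        HourlyActivity(pig_id=pig_id, hour_of_day=h, mean_state=sums[h] / counts[h], n_records=counts[h])
        for h in sorted(sums)
    ]


def overall_mean(records: Sequence[ActivityRecord]) -> float:
    """The pig's all-time mean state code over all usable records."""
    states = [r.state for r in records if not r.is_unknown]
    if not states:
        raise ValueError("no usable records")
    return sum(states) / len(states)


def baseline_relative(
    hourly: Sequence[HourlyActivity], pig_overall_mean: float
) -> list[HourlyActivity]:
    """Express each hour relative to the pig's own overall mean (ratio).

    The overall mean must come from all the pig's records regardless of
    day or timepoint; state codes are >= 1 so it can never be zero.
    """
    if pig_overall_mean <= 0:
        raise ValueError("overall mean must be positive")
    return [
        replace(h, relative_activity=h.mean_state / pig_overall_mean) for h in hourly
    ]


def hourly_to_csv(hourly: Sequence[HourlyActivity], path: str | Path) -> None:
    pd.DataFrame(
        [
            (h.pig_id, h.hour_of_day, h.mean_state, h.relative_activity, h.n_records)
            for h in hourly
        ],
        columns=["pig_id", "hour_of_day", "mean_state", "relative_activity", "n_records"],
    ).to_csv(path, index=False)


def plot_hourly_curve(
    hourly_by_pig: dict[str, Sequence[HourlyActivity]], path: str | Path
) -> None:
    """Write a per-pig baseline-relative diurnal curve as a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for pig_id, hourly in hourly_by_pig.items():
        hours = [h.hour_of_day for h in hourly]
        vals = [
            h.relative_activity if h.relative_activity is not None else h.mean_state
            for h in hourly
        ]
        ax.plot(hours, vals, marker="o", label=pig_id)
    ax.axhline(1.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel("hour of day")
    ax.set_ylabel("activity relative to own baseline")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
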