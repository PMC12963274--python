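"""Daily and participant-level digital mobility outcomes (DMOs).

Walking-activity outcomes (steps/day, minutes walked, bout counts, bout
durations) are computed from every bout regardless of duration; gait
outcomes (walking speed, stride length, stride duration, cadence) are
computed per bout-duration class (>10 s, 10–30 s, >30 s) as stride-count
weighted means, since bouts shorter than 10 s do not support reliable gait
estimates. Everything is stratified by context: ``all``, ``indoor``,
``outdoor`` (plus an ``unknown`` stratum so step counts are conserved);
unknown-context bouts contribute to ``all`` only among the analysis strata.

Daily rows are then reduced to one row per participant and stratum by the
median across valid days (configurable to the mean); participants with
fewer than ``min_days`` valid days are flagged excluded, matching the
wear-time inclusion rule of multi-day monitoring studies (> 2 days).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bouts import WalkingBout
from .config import GAIT_CLASS_LABELS

__all__ = ["aggregate_daily", "aggregate_participant", "CLASS_SUFFIX"]

#: machine-stable column suffix per duration-class label
CLASS_SUFFIX = {">10 s": "gt10", "10–30 s": "10_30", ">30 s": "gt30", ">60 s": "gt60"}

STRATA = ("all", "indoor", "outdoor", "unknown")
GAIT_DMOS = ("walking_speed_mps", "stride_length_m", "stride_duration_s",
             "cadence_spm")


def _gait_cols() -> list[str]:
    return [
        f"{dmo}__{CLASS_SUFFIX[label]}"
        for label in GAIT_CLASS_LABELS
        for dmo in GAIT_DMOS
    ]


def _empty_day_row(pid, day, stratum) -> dict:
    row = {
        "participant_id": pid,
        "day": day,
        "stratum": stratum,
        "steps": 0,
        "walking_min": 0.0,
        "n_bouts": 0,
        "mean_bout_duration_s": np.nan,
        "max_bout_duration_s": np.nan,
    }
    for suffix in CLASS_SUFFIX.values():
        row[f"n_bouts_{suffix}"] = 0
    for col in _gait_cols():
        row[col] = np.nan
    return row


def _day_row(pid, day, stratum, bouts: list[WalkingBout]) -> dict:
    row = _empty_day_row(pid, day, stratum)
    if not bouts:
        return row
    n_strides = np.array([b.n_strides for b in bouts])
    durations = np.array([b.duration_s for b in bouts])
    row["steps"] = int(2 * n_strides.sum())  # one stride = one gait cycle = 2 steps
    row["walking_min"] = float(durations.sum() / 60.0)
    row["n_bouts"] = len(bouts)
    row["mean_bout_duration_s"] = float(durations.mean())
    row["max_bout_duration_s"] = float(durations.max())
    for label, suffix in CLASS_SUFFIX.items():
        row[f"n_bouts_{suffix}"] = sum(label in b.duration_labels for b in bouts)
    for label in GAIT_CLASS_LABELS:
        members = [b for b in bouts if label in b.duration_labels]
        if not members:
            continue
        strides = pd.concat([b.strides for b in members], ignore_index=True)
        suffix = CLASS_SUFFIX[label]
        row[f"walking_speed_mps__{suffix}"] = float(strides["speed_mps"].mean())
        row[f"stride_length_m__{suffix}"] = float(strides["stride_length_m"].mean())
        row[f"stride_duration_s__{suffix}"] = float(strides["stride_duration_s"].mean())
        # cadence in steps/min from the gait-cycle duration: 120 / duration
        row[f"cadence_spm__{suffix}"] = float(
            (120.0 / strides["stride_duration_s"]).mean()
        )
    return row


def aggregate_daily(
    bouts: list[WalkingBout], days: dict[str, list[int]] | None = None
) -> pd.DataFrame:
    """One row per (participant, day, stratum) of daily DMOs.

    ``days`` optionally maps participant_id to the full list of monitored
    days so that zero-bout days still produce (zero-activity) rows.
    """
    by_pd: dict[tuple[str, int], list[WalkingBout]] = {}
    for b in bouts:
        by_pd.setdefault((b.participant_id, b.day), []).append(b)
    keys = set(by_pd)
    if days:
        keys |= {(pid, d) for pid, ds in days.items() for d in ds}
    rows = []
    for pid, day in sorted(keys):
        members = by_pd.get((pid, day), [])
        for stratum in STRATA:
            if stratum == "all":
                sel = members
            else:
                sel = [b for b in members if b.context == stratum]
            rows.append(_day_row(pid, day, stratum, sel))
    return pd.DataFrame(rows)


def aggregate_participant(
    daily: pd.DataFrame, min_days: int = 3, method: str = "median"
) -> pd.DataFrame:
    """Reduce daily DMO rows to one row per (participant, stratum).

    A valid day is a day with at least one bout overall. Participants with
    fewer than ``min_days`` valid days are flagged ``excluded`` (and should
    be omitted from group statistics). Reduction is the median across valid
    days by default.
    """
    if method not in ("median", "mean"):
        raise ValueError("method must be 'median' or 'mean'")
    if len(daily) == 0:
        return pd.DataFrame()
    all_rows = daily[daily["stratum"] == "all"]
    valid_days = (
        all_rows[all_rows["n_bouts"] > 0].groupby("participant_id")["day"].agg(set)
    )
    value_cols = [
        c for c in daily.columns if c not in ("participant_id", "day", "stratum")
    ]
    out = []
    for (pid, stratum), group in daily.groupby(["participant_id", "stratum"]):
        days = valid_days.get(pid, set())
        sub = group[group["day"].isin(days)]
        row = {
            "participant_id": pid,
            "stratum": stratum,
            "n_valid_days": len(days),
            "excluded": len(days) < min_days,
        }
        for col in value_cols:
            vals = sub[col].dropna()
            row[col] = float(getattr(vals, method)()) if len(vals) else np.nan
        out.append(row)
    return pd.DataFrame(out)
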