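"""Walking-bout segmentation from stride-level gait events.

Implements the consensus real-world walking-bout definition: a bout is a
maximal run of valid strides in which no inter-stride break exceeds 3 s;
a stride is valid if its duration lies in [0.2, 3.0] s (inclusive) and its
length is strictly greater than 0.15 m. Candidate bouts with fewer than
``min_strides_per_bout`` strides (default 3 full gait cycles, i.e. about six
foot contacts) are discarded. Bouts are then classified into (possibly
overlapping) duration classes: >10 s, 10–30 s, >30 s, >60 s, where ">10 s"
means strictly greater than 10 s and "10–30 s" means (10, 30].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import BoutConfig, DurationClass

__all__ = [
    "WalkingBout",
    "filter_strides",
    "segment_bouts",
    "classify_bout_duration",
    "segment_participant_days",
    "bouts_to_frame",
]


class StrideValidationError(ValueError):
    """Raised for structurally invalid stride input (negative durations,
    overlapping strides)."""


@dataclass
class WalkingBout:
    bout_id: int
    participant_id: str
    day: int
    start_s: float
    end_s: float
    strides: pd.DataFrame  # time-ordered rows of the input stride table
    context: str = "unknown"
    p_indoor: float = 0.5
    evidence_coverage: float = 0.0
    duration_labels: tuple[str, ...] = field(default_factory=tuple)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_strides(self) -> int:
        return len(self.strides)


def _with_speed(strides: pd.DataFrame) -> pd.DataFrame:
    out = strides.copy()
    out["speed_mps"] = out["stride_length_m"] / out["stride_duration_s"]
    return out


def filter_strides(
    strides: pd.DataFrame, cfg: BoutConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply stride validity filters; returns (valid strides, rejection log).

    Duration bounds are inclusive; the length bound is strict (> 0.15 m).
    Input is sorted by start time if it is not already.
    """
    cfg.validate()
    if len(strides) == 0:
        return strides.copy(), strides.assign(reason=pd.Series(dtype=str))
    if (strides["stride_duration_s"] < 0).any():
        raise StrideValidationError("negative stride duration in input")
    s = strides.sort_values("stride_start_s", kind="mergesort").reset_index(drop=True)
    dur = s["stride_duration_s"].to_numpy()
    length = s["stride_length_m"].to_numpy()
    too_short = dur < cfg.min_stride_duration_s
    too_long = dur > cfg.max_stride_duration_s
    short_step = length <= cfg.min_stride_length_m
    bad = too_short | too_long | short_step
    reason = np.select(
        [too_short, too_long, short_step],
        ["duration_below_min", "duration_above_max", "length_at_or_below_min"],
        default="",
    )
    log = s.loc[bad].assign(reason=reason[bad])
    return s.loc[~bad].reset_index(drop=True), log.reset_index(drop=True)


def _split_indices(starts: np.ndarray, ends: np.ndarray, break_s: float) -> list:
    """Boundaries of maximal runs where gap (next start - prev end) <= break_s.

    A split requires the gap to be strictly greater than the threshold.
    """
    if len(starts) == 0:
        return []
    gaps = starts[1:] - ends[:-1]
    cut = np.flatnonzero(gaps > break_s) + 1
    return np.split(np.arange(len(starts)), cut)


def segment_bouts(
    valid_strides: pd.DataFrame,
    cfg: BoutConfig,
    participant_id: str = "",
    day: int = 0,
    bout_id_start: int = 0,
) -> list[WalkingBout]:
    """Split time-sorted valid strides into walking bouts.

    Splits where the inter-stride gap is strictly greater than the 3 s break
    threshold; fragments with fewer than ``min_strides_per_bout`` strides are
    discarded. Overlapping strides are rejected with the offending indices.
    """
    cfg.validate()
    if len(valid_strides) == 0:
        return []
    s = valid_strides.sort_values("stride_start_s", kind="mergesort")
    s = _with_speed(s.reset_index(drop=True))
    starts = s["stride_start_s"].to_numpy()
    ends = starts + s["stride_duration_s"].to_numpy()
    overlap = np.flatnonzero(starts[1:] < ends[:-1] - 1e-9)
    if overlap.size:
        raise StrideValidationError(
            f"overlapping strides at sorted indices {overlap[:10].tolist()}"
        )
    bouts = []
    bout_id = bout_id_start
    for run in _split_indices(starts, ends, cfg.break_threshold_s):
        if len(run) < cfg.min_strides_per_bout:
            continue
        chunk = s.iloc[run].reset_index(drop=True)
        bout = WalkingBout(
            bout_id=bout_id,
            participant_id=participant_id,
            day=day,
            start_s=float(starts[run[0]]),
            end_s=float(ends[run[-1]]),
            strides=chunk,
        )
        bout.duration_labels = classify_bout_duration(bout, cfg)
        bouts.append(bout)
        bout_id += 1
    return bouts


def classify_bout_duration(bout: WalkingBout, cfg: BoutConfig) -> tuple[str, ...]:
    """All duration-class labels whose interval contains the bout duration.

    Classes may overlap: a 45 s bout is in ">10 s" and ">30 s"; a 9.9 s bout
    is in no gait class (it still counts toward activity outcomes).
    """
    d = bout.duration_s
    return tuple(c.label for c in cfg.duration_classes if c.contains(d))


def segment_participant_days(
    strides: pd.DataFrame, cfg: BoutConfig
) -> tuple[list[WalkingBout], pd.DataFrame]:
    """Filter and segment a multi-participant stride table.

    Returns all bouts (ids unique across the table) plus the stride
    rejection log.
    """
    cfg.validate()
    all_bouts: list[WalkingBout] = []
    logs = []
    if len(strides) == 0:
        return all_bouts, strides.assign(reason=pd.Series(dtype=str))
    for (pid, day), group in strides.groupby(["participant_id", "day"], sort=True):
        valid, log = filter_strides(group, cfg)
        logs.append(log)
        all_bouts.extend(
            segment_bouts(valid, cfg, participant_id=pid, day=int(day),
                          bout_id_start=len(all_bouts))
        )
    return all_bouts, pd.concat(logs, ignore_index=True)


def bouts_to_frame(bouts: list[WalkingBout]) -> pd.DataFrame:
    """Flat summary table (one row per bout) for CSV export."""
    return pd.DataFrame(
        {
            "bout_id": [b.bout_id for b in bouts],
            "participant_id": [b.participant_id for b in bouts],
            "day": [b.day for b in bouts],
            "start_s": [b.start_s for b in bouts],
            "end_s": [b.end_s for b in bouts],
            "duration_s": [b.duration_s for b in bouts],
            "n_strides": [b.n_strides for b in bouts],
            "context": [b.context for b in bouts],
            "p_indoor": [b.p_indoor for b in bouts],
            "evidence_coverage": [b.evidence_coverage for b in bouts],
        }
    )
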