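"""Shared fixtures: small synthetic cohorts and hand-built stride tables."""

import numpy as np
import pandas as pd
import pytest

import gaitcontext as gc


def make_strides(starts, durations, lengths, participant_id="P1", day=0):
    """Stride table from parallel lists."""
    return pd.DataFrame(
        {
            "participant_id": participant_id,
            "day": day,
            "stride_start_s": np.asarray(starts, dtype=float),
            "stride_duration_s": np.asarray(durations, dtype=float),
            "stride_length_m": np.asarray(lengths, dtype=float),
        }
    )


def contiguous_bout(start, n, duration=1.0, speed=1.0, participant_id="P1", day=0):
    """n contiguous strides (gap 0) at constant duration and speed."""
    starts = start + duration * np.arange(n)
    return make_strides(
        starts, [duration] * n, [speed * duration] * n, participant_id, day
    )


@pytest.fixture(scope="session")
def small_cohort():
    """2+2 participants x 2 days, default settings; session-cached."""
    spec = gc.CohortSpec(n_pwp=2, n_control=2, n_days=2, seed=7)
    return gc.generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort_bouts(small_cohort):
    bouts, rejected = gc.segment_participant_days(
        small_cohort.strides, gc.BoutConfig()
    )
    assert len(rejected) == 0
    return bouts


def bout_truth_lookup(truth):
    """Map (participant_id, start_s) -> planted bout row."""
    return {
        (r.participant_id, r.start_s): r
        for r in truth.bouts.itertuples()
    }
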