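"""Slow-phase recovery across a designated march break.

Recovery of heart rate and body core temperature is scored over the third
break by default: the value at the last marching minute before break onset
minus the value at the tenth break minute, with the onset minute counted as
break minute 1.  The fast (30-120 s) vagal phase of HR recovery is outside
this window by design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .segmentation import MARCH, BREAK, ActivitySegment, break_segments


@dataclass
class RecoveryMetrics:
    soldier_id: str
    break_index: int                  # 1-based
    available: bool
    reason: str | None = None         # why unavailable
    hr_pre: float | None = None       # bpm, last MARCH minute before onset
    hr_b10: float | None = None       # bpm at the 10th break minute
    hr_recovery: float | None = None  # hr_pre - hr_b10
    bct_pre: float | None = None
    bct_b10: float | None = None
    bct_recovery: float | None = None


def _unavailable(soldier_id: str, break_index: int, reason: str) -> RecoveryMetrics:
    return RecoveryMetrics(soldier_id, break_index, available=False, reason=reason)


def recovery_at_break(
    minutes: pd.DataFrame,
    segments: list[ActivitySegment],
    soldier_id: str = "",
    break_index: int = 3,
    break_minute: int = 10,
    onset_counts_as: int = 1,
) -> RecoveryMetrics:
    """HR and BCT recovery deltas across the ``break_index``-th break.

    The pre-break value is read at the last MARCH-classified minute before
    the break onset; the break value at break minute ``break_minute`` where
    the onset minute is break minute ``onset_counts_as``.  A missing break,
    a break too short to contain that minute, or missing boundary data mark
    the metric unavailable rather than raising.
    """
    breaks = break_segments(segments)
    if break_index < 1 or break_index > len(breaks):
        return _unavailable(soldier_id, break_index, f"series has only {len(breaks)} breaks")
    seg = breaks[break_index - 1]
    offset = break_minute - onset_counts_as
    if seg.duration <= offset:
        return _unavailable(soldier_id, break_index,
                            f"break lasts {seg.duration} min, shorter than break minute {break_minute}")
    b10_idx = seg.start_minute + offset

    states = minutes["state"].to_numpy(dtype=object)
    pre_idx = None
    for i in range(seg.start_minute - 1, -1, -1):
        if states[i] == MARCH:
            pre_idx = i
            break
    if pre_idx is None:
        return _unavailable(soldier_id, break_index, "no marching minute precedes the break")

    row_pre = minutes.iloc[pre_idx]
    row_b10 = minutes.iloc[b10_idx]
    hr_pre, hr_b10 = float(row_pre["hr"]), float(row_b10["hr"])
    bct_pre, bct_b10 = float(row_pre["bct"]), float(row_b10["bct"])
    if any(math.isnan(v) for v in (hr_pre, hr_b10, bct_pre, bct_b10)):
        return _unavailable(soldier_id, break_index, "missing sensor data at a boundary minute")
    return RecoveryMetrics(
        soldier_id=soldier_id,
        break_index=break_index,
        available=True,
        hr_pre=hr_pre,
        hr_b10=hr_b10,
        hr_recovery=hr_pre - hr_b10,
        bct_pre=bct_pre,
        bct_b10=bct_b10,
        bct_recovery=bct_pre - bct_b10,
    )
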