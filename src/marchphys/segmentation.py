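"""Minute-level binning and march/break segmentation.

All streams are processed on a 1-minute grid anchored at the march start.
A minute with mean step frequency above 1 Hz is marching; at or below 1 Hz
it is a break (marching strictly requires exceedance, so exactly 1.0 Hz
falls to BREAK).  Maximal same-state runs form activity segments; runs
shorter than a debounce window are absorbed by their surroundings so that a
momentary stop does not open a break.  The onset of a break is the first
minute of a BREAK segment — the minute step frequency dropped below 1 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MARCH = "MARCH"
BREAK = "BREAK"
MISSING = "MISSING"

MINUTE_COLUMNS = ["minute_index", "clock", "hr", "bct", "hacc", "step_freq"]


@dataclass(frozen=True)
class ActivitySegment:
    """A maximal run of same-state minutes, half-open [start_minute, end_minute)."""

    state: str
    start_minute: int
    end_minute: int

    @property
    def duration(self) -> int:
        return self.end_minute - self.start_minute

    def __post_init__(self) -> None:
        if self.end_minute <= self.start_minute:
            raise ValueError("segment must span at least one minute")


def bin_to_minutes(samples: pd.DataFrame, start: pd.Timestamp | None = None, n_minutes: int | None = None) -> pd.DataFrame:
    """Aggregate timestamped sensor samples onto the 1-minute protocol grid.

    ``samples`` needs a time-sorted ``timestamp`` column plus any of ``hr``,
    ``bct``, ``step_freq`` (averaged per minute) and ``hacc`` (summed to
    counts per minute).  Minutes without samples are emitted with NaNs and
    will be labelled MISSING by :func:`classify_states`.
    """
    ts = pd.to_datetime(samples["timestamp"])
    if not ts.is_monotonic_increasing:
        raise ValueError("samples must be sorted by timestamp")
    if start is None:
        start = ts.iloc[0].floor("min")
    start = pd.Timestamp(start)
    minute = ((ts - start).dt.total_seconds() // 60).astype(int)
    if n_minutes is None:
        n_minutes = int(minute.max()) + 1
    df = samples.assign(minute_index=minute)
    df = df[(df["minute_index"] >= 0) & (df["minute_index"] < n_minutes)]
    agg = {}
    for col in ("hr", "bct", "step_freq"):
        if col in df:
            agg[col] = df.groupby("minute_index")[col].mean()
    if "hacc" in df:
        agg["hacc"] = df.groupby("minute_index")["hacc"].sum(min_count=1)
    grid = pd.DataFrame(index=pd.RangeIndex(n_minutes, name="minute_index"))
    for col, series in agg.items():
        grid[col] = series
    grid = grid.reset_index()
    grid.insert(1, "clock", start + pd.to_timedelta(grid["minute_index"], unit="min"))
    for col in ("hr", "bct", "hacc", "step_freq"):
        if col not in grid:
            grid[col] = np.nan
    return grid[MINUTE_COLUMNS]


def _nan_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of consecutive NaNs."""
    isna = np.isnan(values)
    runs, start = [], None
    for i, flag in enumerate(isna):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(values)))
    return runs


def interpolate_gaps(minutes: pd.DataFrame, max_gap_min: int = 5,
                     columns: tuple[str, ...] = ("hr", "bct", "hacc", "step_freq")) -> pd.DataFrame:
    """Linearly fill interior sensor gaps of at most ``max_gap_min`` minutes.

    Longer gaps, and gaps touching either end of the series, stay NaN and the
    affected minutes remain MISSING.
    """
    out = minutes.copy()
    n = len(out)
    for col in columns:
        if col not in out:
            continue
        vals = out[col].to_numpy(dtype=float, copy=True)
        filled = pd.Series(vals).interpolate(method="linear", limit_area="inside").to_numpy()
        for lo, hi in _nan_runs(vals):
            if hi - lo <= max_gap_min and lo > 0 and hi < n:
                vals[lo:hi] = filled[lo:hi]
        out[col] = vals
    return out


def classify_states(minutes: pd.DataFrame, threshold_hz: float = 1.0) -> pd.DataFrame:
    """Label each minute MARCH (step frequency > threshold), BREAK (<=) or MISSING."""
    out = minutes.copy()
    sf = out["step_freq"].to_numpy(dtype=float)
    state = np.where(sf > threshold_hz, MARCH, BREAK).astype(object)
    state[np.isnan(sf)] = MISSING
    out["state"] = state
    return out


def _runs_of(states: np.ndarray) -> list[ActivitySegment]:
    runs: list[ActivitySegment] = []
    start = 0
    for i in range(1, len(states) + 1):
        if i == len(states) or states[i] != states[start]:
            runs.append(ActivitySegment(str(states[start]), start, i))
            start = i
    return runs


def extract_segments(minutes: pd.DataFrame, min_segment_min: int = 3) -> list[ActivitySegment]:
    """Maximal MARCH/BREAK runs after debouncing sub-threshold blips.

    Within each block of contiguous non-missing minutes, any run shorter than
    ``min_segment_min`` is reassigned to the state of its longer neighbour
    (its only neighbour at block edges) until every surviving run meets the
    minimum; a block consisting of a single short run is kept as is.  MISSING
    minutes separate blocks and are never part of a segment.
    """
    states = minutes["state"].to_numpy(dtype=object)
    if (states == MISSING).all():
        raise ValueError("cannot segment an all-missing series")
    segments: list[ActivitySegment] = []
    availability = np.where(states == MISSING, MISSING, "DATA")
    for block in _runs_of(availability):
        if block.state == MISSING:
            continue
        sub = _runs_of(states[block.start_minute:block.end_minute])
        sub = [ActivitySegment(s.state, s.start_minute + block.start_minute,
                               s.end_minute + block.start_minute) for s in sub]
        segments.extend(_debounce(sub, min_segment_min))
    return segments


def _debounce(runs: list[ActivitySegment], min_len: int) -> list[ActivitySegment]:
    runs = list(runs)
    while len(runs) > 1:
        short = [i for i, r in enumerate(runs) if r.duration < min_len]
        if not short:
            break
        i = min(short, key=lambda j: runs[j].duration)
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i + 1 < len(runs) else None
        absorb = max((r for r in (left, right) if r is not None), key=lambda r: r.duration)
        runs[i] = ActivitySegment(absorb.state, runs[i].start_minute, runs[i].end_minute)
        runs = _merge_adjacent(runs)
    return runs


def _merge_adjacent(runs: list[ActivitySegment]) -> list[ActivitySegment]:
    merged = [runs[0]]
    for r in runs[1:]:
        if r.state == merged[-1].state and r.start_minute == merged[-1].end_minute:
            merged[-1] = ActivitySegment(r.state, merged[-1].start_minute, r.end_minute)
        else:
            merged.append(r)
    return merged


def break_segments(segments: list[ActivitySegment]) -> list[ActivitySegment]:
    """The BREAK segments in timeline order (break onsets are their first minutes)."""
    return [s for s in segments if s.state == BREAK]


def missing_fraction(minutes: pd.DataFrame) -> float:
    states = minutes["state"].to_numpy(dtype=object)
    return float((states == MISSING).mean())
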