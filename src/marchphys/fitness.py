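"""Cardiorespiratory fitness from the progressive endurance run.

VO2peak is predicted from the peak velocity of a progressive outdoor run
(start 8.5 km/h, +0.5 km/h every 200 m, to voluntary exhaustion) through the
linear regression VO2peak = 2.309 * v_peak + 16.549 (mL·kg⁻¹·min⁻¹), and the
cohort is split into lower/middle/higher fitness thirds (LT/MT/HT).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

TERTILES = ("LT", "MT", "HT")

VO2PEAK_SLOPE = 2.309
VO2PEAK_INTERCEPT = 16.549


class PeakVelocity(NamedTuple):
    velocity_kmh: float
    completed: bool  # False when not even the first stage was finished


def peak_velocity_from_run(
    completed_distance_m: float,
    start_speed_kmh: float = 8.5,
    increment_kmh: float = 0.5,
    stage_length_m: float = 200.0,
) -> PeakVelocity:
    """Speed of the last fully completed stage of the progressive run.

    A partial final stage does not count.  A distance shorter than one stage
    returns the start speed flagged ``completed=False``.
    """
    if completed_distance_m < 0:
        raise ValueError(f"completed distance must be non-negative, got {completed_distance_m}")
    n_stages = int(completed_distance_m // stage_length_m)
    if n_stages < 1:
        return PeakVelocity(start_speed_kmh, False)
    return PeakVelocity(start_speed_kmh + increment_kmh * (n_stages - 1), True)


def estimate_vo2peak(
    peak_velocity_kmh: float,
    slope: float = VO2PEAK_SLOPE,
    intercept: float = VO2PEAK_INTERCEPT,
) -> float:
    """Predict VO2peak (mL·kg⁻¹·min⁻¹) from run peak velocity (km/h)."""
    v = np.asarray(peak_velocity_kmh, dtype=float)
    if np.any(v < 0):
        raise ValueError("peak velocity must be non-negative")
    out = slope * v + intercept
    return float(out) if out.ndim == 0 else out


def velocity_from_vo2peak(
    vo2peak: float,
    slope: float = VO2PEAK_SLOPE,
    intercept: float = VO2PEAK_INTERCEPT,
    start_speed_kmh: float = 8.5,
    increment_kmh: float = 0.5,
    quantize: bool = True,
) -> float:
    """Invert the regression; optionally snap to the run protocol's 0.5 km/h stages.

    Quantization rounds to the nearest reachable stage speed (>= start speed),
    mirroring that the field test only resolves peak velocity in 0.5 km/h steps.
    """
    v = (np.asarray(vo2peak, dtype=float) - intercept) / slope
    if quantize:
        stages = np.round((v - start_speed_kmh) / increment_kmh)
        v = start_speed_kmh + increment_kmh * np.maximum(stages, 0)
    return float(v) if v.ndim == 0 else v


def assign_tertiles(roster: pd.DataFrame, vo2_col: str = "vo2peak") -> pd.DataFrame:
    """Allocate soldiers to fitness thirds by ascending VO2peak.

    Group sizes are balanced (differ by at most one, extras assigned to the
    outer groups first), ties broken by stable input order, so every LT
    member's VO2peak <= every MT member's <= every HT member's.  Returns a
    copy of the roster with a ``tertile`` column.
    """
    n = len(roster)
    if n < 3:
        raise ValueError(f"tertile allocation needs at least 3 soldiers, got {n}")
    if roster[vo2_col].isna().any():
        raise ValueError("tertile allocation requires vo2peak for every soldier")
    base, rem = divmod(n, 3)
    sizes = [base, base, base]
    if rem >= 1:
        sizes[0] += 1
    if rem == 2:
        sizes[2] += 1
    order = np.argsort(roster[vo2_col].to_numpy(), kind="stable")
    labels = np.empty(n, dtype=object)
    bounds = np.cumsum([0] + sizes)
    for tert, lo, hi in zip(TERTILES, bounds[:-1], bounds[1:]):
        labels[order[lo:hi]] = tert
    out = roster.copy()
    out["tertile"] = labels
    return out
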