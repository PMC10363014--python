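"""Energy expenditure, intake and deficit accounting.

Per-minute physical-activity energy expenditure (PAEE) is predicted from
heart rate above rest (HRaR = HR - supine resting HR) with a state-specific
linear model, in kJ/min converted to kcal/min by the 4.1868 divisor:

    marching:  PAEE = (HRaR * 0.7810 - 15.9337) / 4.1868
    break:     PAEE = (HRaR * 0.4840 + H-Acc[cpm] * 0.0010 - 4.7964) / 4.1868

Negative predictions are clamped to zero — expenditure cannot be negative.
Resting energy expenditure (REE) uses the Mifflin-St Jeor men's equation
(10 W + 6.25 H - 5 A + 5, kcal/day) prorated over the protocol window, and
total energy expenditure is TEE = PAEE + prorated REE.  The energy deficit
is intake - TEE; the percentage of TEE replaced by intake is reported as a
half-up-rounded integer.  Work-rate intensity follows Howley's occupational
classification, with "very heavy" meaning a mean PAEE rate strictly above
7.5 kcal/min (31.4 kJ/min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segmentation import MARCH, BREAK, MISSING

KCAL_PER_KJ = 4.1868
MARCH_COEF = (0.7810, 15.9337)           # (HRaR slope, offset) in kJ/min
BREAK_COEF = (0.4840, 0.0010, 4.7964)    # (HRaR slope, hacc slope, offset)
MINUTES_PER_DAY = 1440

#: Howley occupational work-rate classes as (lower bound kcal/min, label);
#: a rate qualifies for the highest class whose bound it strictly exceeds.
INTENSITY_CLASSES = (
    (7.5, "very heavy"),
    (5.0, "heavy"),
    (2.5, "moderate"),
    (0.0, "light"),
)


@dataclass
class EnergySummary:
    """Per-soldier energy bookkeeping over the march protocol."""

    soldier_id: str
    ree_daily: float          # kcal/day
    ree_march: float          # kcal over the protocol window
    paee_total: float         # kcal
    tee: float                # kcal
    mean_paee_rate: float     # kcal/min over non-missing minutes
    intensity_class: str
    protocol_minutes: int
    intake: float | None = None   # kcal
    deficit: float | None = None  # intake - tee
    pct_replaced: int | None = None


def round_half_up(x: float) -> int:
    """Round to the nearest integer with ties going up (not banker's)."""
    return int(math.floor(x + 0.5))


def ree_daily(weight_kg: float, height_cm: float, age_y: float) -> float:
    """Mifflin-St Jeor resting energy expenditure for men (kcal/day)."""
    for name, v in (("weight", weight_kg), ("height", height_cm), ("age", age_y)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing anthropometric: {name}")
    return 10.0 * weight_kg + 6.25 * height_cm - 5.0 * age_y + 5.0


def paee_minute(hr: float, resting_hr: float, hacc: float, state: str, clamp: bool = True) -> float:
    """PAEE (kcal/min) for one minute from HR, resting HR and hip counts.

    HRaR may be negative at rest; the break model also uses the
    accelerometer counts.  With ``clamp`` (default) negative predictions
    return 0.
    """
    if resting_hr is None or (isinstance(resting_hr, float) and math.isnan(resting_hr)):
        raise ValueError("resting heart rate is required")
    hrar = hr - resting_hr
    if state == MARCH:
        kj = hrar * MARCH_COEF[0] - MARCH_COEF[1]
    elif state == BREAK:
        kj = hrar * BREAK_COEF[0] + hacc * BREAK_COEF[1] - BREAK_COEF[2]
    else:
        raise ValueError(f"cannot compute PAEE for state {state!r}")
    kcal = kj / KCAL_PER_KJ
    return max(kcal, 0.0) if clamp else kcal


def paee_series(minutes: pd.DataFrame, resting_hr: float, clamp: bool = True) -> np.ndarray:
    """Vectorised per-minute PAEE (kcal/min); NaN at MISSING minutes."""
    if resting_hr is None or math.isnan(resting_hr):
        raise ValueError("resting heart rate is required")
    hr = minutes["hr"].to_numpy(dtype=float)
    hacc = minutes["hacc"].to_numpy(dtype=float)
    state = minutes["state"].to_numpy(dtype=object)
    hrar = hr - resting_hr
    kj = np.where(
        state == MARCH,
        hrar * MARCH_COEF[0] - MARCH_COEF[1],
        hrar * BREAK_COEF[0] + hacc * BREAK_COEF[1] - BREAK_COEF[2],
    )
    kcal = kj / KCAL_PER_KJ
    if clamp:
        kcal = np.maximum(kcal, 0.0)
    kcal = np.where(state == MISSING, np.nan, kcal)
    return kcal


def classify_intensity(mean_paee_rate: float, very_heavy_kcal_min: float = 7.5) -> str:
    """Howley occupational class of a mean work rate (kcal/min).

    "very heavy" requires strictly exceeding the threshold (default
    7.5 kcal/min); exactly at a bound falls to the class below.
    """
    if mean_paee_rate < 0:
        raise ValueError("work rate must be non-negative")
    classes = ((very_heavy_kcal_min, "very heavy"),) + INTENSITY_CLASSES[1:]
    for bound, label in classes:
        if mean_paee_rate > bound:
            return label
    return INTENSITY_CLASSES[-1][1]


def total_energy(
    minutes: pd.DataFrame,
    soldier_id: str,
    weight_kg: float,
    height_cm: float,
    age_y: float,
    resting_hr: float,
    clamp: bool = True,
    very_heavy_kcal_min: float = 7.5,
) -> EnergySummary:
    """TEE = summed per-minute PAEE + REE prorated over the protocol window.

    MISSING minutes contribute no PAEE and are excluded from the protocol
    length used for proration.
    """
    if len(minutes) == 0:
        raise ValueError("empty minute series")
    per_min = paee_series(minutes, resting_hr, clamp=clamp)
    valid = ~np.isnan(per_min)
    protocol_minutes = int(valid.sum())
    if protocol_minutes == 0:
        raise ValueError("no non-missing minutes in series")
    paee_total = float(np.nansum(per_min))
    ree_day = ree_daily(weight_kg, height_cm, age_y)
    ree_march = ree_day * protocol_minutes / MINUTES_PER_DAY
    rate = paee_total / protocol_minutes
    return EnergySummary(
        soldier_id=soldier_id,
        ree_daily=ree_day,
        ree_march=ree_march,
        paee_total=paee_total,
        tee=paee_total + ree_march,
        mean_paee_rate=rate,
        intensity_class=classify_intensity(rate, very_heavy_kcal_min),
        protocol_minutes=protocol_minutes,
    )


def energy_balance(summary: EnergySummary, diary_kcal: "pd.Series | np.ndarray | list[float]") -> EnergySummary:
    """Complete a summary with intake, deficit and percent of TEE replaced."""
    kcal = np.asarray(diary_kcal, dtype=float)
    if kcal.size and (kcal < 0).any():
        raise ValueError("diary entries must have non-negative kcal")
    intake = float(kcal.sum()) if kcal.size else 0.0
    summary.intake = intake
    summary.deficit = intake - summary.tee
    summary.pct_replaced = round_half_up(100.0 * intake / summary.tee)
    return summary
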