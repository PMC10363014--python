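"""Configuration objects for the synthetic cohort and the analysis pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import yaml


def _check_mean_sd(name: str, value: Sequence[float]) -> tuple[float, float]:
    mean, sd = float(value[0]), float(value[1])
    if sd < 0:
        raise ValueError(f"{name}: sd must be non-negative, got {sd}")
    return (mean, sd)


@dataclass
class CohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the field study the package models: a 475-minute
    (7:55 h) loaded march starting at 15:11 with four breaks of 19-24
    minutes, an all-male cohort of 55 starters with VO2peak 54.2 +/- 7.9
    mL·kg⁻¹·min⁻¹, step frequency above 1 Hz while marching and below 1 Hz
    at breaks, and ad-libitum energy intake far below expenditure
    (22/26/36% of TEE by fitness tertile).
    """

    n_soldiers: int = 55
    seed: int = 0

    # anthropometrics and fitness: (mean, sd), truncated to physical range
    age_mean_sd: tuple[float, float] = (20.3, 1.3)
    height_mean_sd: tuple[float, float] = (178.5, 7.0)
    weight_mean_sd: tuple[float, float] = (74.8, 9.8)
    vo2peak_mean_sd: tuple[float, float] = (54.2, 7.9)
    resting_hr_mean_sd: tuple[float, float] = (60.0, 3.0)
    age_range: tuple[float, float] = (18.0, 30.0)
    height_range: tuple[float, float] = (158.0, 200.0)
    weight_range: tuple[float, float] = (55.0, 115.0)
    vo2peak_range: tuple[float, float] = (25.0, 80.0)
    resting_hr_range: tuple[float, float] = (40.0, 90.0)
    # supine resting HR is lower in fitter soldiers: bpm per (mL/kg/min)
    resting_hr_vo2_slope: float = -0.35

    # timeline
    march_start_clock: str = "15:11"
    march_end_clock: str = "23:06"  # 475 minutes later
    break_starts: tuple[int, ...] = (90, 185, 280, 375)
    break_durations_min: tuple[int, ...] = (21, 21, 22, 20)

    # step frequency (Hz); march values truncated > 1, break values < 1
    march_step_freq_hz: tuple[float, float] = (1.8, 0.10)
    break_step_freq_hz: tuple[float, float] = (0.5, 0.15)

    # energetics truth model
    march_paee_kcal_min: float = 9.9      # cohort-mean marching rate at reference load
    march_paee_soldier_sd: float = 0.5    # between-soldier spread (kcal/min)
    march_paee_minute_sd: float = 0.30    # within-soldier minute-to-minute wiggle
    carried_load_kg: float = 23.2         # clothing 5.7 + pack/rifle 17.6
    break_hrar_equilibrium_bpm: float = 40.0
    break_hr_tau_min: float = 2.0

    # sensor noise
    hr_noise_sd: float = 3.0

    # hip accelerometer (counts per minute)
    march_hacc_cpm: tuple[float, float] = (6000.0, 800.0)
    break_hacc_cpm: tuple[float, float] = (300.0, 150.0)

    # body core temperature
    bct_start_c: tuple[float, float] = (37.3, 0.2)
    bct_time_constant_min: float = 40.0       # heating
    bct_cooling_time_constant_min: float = 240.0
    bct_gain_c: float = 2.8                   # steady state = 37.0 + gain * rel. intensity
    bct_base_c: float = 37.0
    bct_noise_sd: float = 0.0

    # intake, questionnaire, dropout
    intake_fraction_by_tertile: tuple[float, float, float] = (0.22, 0.26, 0.36)
    intake_noise_frac: float = 0.04
    motivation_mean_by_tertile: tuple[float, float, float] = (5.0, 6.0, 7.5)
    motivation_sd: float = 1.5
    pain_pre_mean_by_tertile: tuple[float, float, float] = (2.6, 2.2, 1.8)
    pain_pre_sd: float = 1.3
    pain_post_mean: float = 7.0
    pain_post_sd: float = 1.5
    dropout_hazard_per_pain_point: float = 0.06

    def __post_init__(self) -> None:
        if self.n_soldiers <= 0:
            raise ValueError(f"n_soldiers must be positive, got {self.n_soldiers}")
        for name in ("age", "height", "weight", "vo2peak", "resting_hr"):
            key = f"{name}_mean_sd"
            setattr(self, key, _check_mean_sd(key, getattr(self, key)))
        if len(self.break_starts) != len(self.break_durations_min):
            raise ValueError("break_starts and break_durations_min must have equal length")
        total = self.total_minutes
        if total <= sum(self.break_durations_min):
            raise ValueError("march timeline shorter than the total break time")
        prev_end = 0
        for start, dur in zip(self.break_starts, self.break_durations_min):
            if dur < 10:
                raise ValueError(f"break duration {dur} < 10 min; recovery metrics need a 10th break minute")
            if start <= prev_end:
                raise ValueError("break windows must not overlap and must follow each other")
            if start + dur >= total:
                raise ValueError("break window extends past the march end")
            prev_end = start + dur
        for f in self.intake_fraction_by_tertile:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"intake fraction {f} outside [0, 1]")
        if not 0.0 <= self.dropout_hazard_per_pain_point <= 1.0:
            raise ValueError("dropout hazard must be a probability")

    @property
    def total_minutes(self) -> int:
        h0, m0 = (int(x) for x in self.march_start_clock.split(":"))
        h1, m1 = (int(x) for x in self.march_end_clock.split(":"))
        minutes = (h1 * 60 + m1) - (h0 * 60 + m0)
        if minutes <= 0:
            minutes += 24 * 60  # march crossing midnight
        return minutes

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        # YAML lists arrive as lists; dataclass tuples tolerate sequences
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class AnalysisConfig:
    """Tunables of the analysis pipeline (all defaults mirror the protocol)."""

    # fitness
    run_start_speed_kmh: float = 8.5
    run_increment_kmh: float = 0.5
    run_stage_length_m: float = 200.0
    vo2peak_slope: float = 2.309
    vo2peak_intercept: float = 16.549

    # segmentation
    step_freq_threshold_hz: float = 1.0
    debounce_min: int = 3
    interpolation_gap_max_min: int = 5
    max_missing_fraction: float = 0.10

    # energetics
    clamp_negative_paee: bool = True
    howley_very_heavy_kcal_min: float = 7.5
    paee_march_coef: tuple[float, float] = (0.7810, 15.9337)
    paee_break_coef: tuple[float, float, float] = (0.4840, 0.0010, 4.7964)
    kcal_per_kj: float = 4.1868  # divisor converting kJ/min to kcal/min

    # recovery
    recovery_break_index: int = 3
    recovery_break_minute: int = 10
    recovery_onset_counts_as: int = 1

    # statistics
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
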