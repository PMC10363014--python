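"""End-to-end cohort analysis: fitness, segmentation, energetics, recovery, stats.

The pipeline mirrors a field-study workflow: tertiles are allocated on the
full starting roster, but per-soldier physiology is analyzed only for
completers — dropouts and soldiers with too many missing minutes are
excluded, because their truncated streams are not comparable with complete
ones.  Group comparisons gate each outcome through Shapiro-Wilk (ordinal
questionnaire scores are forced onto the nonparametric track) and the
dropout-by-tertile association uses the exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .energetics import EnergySummary, energy_balance, total_energy
from .fitness import TERTILES, assign_tertiles, estimate_vo2peak
from .recovery import RecoveryMetrics, recovery_at_break
from .segmentation import (
    MISSING,
    classify_states,
    extract_segments,
    interpolate_gaps,
    missing_fraction,
)
from .stats import CategoricalAssociation, GroupComparison, categorical_association, compare_three_groups

#: outcomes always analyzed nonparametrically (ordinal 1-10 scales)
ORDINAL_VARIABLES = ("motivation_pre", "pain_pre", "pain_post")


@dataclass
class AnalysisResult:
    roster: pd.DataFrame                       # full roster with vo2peak + tertile
    excluded: dict[str, str]                   # id -> reason
    per_soldier: pd.DataFrame                  # one row per completer, all outcomes
    segments: dict[str, list]                  # id -> ActivitySegment list
    comparisons: dict[str, GroupComparison] = field(default_factory=dict)
    dropout_association: CategoricalAssociation | None = None
    dropout_table: pd.DataFrame | None = None


def soldier_energy_summary(
    minutes: pd.DataFrame,
    profile: pd.Series,
    diary_kcal,
    config: AnalysisConfig = AnalysisConfig(),
) -> EnergySummary:
    """Classified-minutes -> completed EnergySummary for one soldier."""
    summary = total_energy(
        minutes,
        soldier_id=str(profile["id"]),
        weight_kg=profile["weight_kg"],
        height_cm=profile["height_cm"],
        age_y=profile["age_y"],
        resting_hr=profile["resting_hr_bpm"],
        clamp=config.clamp_negative_paee,
        very_heavy_kcal_min=config.howley_very_heavy_kcal_min,
    )
    return energy_balance(summary, diary_kcal)


def _prepare_minutes(minutes: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    filled = interpolate_gaps(minutes, config.interpolation_gap_max_min)
    return classify_states(filled, config.step_freq_threshold_hz)


def analyze_dataset(
    dataset=None,
    *,
    roster: pd.DataFrame | None = None,
    minutes: dict[str, pd.DataFrame] | None = None,
    diary: pd.DataFrame | None = None,
    questionnaire: pd.DataFrame | None = None,
    config: AnalysisConfig | None = None,
    stats_seed: int = 0,
) -> AnalysisResult:
    """Run the full analysis on a dataset (synthetic or loaded from disk)."""
    if dataset is not None:
        roster, minutes, diary, questionnaire = (
            dataset.roster, dataset.minutes, dataset.diary, dataset.questionnaire,
        )
    if roster is None or minutes is None:
        raise ValueError("roster and minutes are required")
    config = config or AnalysisConfig()

    roster = roster.copy()
    roster["vo2peak"] = estimate_vo2peak(
        roster["run_peak_velocity_kmh"].to_numpy(),
        slope=config.vo2peak_slope,
        intercept=config.vo2peak_intercept,
    )
    roster["bmi"] = roster["weight_kg"] / (roster["height_cm"] / 100.0) ** 2
    roster = assign_tertiles(roster)

    quest = questionnaire.set_index("id") if questionnaire is not None else None
    diary_by_id = diary.groupby("id")["kcal"] if diary is not None and len(diary) else None

    excluded: dict[str, str] = {}
    rows = []
    segments_by_id: dict[str, list] = {}
    for _, profile in roster.iterrows():
        sid = profile["id"]
        if quest is not None and sid in quest.index and int(quest.loc[sid, "dropout"]):
            excluded[sid] = "ended marching early"
            continue
        if sid not in minutes:
            excluded[sid] = "no sensor stream"
            continue
        mins = _prepare_minutes(minutes[sid], config)
        if missing_fraction(mins) > config.max_missing_fraction:
            excluded[sid] = "too many missing minutes"
            continue
        segs = extract_segments(mins, config.debounce_min)
        segments_by_id[sid] = segs

        kcal = diary_by_id.get_group(sid) if diary_by_id is not None and sid in diary_by_id.groups else []
        energy = soldier_energy_summary(mins, profile, kcal, config)
        rec = recovery_at_break(
            mins, segs, soldier_id=sid,
            break_index=config.recovery_break_index,
            break_minute=config.recovery_break_minute,
            onset_counts_as=config.recovery_onset_counts_as,
        )
        valid = mins["state"].to_numpy(dtype=object) != MISSING
        hr = mins["hr"].to_numpy(dtype=float)[valid]
        bct = mins["bct"].to_numpy(dtype=float)[valid]
        row = {
            "id": sid,
            "tertile": profile["tertile"],
            "vo2peak": profile["vo2peak"],
            "hr_mean": hr.mean(),
            "hr_peak": hr.max(),
            "bct_start": bct[0],
            "bct_mean": bct.mean(),
            "bct_peak": bct.max(),
            "hr_recovery": rec.hr_recovery if rec.available else np.nan,
            "bct_recovery": rec.bct_recovery if rec.available else np.nan,
            "ree_daily": energy.ree_daily,
            "ree_march": energy.ree_march,
            "paee": energy.paee_total,
            "tee": energy.tee,
            "mean_paee_rate": energy.mean_paee_rate,
            "intensity_class": energy.intensity_class,
            "intake": energy.intake,
            "deficit": energy.deficit,
            "pct_replaced": energy.pct_replaced,
            "protocol_minutes": energy.protocol_minutes,
        }
        if quest is not None and sid in quest.index:
            for col in ORDINAL_VARIABLES:
                if col in quest.columns:
                    row[col] = float(quest.loc[sid, col])
        rows.append(row)

    per_soldier = pd.DataFrame(rows)
    result = AnalysisResult(roster=roster, excluded=excluded, per_soldier=per_soldier, segments=segments_by_id)
    if len(per_soldier) == 0:
        return result

    continuous = [
        "hr_mean", "hr_peak", "hr_recovery", "bct_start", "bct_mean", "bct_peak",
        "bct_recovery", "tee", "paee", "intake", "deficit",
    ]
    have_three = per_soldier["tertile"].nunique() == 3
    if have_three:
        order = per_soldier["tertile"].map({t: i for i, t in enumerate(TERTILES)})
        sorted_df = per_soldier.loc[order.sort_values(kind="stable").index]
        for var in continuous + [v for v in ORDINAL_VARIABLES if v in per_soldier]:
            sub = sorted_df[["tertile", var]].dropna()
            if sub["tertile"].nunique() < 3 or sub[var].size < 9:
                continue
            force = "nonparametric" if var in ORDINAL_VARIABLES else None
            result.comparisons[var] = compare_three_groups(
                sub[var], sub["tertile"], variable=var, alpha=config.alpha, force=force,
            )

    if quest is not None and "dropout" in quest.columns:
        merged = roster.set_index("id").join(quest[["dropout"]])
        table = (
            merged.groupby("tertile")["dropout"]
            .agg(dropped="sum", completed=lambda s: int((1 - s).sum()))
            .reindex(list(TERTILES))
        )
        result.dropout_table = table
        counts = table.to_numpy(dtype=int)
        if counts.sum() > 0 and (counts.sum(axis=1) > 0).all():
            result.dropout_association = categorical_association(counts, seed=stats_seed)
    return result
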