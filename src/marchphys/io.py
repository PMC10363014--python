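"""Plain-text dataset and result persistence (CSV / JSON / markdown)."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .pipeline import AnalysisResult
from .synthetic import GroundTruth, SyntheticDataset
from .config import CohortConfig

_MINUTE_COLS = {
    "minute_index": "minute_index",
    "clock": "clock_iso8601",
    "hr": "hr_bpm",
    "bct": "bct_c",
    "hacc": "hacc_cpm",
    "step_freq": "step_freq_hz",
}
_COHORT_COLS = ["id", "age_y", "height_cm", "weight_kg", "resting_hr_bpm", "run_peak_velocity_kmh"]


def write_dataset(dataset: SyntheticDataset, outdir: str | Path, write_truth: bool = True) -> Path:
    """Write cohort.csv, minutes/<id>.csv, diary.csv, questionnaire.csv, truth.json."""
    out = Path(outdir)
    (out / "minutes").mkdir(parents=True, exist_ok=True)
    dataset.roster[_COHORT_COLS].to_csv(out / "cohort.csv", index=False)
    for sid, mins in dataset.minutes.items():
        df = mins.rename(columns=_MINUTE_COLS)
        df["clock_iso8601"] = pd.to_datetime(df["clock_iso8601"]).dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(out / "minutes" / f"{sid}.csv", index=False)
    dataset.diary.to_csv(out / "diary.csv", index=False)
    dataset.questionnaire.to_csv(out / "questionnaire.csv", index=False)
    if write_truth:
        truth = dataset.truth
        payload = {
            "state_template": truth.state_template.tolist(),
            "tertile": truth.tertile,
            "tee": truth.tee,
            "intake": truth.intake,
            "dropout": truth.dropout,
            "paee": {k: np.round(v, 6).tolist() for k, v in truth.paee.items()},
            "states": {k: v.tolist() for k, v in truth.states.items()},
        }
        (out / "truth.json").write_text(json.dumps(payload))
    return out


def read_dataset(datadir: str | Path):
    """Load a dataset directory back into pipeline inputs.

    Returns (roster, minutes, diary, questionnaire); diary/questionnaire are
    None when absent.
    """
    d = Path(datadir)
    roster = pd.read_csv(d / "cohort.csv")
    inverse = {v: k for k, v in _MINUTE_COLS.items()}
    minutes = {}
    for path in sorted((d / "minutes").glob("*.csv")):
        df = pd.read_csv(path).rename(columns=inverse)
        df["clock"] = pd.to_datetime(df["clock"])
        minutes[path.stem] = df
    diary = pd.read_csv(d / "diary.csv") if (d / "diary.csv").exists() else None
    quest = pd.read_csv(d / "questionnaire.csv") if (d / "questionnaire.csv").exists() else None
    return roster, minutes, diary, quest


def write_analysis(result: AnalysisResult, outdir: str | Path) -> Path:
    """Write energy/recovery tables, per-soldier segments and the group report."""
    out = Path(outdir)
    (out / "segments").mkdir(parents=True, exist_ok=True)
    result.per_soldier.to_csv(out / "per_soldier.csv", index=False)
    energy_cols = ["id", "tertile", "ree_daily", "ree_march", "paee", "tee",
                   "mean_paee_rate", "intensity_class", "intake", "deficit",
                   "pct_replaced", "protocol_minutes"]
    result.per_soldier[[c for c in energy_cols if c in result.per_soldier]].to_csv(
        out / "energy_summary.csv", index=False)
    rec_cols = ["id", "tertile", "hr_recovery", "bct_recovery"]
    result.per_soldier[[c for c in rec_cols if c in result.per_soldier]].to_csv(
        out / "recovery.csv", index=False)
    for sid, segs in result.segments.items():
        pd.DataFrame(
            [(s.state, s.start_minute, s.end_minute) for s in segs],
            columns=["state", "start_minute", "end_minute"],
        ).to_csv(out / "segments" / f"{sid}.csv", index=False)

    report = {
        "n_analyzed": int(len(result.per_soldier)),
        "excluded": result.excluded,
        "comparisons": {
            name: {
                "test_used": c.test_used,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "omnibus_significant": c.omnibus_significant,
                "posthoc": [asdict(p) for p in c.posthoc],
                "descriptives": c.descriptives,
                "notes": c.notes,
            }
            for name, c in result.comparisons.items()
        },
    }
    if result.dropout_association is not None:
        report["dropout"] = {
            "table": result.dropout_table.to_dict(),
            "p_value": result.dropout_association.p_value,
            "method": result.dropout_association.method,
        }
    (out / "group_report.json").write_text(json.dumps(report, indent=2, default=float))
    (out / "group_report.md").write_text(format_report(result))
    return out


def format_report(result: AnalysisResult) -> str:
    """Human-readable group-comparison table (descriptives + omnibus + post-hoc)."""
    lines = [
        "# Fitness-group comparison",
        "",
        f"Soldiers analyzed: {len(result.per_soldier)} "
        f"(excluded: {len(result.excluded)})",
        "",
        "| variable | test | LT | MT | HT | statistic | P | post-hoc |",
        "|---|---|---|---|---|---|---|---|",
    ]
    for name, c in result.comparisons.items():
        cells = []
        for g in ("LT", "MT", "HT"):
            d = c.descriptives.get(g)
            if d is None:
                cells.append("-")
            elif c.test_used == "ANOVA":
                cells.append(f"{d['mean']:.1f} ± {d['sd']:.1f}")
            else:
                cells.append(f"{d['median']:.1f}; {d['iqr']:.1f}")
        sig = "; ".join(f"{p.pair[0]} vs {p.pair[1]} (p={p.adjusted_p:.3f})"
                        for p in c.posthoc if p.significant) or "-"
        lines.append(
            f"| {name} | {c.test_used} | {cells[0]} | {cells[1]} | {cells[2]} | "
            f"{c.statistic:.2f} | {c.p_value:.3f} | {sig} |"
        )
    if result.dropout_association is not None:
        lines += [
            "",
            f"Dropout by tertile: exact test p = {result.dropout_association.p_value:.3f} "
            f"({result.dropout_association.method}).",
        ]
    return "\n".join(lines) + "\n"
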