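"""Scoring and filtering of the four behavioral assays.

Novel object recognition (NOR) and Y-maze probe recognition and spatial
memory; accelerating rotarod and balance beam probe motor coordination.
The preference scores and the trial exclusion rules are applied exactly as
published for blast-injury cohorts:

* NOR preference = (time3/time4) / (time1/time2): day-2 novel-over-familiar
  exploration corrected for any unequal object preference on day 1.
* Y-maze preference = time in "new" arm / time in "familiar" arm.
* Exclusions: NOR trials with < 10 s total day-2 object exploration;
  Y-maze trials with < 15 s in either scored arm, fewer than 7 total arm
  visits, or camera tracking lost for > 10% of the trial.
* Motor trials are averaged per subject-day (mean ± SEM), then per group.
  Rotarod run times are reported raw; other assays are conventionally
  expressed relative to pre-injury baseline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NORTrial",
    "YMazeTrial",
    "MotorTrial",
    "filter_trials",
    "nor_preference",
    "ymaze_preference",
    "aggregate_motor",
    "UndefinedScoreError",
]

NOR_MIN_EXPLORATION_S = 10.0
YMAZE_MIN_ARM_S = 15.0
YMAZE_MIN_VISITS = 7
MAX_TRACKING_LOSS = 0.10


class UndefinedScoreError(ZeroDivisionError):
    """A preference score's denominator is zero."""


@dataclass
class NORTrial:
    """Exploration seconds: objects #1/#2 on day 1, #3 (novel)/#2 on day 2."""

    subject_id: str
    time1: float
    time2: float
    time3: float
    time4: float
    tracking_loss_frac: float = 0.0


@dataclass
class YMazeTrial:
    subject_id: str
    time_new: float
    time_familiar: float
    visits_total: int
    tracking_loss_frac: float = 0.0


@dataclass
class MotorTrial:
    subject_id: str
    day_index: int
    kind: str  # "rotarod" (run time, s) or "beam" (mean velocity)
    value: float


def filter_trials(trials, assay: str):
    """Apply the published exclusion rules for ``assay``.

    Returns ``(included, exclusion_log)``; the log holds
    ``(subject_id, rule)`` pairs.  Trials are never mutated.
    """
    included, log = [], []
    if assay == "nor":
        for t in trials:
            if t.time3 + t.time4 < NOR_MIN_EXPLORATION_S:
                log.append((t.subject_id, "day2_exploration_below_10s"))
            else:
                included.append(t)
    elif assay == "ymaze":
        for t in trials:
            if t.time_new < YMAZE_MIN_ARM_S or t.time_familiar < YMAZE_MIN_ARM_S:
                log.append((t.subject_id, "arm_time_below_15s"))
            elif t.visits_total < YMAZE_MIN_VISITS:
                log.append((t.subject_id, "fewer_than_7_visits"))
            elif t.tracking_loss_frac > MAX_TRACKING_LOSS:
                log.append((t.subject_id, "tracking_loss_above_10pct"))
            else:
                included.append(t)
    elif assay in ("rotarod", "beam"):
        included = list(trials)
    else:
        raise ValueError(f"unknown assay {assay!r}")
    return included, log


def nor_preference(t: NORTrial) -> float:
    """Day-1-bias-corrected novel-object preference."""
    if t.time1 <= 0 or t.time2 <= 0 or t.time4 <= 0:
        raise UndefinedScoreError("NOR preference undefined for zero times")
    return (t.time3 / t.time4) / (t.time1 / t.time2)


def ymaze_preference(t: YMazeTrial) -> float:
    """New-arm over familiar-arm time ratio."""
    if t.time_familiar <= 0:
        raise UndefinedScoreError("Y-maze preference undefined: familiar time 0")
    return t.time_new / t.time_familiar


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0


def aggregate_motor(trials, baseline_means: dict | None = None) -> pd.DataFrame:
    """Mean ± SEM per subject-day, then group mean ± SEM per day and kind.

    Rows with ``level="subject_day"`` carry each subject's daily average;
    ``level="group_day"`` averages those across subjects; ``level="group"``
    pools across days.  A single trial reports SEM 0.

    ``baseline_means`` (subject_id -> pre-injury mean) switches values to
    relative units for every kind except rotarod, which is conventionally
    reported as raw run time.
    """
    if not trials:
        raise ValueError("aggregate_motor needs at least one trial")
    df = pd.DataFrame(
        [
            {"subject_id": t.subject_id, "day_index": t.day_index,
             "kind": t.kind, "value": t.value}
            for t in trials
        ]
    )
    if baseline_means:
        from .staging import normalize_to_baseline

        norm = df["kind"] != "rotarod"
        df.loc[norm, "value"] = [
            normalize_to_baseline(v, [baseline_means[s]])
            for v, s in zip(df.loc[norm, "value"], df.loc[norm, "subject_id"])
        ]
    rows = []
    per_subj = (
        df.groupby(["kind", "day_index", "subject_id"])["value"]
        .agg(["mean", list])
        .reset_index()
    )
    for _, r in per_subj.iterrows():
        vals = np.asarray(r["list"], dtype=float)
        rows.append(
            {"level": "subject_day", "kind": r["kind"], "day_index": r["day_index"],
             "subject_id": r["subject_id"], "mean": float(r["mean"]), "sem": _sem(vals),
             "n": len(vals)}
        )
    subj_day = pd.DataFrame(rows)
    for (kind, day), grp in subj_day.groupby(["kind", "day_index"]):
        vals = grp["mean"].to_numpy(float)
        rows.append(
            {"level": "group_day", "kind": kind, "day_index": day, "subject_id": "",
             "mean": float(vals.mean()), "sem": _sem(vals), "n": len(vals)}
        )
    for kind, grp in subj_day.groupby("kind"):
        vals = grp["mean"].to_numpy(float)
        rows.append(
            {"level": "group", "kind": kind, "day_index": -1, "subject_id": "",
             "mean": float(vals.mean()), "sem": _sem(vals), "n": len(vals)}
        )
    return pd.DataFrame(rows)
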