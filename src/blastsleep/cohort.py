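"""Delta/alpha-ratio scoring and HD/LD cohort stratification.

A dominance of delta over alpha power is a classical EEG severity marker
after brain injury.  Each subject is scored by the delta/alpha band-power
ratio in each of the three vigilance states (NREM, REM, AWAKE),
baseline-normalized to the subject's own pre-injury record; injured
subjects are then split into a high-delta/alpha (HD) and a low-delta/alpha
(LD) group by 2-means clustering of the 3-dimensional normalized scores,
with controls included in the clustering.  Cluster identity is converted
into labels by the control-majority rule: injured subjects sharing a
cluster with most controls are LD, the rest HD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .signal_io import Hypnogram

__all__ = [
    "DeltaAlphaScore",
    "CohortAssignment",
    "delta_alpha_scores",
    "stratify_kmeans",
    "DegenerateClusterWarning",
]

SCORE_STATES = ("NREM", "REM", "AWAKE")


class DegenerateClusterWarning(UserWarning):
    pass


@dataclass
class DeltaAlphaScore:
    """Per-state delta/alpha ratios, raw and in baseline relative units."""

    subject_id: str
    day_index: int = 0
    raw: dict = field(default_factory=dict)  # state -> ratio (post)
    baseline: dict = field(default_factory=dict)  # state -> ratio (pre)
    normalized: dict = field(default_factory=dict)  # state -> post/pre

    def complete(self) -> bool:
        return all(np.isfinite(self.normalized.get(s, np.nan)) for s in SCORE_STATES)

    def vector(self) -> np.ndarray:
        return np.array([self.normalized[s] for s in SCORE_STATES], dtype=float)


@dataclass
class CohortAssignment:
    labels: dict  # subject_id -> CONTROL / SBI-HD / SBI-LD
    centroids: np.ndarray  # (2, 3) in score space
    separation: float  # centroid distance
    plot_radius: float  # 90% of the centroid distance, for QC scatter plots
    degenerate: bool = False


def _state_ratio(bp: pd.DataFrame, h: Hypnogram, state: str) -> float:
    mask = np.asarray(h.labels == state)
    if len(mask) < len(bp):
        mask = np.pad(mask, (0, len(bp) - len(mask)))
    sub = bp[mask[: len(bp)]].dropna(subset=["delta", "alpha"])
    if not len(sub):
        return float("nan")
    alpha = float(sub["alpha"].mean())
    if alpha <= 0:
        return float("nan")
    return float(sub["delta"].mean()) / alpha


def delta_alpha_scores(
    bp: pd.DataFrame,
    h: Hypnogram,
    baseline_bp: pd.DataFrame,
    baseline_h: Hypnogram,
    subject_id: str = "subj",
    day_index: int = 0,
) -> DeltaAlphaScore:
    """Per-state mean-delta over mean-alpha, normalized to baseline.

    A state absent from either record leaves that state's score NaN; a
    subject with any missing state is excluded from clustering.
    """
    score = DeltaAlphaScore(subject_id=subject_id, day_index=day_index)
    for state in SCORE_STATES:
        post = _state_ratio(bp, h, state)
        pre = _state_ratio(baseline_bp, baseline_h, state)
        score.raw[state] = post
        score.baseline[state] = pre
        score.normalized[state] = post / pre if np.isfinite(post) and pre > 0 else float("nan")
    return score


def stratify_kmeans(
    scores: list[DeltaAlphaScore],
    group_of: dict,
    seed: int = 0,
    n_restarts: int = 50,
) -> CohortAssignment:
    """2-means over normalized (NREM, REM, AWAKE) scores of all subjects.

    ``group_of`` maps subject_id to ``"control"`` or ``"injured"``.
    Injured subjects in the cluster holding the majority of controls are
    labeled SBI-LD, the others SBI-HD; a control-majority tie is broken by
    calling the lower-mean-ratio cluster LD.  Identical scores for every
    subject are a degenerate case: all injured become SBI-LD with a
    warning.
    """
    usable = [s for s in scores if s.complete()]
    injured = [s for s in usable if group_of[s.subject_id] == "injured"]
    controls = [s for s in usable if group_of[s.subject_id] == "control"]
    if len(injured) < 2:
        raise ValueError("need at least two injured subjects with complete scores")

    x = np.vstack([s.vector() for s in usable])
    labels = {s.subject_id: "CONTROL" for s in controls}

    if np.allclose(x, x[0]):
        warnings.warn(
            "all subjects have identical scores; labeling all injured SBI-LD",
            DegenerateClusterWarning,
        )
        labels.update({s.subject_id: "SBI-LD" for s in injured})
        c = np.vstack([x[0], x[0]])
        return CohortAssignment(labels, c, 0.0, 0.0, degenerate=True)

    km = KMeans(
        n_clusters=2, init="random", n_init=n_restarts, random_state=int(seed) % (2**32)
    ).fit(x)
    assign = dict(zip((s.subject_id for s in usable), km.labels_))

    ctrl_counts = np.bincount([assign[s.subject_id] for s in controls], minlength=2)
    if ctrl_counts[0] == ctrl_counts[1]:
        # tie (possibly no controls): the lower-mean-score cluster is LD
        ld_cluster = int(np.argmin(km.cluster_centers_.mean(axis=1)))
    else:
        ld_cluster = int(np.argmax(ctrl_counts))

    for s in injured:
        labels[s.subject_id] = "SBI-LD" if assign[s.subject_id] == ld_cluster else "SBI-HD"

    sep = float(np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1]))
    return CohortAssignment(
        labels=labels,
        centroids=km.cluster_centers_,
        separation=sep,
        plot_radius=0.9 * sep,
    )


def assignment_frame(assignment: CohortAssignment, scores: list[DeltaAlphaScore]) -> pd.DataFrame:
    """CSV-ready view: subject, label and the three state scores."""
    by_id = {s.subject_id: s for s in scores}
    rows = []
    for sid, lab in sorted(assignment.labels.items()):
        s = by_id.get(sid)
        rows.append(
            {
                "subject_id": sid,
                "label": lab,
                "score_NREM": s.normalized.get("NREM") if s else np.nan,
                "score_REM": s.normalized.get("REM") if s else np.nan,
                "score_AWAKE": s.normalized.get("AWAKE") if s else np.nan,
            }
        )
    return pd.DataFrame(rows)
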