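"""Rule-based sleep/wake staging of 5-s epochs.

Epochs are classified with a strict precedence of band-power ratio rules:

1. AWAKE  — gamma/delta above its cut **and** EMG power above its cut
   (waking cortex: low delta, high gamma, high muscle tone);
2. NREM   — delta/EMG above its cut (delta-dominant, atonic);
3. REM    — theta/(delta · EMG) above its cut (theta-dominant, atonic);
4. UNDETECTABLE otherwise, and for epochs with missing band powers.

Every cut is calibrated on a window of the record (default the first hour)
as ``median + k · s_med`` of the relevant ratio, where ``s_med`` is the RMS
deviation from the median (:func:`blastsleep.spectral.robust_scale`):
k = 0.5 for gamma/delta, 1.0 for delta/EMG, and a configurable k
(default 1.0) for the REM ratio, whose cut is a judgment call in practice.
The AWAKE EMG cut is the calibration-window median EMG power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .signal_io import Hypnogram, SignalRecord, STATES
from .spectral import SpectralParams, band_power_pipeline, robust_scale

__all__ = [
    "Thresholds",
    "calibrate_thresholds",
    "classify_epochs",
    "stage_record",
    "state_metrics",
    "normalize_to_baseline",
    "staging_qc",
]

#: Relative floor applied to ratio denominators, as a fraction of the
#: record median of that quantity, to keep all-zero epochs finite.
DENOM_FLOOR_REL = 1e-12


@dataclass
class Thresholds:
    """Calibrated staging cuts (all in the band-power ratio units)."""

    awake_gd: float
    awake_emg: float
    nrem_de: float
    rem_tde: float
    calibration_window_s: float = 3600.0
    rem_k: float = 1.0


def _floored(x: np.ndarray) -> np.ndarray:
    """Denominator guard: floor at DENOM_FLOOR_REL × record median (>0)."""
    finite = x[np.isfinite(x)]
    med = np.median(finite) if finite.size else 0.0
    floor = DENOM_FLOOR_REL * med if med > 0 else DENOM_FLOOR_REL
    return np.maximum(x, floor)


def _ratios(bp: pd.DataFrame) -> dict[str, np.ndarray]:
    delta = bp["delta"].to_numpy(float)
    gamma = bp["gamma"].to_numpy(float)
    theta = bp["theta"].to_numpy(float)
    emg = bp["emg_power"].to_numpy(float)
    d = _floored(delta)
    e = _floored(emg)
    return {
        "gd": gamma / d,
        "de": delta / e,
        "tde": theta / (d * e),
        "emg": emg,
    }


def calibrate_thresholds(
    bp: pd.DataFrame,
    window_s: float = 3600.0,
    rem_k: float = 1.0,
    start_s: float = 0.0,
) -> Thresholds:
    """Derive staging cuts from a ``window_s`` calibration window.

    The window starts at ``start_s`` (default: the first hour of the
    record); a fixed reference hour elsewhere in the record is selected by
    passing its offset.
    """
    span = bp["start_s"].max() + np.diff(bp["start_s"]).mean() if len(bp) > 1 else 0.0
    if start_s + window_s > span + 1e-9:
        raise ValueError(
            f"calibration window [{start_s}, {start_s + window_s}) s exceeds "
            f"the record ({span:.0f} s)"
        )
    cal = bp[(bp["start_s"] >= start_s) & (bp["start_s"] < start_s + window_s)]
    cal = cal.dropna(subset=["delta", "theta", "gamma", "emg_power"])
    r = _ratios(cal)
    m_gd, s_gd = robust_scale(r["gd"])
    m_de, s_de = robust_scale(r["de"])
    m_tde, s_tde = robust_scale(r["tde"])
    return Thresholds(
        awake_gd=m_gd + 0.5 * s_gd,
        awake_emg=float(np.median(r["emg"])),
        nrem_de=m_de + 1.0 * s_de,
        rem_tde=m_tde + rem_k * s_tde,
        calibration_window_s=window_s,
        rem_k=rem_k,
    )


def classify_epochs(
    bp: pd.DataFrame, th: Thresholds, t0: str = "09:00", epoch_len_s: float = 5.0
) -> Hypnogram:
    """Label every epoch of ``bp`` by the precedence rules."""
    r = _ratios(bp)
    missing = (
        bp[["delta", "theta", "gamma", "emg_power"]].isna().any(axis=1).to_numpy()
    )
    labels = np.full(len(bp), "UNDETECTABLE", dtype="U12")
    awake = (r["gd"] > th.awake_gd) & (r["emg"] > th.awake_emg)
    nrem = ~awake & (r["de"] > th.nrem_de)
    rem = ~awake & ~nrem & (r["tde"] > th.rem_tde)
    labels[awake] = "AWAKE"
    labels[nrem] = "NREM"
    labels[rem] = "REM"
    labels[missing] = "UNDETECTABLE"
    return Hypnogram(labels=labels, epoch_len_s=epoch_len_s, t0=t0)


def stage_record(
    record: SignalRecord,
    epoch_len_s: float = 5.0,
    calibration_window_s: float = 3600.0,
    rem_k: float = 1.0,
    thresholds: Thresholds | None = None,
    eeg_params: SpectralParams | None = None,
    emg_params: SpectralParams | None = None,
) -> tuple[Hypnogram, pd.DataFrame, Thresholds]:
    """Full staging pipeline: band powers → calibration → classification."""
    bp = band_power_pipeline(
        record, epoch_len_s=epoch_len_s, eeg_params=eeg_params, emg_params=emg_params
    )
    if thresholds is None:
        thresholds = calibrate_thresholds(bp, calibration_window_s, rem_k=rem_k)
    h = classify_epochs(bp, thresholds, t0=record.t0, epoch_len_s=epoch_len_s)
    return h, bp, thresholds


# ---------------------------------------------------------------------------
# State metrics
# ---------------------------------------------------------------------------


def _episodes(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Maximal runs of identical labels as (start_epoch, length, label)."""
    if len(labels) == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(labels)]])
    return [(int(s), int(e - s), str(labels[s])) for s, e in zip(starts, ends)]


def state_metrics(h: Hypnogram) -> pd.DataFrame:
    """Per-state totals, episode counts and mean episode durations.

    Rows are emitted per (day, phase) cell and for the marginals
    (``phase="all"``, ``day=-1`` meaning the whole record).  An episode
    crossing a phase or day boundary is split at the boundary, so the
    conservation identity — per-state totals summing to the record
    duration — holds exactly within every cell.
    """
    from .signal_io import _parse_clock, DARK_START_MIN, DARK_END_MIN

    n = h.n_epochs
    starts = h.epoch_starts()
    minutes = (_parse_clock(h.t0) + starts / 60.0) % (24 * 60)
    dark = (minutes >= DARK_START_MIN) & (minutes < DARK_END_MIN)
    day = (starts // 86400).astype(int)

    rows = []
    cells = [("all", -1, np.ones(n, dtype=bool))]
    for d in np.unique(day):
        cells.append(("all", int(d), day == d))
        cells.append(("dark", int(d), (day == d) & dark))
        cells.append(("light", int(d), (day == d) & ~dark))
    cells.append(("dark", -1, dark))
    cells.append(("light", -1, ~dark))

    for phase, d, mask in cells:
        if not mask.any():
            continue
        sub = h.labels[mask]
        eps = _episodes(sub)
        for state in STATES:
            lens = [l for _, l, lab in eps if lab == state]
            total = float(sum(lens)) * h.epoch_len_s
            count = len(lens)
            rows.append(
                {
                    "state": state,
                    "phase": phase,
                    "day": d,
                    "total_s": total,
                    "episode_count": count,
                    "mean_episode_s": total / count if count else np.nan,
                }
            )
    return pd.DataFrame(rows)


def normalize_to_baseline(value: float, baseline_values) -> float:
    """Express ``value`` in relative units of the pre-injury baseline mean."""
    base = float(np.mean(np.asarray(baseline_values, dtype=float)))
    if base == 0.0:
        raise ZeroDivisionError("baseline mean is zero; cannot normalize")
    return float(value) / base


def staging_qc(h: Hypnogram) -> dict:
    """Automated QC summary replacing manual trace inspection.

    Reports the fraction of UNDETECTABLE epochs, per-state fractions and
    the epoch-to-epoch transition matrix.
    """
    n = max(h.n_epochs, 1)
    fractions = {s: float(np.mean(h.labels == s)) for s in STATES}
    trans: dict[str, dict[str, int]] = {a: {b: 0 for b in STATES} for a in STATES}
    for a, b in zip(h.labels[:-1], h.labels[1:]):
        trans[str(a)][str(b)] += 1
    return {
        "n_epochs": h.n_epochs,
        "epoch_len_s": h.epoch_len_s,
        "fraction_undetectable": fractions["UNDETECTABLE"],
        "state_fractions": fractions,
        "transition_counts": trans,
    }
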