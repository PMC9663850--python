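"""Reading and writing the file formats the pipeline touches.

Signals travel either as EDF (European Data Format, 16-bit) for
interoperability with acquisition exports, or as a two-column CSV with a JSON
sidecar, which is the canonical fixture format.  Hypnograms, spindle events
and scalar metrics are plain CSV/TSV tables.

The EDF codec here is deliberately minimal: one data record per second,
two channels at a common sampling rate, labels identifying EEG and EMG by
case-insensitive substring (telemetry export labels vary).
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalRecord",
    "Hypnogram",
    "STATES",
    "read_signal_record",
    "write_signal_record",
    "read_hypnogram",
    "write_hypnogram",
    "write_spindle_table",
    "read_spindle_table",
    "write_metrics_table",
    "FormatError",
    "ConsistencyError",
]

#: Valid hypnogram labels, in precedence order of the staging rules.
STATES = ("AWAKE", "NREM", "REM", "UNDETECTABLE")

#: Dark (active) phase for the reverse-cycle housing: lights off 9:00-21:00.
DARK_START_MIN = 9 * 60
DARK_END_MIN = 21 * 60


class FormatError(ValueError):
    """File content does not conform to the expected format."""


class ConsistencyError(ValueError):
    """Internally inconsistent inputs (mismatched lengths, rates...)."""


def _parse_clock(t0: str) -> int:
    """``"HH:MM"`` -> minutes past midnight."""
    try:
        hh, mm = t0.split(":")
        minutes = int(hh) * 60 + int(mm)
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"bad clock time {t0!r}, expected HH:MM") from exc
    if not 0 <= minutes < 24 * 60:
        raise FormatError(f"clock time {t0!r} out of range")
    return minutes


@dataclass
class SignalRecord:
    """Synchronized EEG/EMG traces for one subject-day.

    Amplitudes are in microvolts, ``fs`` in Hz.  ``t0`` is the wall-clock
    time of the first sample as ``"HH:MM"``; the housing is on a reverse
    light cycle, so 9:00-21:00 is the dark (active) phase and 21:00-9:00
    the light phase.
    """

    eeg: np.ndarray
    emg: np.ndarray
    fs: float = 500.0
    t0: str = "09:00"
    subject_id: str = "subj"
    day_index: int = 0

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg)
        self.emg = np.asarray(self.emg)
        if self.eeg.ndim != 1 or self.emg.ndim != 1:
            raise ConsistencyError("eeg and emg must be 1-D")
        if len(self.eeg) != len(self.emg):
            raise ConsistencyError(
                f"eeg length {len(self.eeg)} != emg length {len(self.emg)}"
            )
        if self.fs <= 0:
            raise ConsistencyError("fs must be positive")
        _parse_clock(self.t0)

    @property
    def n_samples(self) -> int:
        return len(self.eeg)

    @property
    def duration_s(self) -> float:
        return len(self.eeg) / self.fs

    def is_dark(self, t_s: np.ndarray | float) -> np.ndarray | bool:
        """Dark-phase mask for offsets ``t_s`` (seconds from record start)."""
        minutes = (_parse_clock(self.t0) + np.asarray(t_s) / 60.0) % (24 * 60)
        return (minutes >= DARK_START_MIN) & (minutes < DARK_END_MIN)


@dataclass
class Hypnogram:
    """Per-epoch sleep/wake labels in fixed-length epochs (default 5 s)."""

    labels: np.ndarray
    epoch_len_s: float = 5.0
    t0: str = "09:00"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U12")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise FormatError(f"unknown hypnogram labels: {sorted(bad)}")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def epoch_starts(self) -> np.ndarray:
        return np.arange(self.n_epochs) * self.epoch_len_s


# ---------------------------------------------------------------------------
# CSV signal format: <path>.csv (time_s, eeg_uv, emg_uv) + <path>.json sidecar
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_signal_csv(rec: SignalRecord, path: Path) -> None:
    t = np.arange(rec.n_samples) / rec.fs
    df = pd.DataFrame({"time_s": t, "eeg_uv": rec.eeg, "emg_uv": rec.emg})
    df.to_csv(path, index=False, float_format="%.6f")
    meta = {
        "fs": rec.fs,
        "t0": rec.t0,
        "subject_id": rec.subject_id,
        "day_index": rec.day_index,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_signal_csv(path: Path) -> SignalRecord:
    df = pd.read_csv(path)
    for col in ("time_s", "eeg_uv", "emg_uv"):
        if col not in df.columns:
            raise FormatError(f"signal CSV missing column {col!r}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar metadata {sidecar}")
    meta = json.loads(sidecar.read_text())
    return SignalRecord(
        eeg=df["eeg_uv"].to_numpy(float),
        emg=df["emg_uv"].to_numpy(float),
        fs=float(meta["fs"]),
        t0=str(meta.get("t0", "09:00")),
        subject_id=str(meta.get("subject_id", "subj")),
        day_index=int(meta.get("day_index", 0)),
    )


# ---------------------------------------------------------------------------
# Minimal EDF (16-bit) codec: 1-s data records, two channels, common rate.
# ---------------------------------------------------------------------------

_EDF_HDR = 256  # bytes, fixed part
_PHYS_DIG_SPAN = 65535  # -32768 .. 32767


def _edf_field(value: str, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def _fmt8(v: float) -> str:
    """Shortest float representation that fits an 8-char EDF field."""
    for prec in range(7, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def _write_signal_edf(rec: SignalRecord, path: Path) -> None:
    if rec.fs != round(rec.fs):
        raise FormatError("EDF writer requires an integer sampling rate")
    spr = int(rec.fs)  # samples per 1-s data record
    n_rec = rec.n_samples // spr
    if n_rec * spr != rec.n_samples:
        raise ConsistencyError(
            "EDF writer requires a whole number of seconds of signal"
        )
    minutes = _parse_clock(rec.t0)
    start = _dt.time(minutes // 60, minutes % 60)
    channels = [("EEG", np.asarray(rec.eeg, float)), ("EMG", np.asarray(rec.emg, float))]

    header = b"".join(
        [
            _edf_field("0", 8),  # version
            _edf_field(rec.subject_id, 80),  # patient id
            _edf_field(f"day {rec.day_index}", 80),  # recording id
            _edf_field("01.01.00", 8),  # start date (placeholder)
            _edf_field(start.strftime("%H.%M.%S"), 8),
            _edf_field(str(_EDF_HDR * (1 + len(channels))), 8),
            _edf_field("", 44),  # reserved
            _edf_field(str(n_rec), 8),
            _edf_field("1", 8),  # record duration, s
            _edf_field(str(len(channels)), 4),
        ]
    )

    phys: list[tuple[float, float]] = []
    for _, x in channels:
        lo = float(np.min(x, initial=0.0))
        hi = float(np.max(x, initial=0.0))
        if hi <= lo:  # constant channel: force a non-degenerate span
            hi = lo + 1.0
        phys.append((lo, hi))

    def col(fmt: str, width: int, values: Sequence) -> bytes:
        return b"".join(_edf_field(fmt.format(v), width) for v in values)

    phys = [(float(_fmt8(lo)), float(_fmt8(hi))) for lo, hi in phys]
    header += col("{}", 16, [name for name, _ in channels])  # label
    header += col("{}", 80, ["" for _ in channels])  # transducer
    header += col("{}", 8, ["uV" for _ in channels])
    header += col("{}", 8, [_fmt8(lo) for lo, _ in phys])  # physical min
    header += col("{}", 8, [_fmt8(hi) for _, hi in phys])  # physical max
    header += col("{}", 8, [-32768 for _ in channels])
    header += col("{}", 8, [32767 for _ in channels])
    header += col("{}", 80, ["" for _ in channels])  # prefiltering
    header += col("{}", 8, [spr for _ in channels])
    header += col("{}", 32, ["" for _ in channels])  # reserved

    digital = []
    for (_, x), (lo, hi) in zip(channels, phys):
        # phys already round-trips through the 8-char header representation
        gain = (hi - lo) / _PHYS_DIG_SPAN
        d = np.round((x - lo) / gain) - 32768
        digital.append(np.clip(d, -32768, 32767).astype("<i2"))

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_rec):
            for d in digital:
                fh.write(d[r * spr : (r + 1) * spr].tobytes())


def _read_edf_header(fh) -> dict:
    raw = fh.read(_EDF_HDR)
    if len(raw) < _EDF_HDR:
        raise FormatError("truncated EDF header")

    def f(off: int, width: int) -> str:
        return raw[off : off + width].decode("ascii", "replace").strip()

    try:
        n_rec = int(f(236, 8))
        rec_dur = float(f(244, 8))
        ns = int(f(252, 4))
    except ValueError as exc:
        raise FormatError("unreadable EDF header") from exc
    hdr = {
        "patient": f(8, 80),
        "recording": f(88, 80),
        "starttime": f(176, 8),
        "n_records": n_rec,
        "record_duration_s": rec_dur,
        "n_signals": ns,
    }
    sig_raw = fh.read(256 * ns)
    if len(sig_raw) < 256 * ns:
        raise FormatError("truncated EDF signal headers")

    # per-field arrays are concatenated: labels (16B each), transducer (80),
    # dimension (8), phys min/max (8/8), dig min/max (8/8), prefilter (80),
    # samples-per-record (8), reserved (32)
    def sf(block_off: int, width: int, i: int) -> str:
        off = block_off * ns + i * width
        return sig_raw[off : off + width].decode("ascii", "replace").strip()

    sigs = []
    for i in range(ns):
        try:
            sigs.append(
                {
                    "label": sf(0, 16, i),
                    "phys_min": float(sf(104, 8, i)),
                    "phys_max": float(sf(112, 8, i)),
                    "dig_min": int(sf(120, 8, i)),
                    "dig_max": int(sf(128, 8, i)),
                    "spr": int(sf(216, 8, i)),
                }
            )
        except ValueError as exc:
            raise FormatError("unreadable EDF signal header") from exc
    hdr["signals"] = sigs
    return hdr


def _read_signal_edf(path: Path) -> SignalRecord:
    with open(path, "rb") as fh:
        hdr = _read_edf_header(fh)
        sigs = hdr["signals"]
        data = np.frombuffer(fh.read(), dtype="<i2")

    def find(tag: str) -> int:
        for i, s in enumerate(sigs):
            if tag.lower() in s["label"].lower():
                return i
        raise FormatError(f"EDF file has no channel with {tag!r} in its label")

    i_eeg, i_emg = find("EEG"), find("EMG")
    if sigs[i_eeg]["spr"] != sigs[i_emg]["spr"] or hdr["record_duration_s"] <= 0:
        raise ConsistencyError("EEG and EMG must share one sampling rate")
    fs = sigs[i_eeg]["spr"] / hdr["record_duration_s"]

    sprs = [s["spr"] for s in sigs]
    per_rec = sum(sprs)
    n_rec = hdr["n_records"]
    if len(data) < n_rec * per_rec:
        raise ConsistencyError("EDF data shorter than header declares")
    data = data[: n_rec * per_rec].reshape(n_rec, per_rec)
    offsets = np.cumsum([0] + sprs)

    traces = {}
    for i in (i_eeg, i_emg):
        s = sigs[i]
        dig = data[:, offsets[i] : offsets[i + 1]].astype(float).ravel()
        gain = (s["phys_max"] - s["phys_min"]) / (s["dig_max"] - s["dig_min"])
        traces[i] = s["phys_min"] + (dig - s["dig_min"]) * gain

    tt = hdr["starttime"].replace(".", ":")[:5]
    try:
        _parse_clock(tt)
    except FormatError:
        tt = "09:00"
    day = 0
    if hdr["recording"].startswith("day "):
        try:
            day = int(hdr["recording"].split()[1])
        except (IndexError, ValueError):
            day = 0
    return SignalRecord(
        eeg=traces[i_eeg],
        emg=traces[i_emg],
        fs=fs,
        t0=tt,
        subject_id=hdr["patient"] or "subj",
        day_index=day,
    )


def write_signal_record(rec: SignalRecord, path, format: str | None = None) -> Path:
    """Write ``rec`` as CSV (+JSON sidecar) or EDF, inferred from the suffix."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "CSV":
        _write_signal_csv(rec, path)
    elif fmt == "EDF":
        _write_signal_edf(rec, path)
    else:
        raise FormatError(f"unknown signal format {fmt!r}")
    return path


def read_signal_record(path, format: str | None = None) -> SignalRecord:
    """Read a two-channel EEG/EMG record from CSV or EDF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).upper()
    if fmt == "CSV":
        return _read_signal_csv(path)
    if fmt == "EDF":
        return _read_signal_edf(path)
    raise FormatError(f"unknown signal format {fmt!r}")


# ---------------------------------------------------------------------------
# Hypnogram CSV
# ---------------------------------------------------------------------------


def write_hypnogram(h: Hypnogram, path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "epoch_index": np.arange(h.n_epochs),
            "start_s": h.epoch_starts(),
            "label": h.labels,
        }
    )
    with open(path, "w") as fh:
        fh.write(f"# epoch_len_s={h.epoch_len_s:.6f} t0={h.t0}\n")
        df.to_csv(fh, index=False, float_format="%.6f")
    return path


def read_hypnogram(path) -> Hypnogram:
    path = Path(path)
    epoch_len, t0 = 5.0, "09:00"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            for tok in first[1:].split():
                k, _, v = tok.partition("=")
                if k == "epoch_len_s":
                    epoch_len = float(v)
                elif k == "t0":
                    t0 = v
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if "label" not in df.columns:
        raise FormatError("hypnogram CSV missing 'label' column")
    labels = df["label"].astype(str).to_numpy()
    bad = set(labels) - set(STATES)
    if bad:
        raise FormatError(f"unknown hypnogram labels: {sorted(bad)}")
    return Hypnogram(labels=labels, epoch_len_s=epoch_len, t0=t0)


# ---------------------------------------------------------------------------
# Spindle TSV and metrics CSV
# ---------------------------------------------------------------------------

SPINDLE_COLUMNS = (
    "subject",
    "start_s",
    "end_s",
    "duration_s",
    "amplitude_uv",
    "cycles",
    "intra_freq_hz",
    "symmetry",
)


def write_spindle_table(spindles, path, subject: str = "subj") -> Path:
    """Write detected spindles as a TSV sorted by onset time."""
    path = Path(path)
    rows = [
        {
            "subject": getattr(s, "subject", subject),
            "start_s": s.start_s,
            "end_s": s.end_s,
            "duration_s": s.duration_s,
            "amplitude_uv": s.amplitude_uv,
            "cycles": s.cycles,
            "intra_freq_hz": s.intra_freq_hz,
            "symmetry": s.symmetry,
        }
        for s in spindles
    ]
    df = pd.DataFrame(rows, columns=SPINDLE_COLUMNS)
    if len(df):
        df = df.sort_values("start_s", kind="stable")
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_spindle_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SPINDLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"spindle table missing columns {sorted(missing)}")
    return df


def write_metrics_table(df: pd.DataFrame, path) -> Path:
    """Long-format metrics CSV: subject, day, state, metric, value, rel_units."""
    path = Path(path)
    cols = ["subject", "day", "state", "metric", "value", "rel_units"]
    out = df.reindex(columns=cols)
    out.to_csv(path, index=False, float_format="%.6f")
    return path
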