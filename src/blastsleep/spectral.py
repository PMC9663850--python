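"""Thomson multitaper spectrograms and per-epoch band powers.

The sliding multitaper spectrogram (DPSS tapers, time-bandwidth 3, 5 tapers,
5-s window moved in 0.1-s steps) is the spectral backbone of the whole
pipeline: stage classification, delta/alpha stratification and every
threshold derive from the band powers it yields.

Two paths are provided:

* :func:`multitaper_spectrogram` materializes the full time-frequency power
  matrix; use it for short traces and QC.
* :func:`band_power_pipeline` streams a full record in chunks and reduces
  each frame directly to the five canonical EEG bands plus broadband EMG
  power, which keeps a 24-h, 500-Hz record inside laptop memory and a few
  CPU-minutes.  Frame placement and taper math are identical to the full
  spectrogram, only the reduction is fused.

Band powers are *integrated* spectral density over the band (µV²), i.e.
density summed over the band's frequency bins times the bin width; a pure
sinusoid of RMS r inside a band therefore contributes ≈ r² to that band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.fft
from scipy.signal.windows import dpss

from .signal_io import SignalRecord

__all__ = [
    "BANDS",
    "SpectralParams",
    "Spectrogram",
    "multitaper_spectrogram",
    "epoch_band_powers",
    "band_power_pipeline",
    "robust_scale",
]

#: Canonical EEG frequency bands, half-open [low, high) Hz.  The shared
#: 8-Hz edge between theta and alpha is resolved in favour of alpha.
BANDS = {
    "delta": (2.0, 4.0),
    "theta": (5.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (16.0, 31.0),
    "gamma": (32.0, 100.0),
}

#: Broadband EMG integration range, Hz.
EMG_BAND = (5.0, 170.0)


@dataclass
class SpectralParams:
    """Sliding-window multitaper settings.

    ``time_bandwidth`` is the DPSS NW product; with the default window this
    gives a ±0.6 Hz analysis half-bandwidth.  ``band_limit`` clips the
    retained frequency axis (EEG default 0-150 Hz, EMG 5-170 Hz).
    """

    window_s: float = 5.0
    step_s: float = 0.1
    time_bandwidth: float = 3.0
    n_tapers: int = 5
    band_limit: tuple[float, float] = (0.0, 150.0)

    def __post_init__(self) -> None:
        if not self.window_s > self.step_s > 0:
            raise ValueError("need window_s > step_s > 0")
        if self.n_tapers < 1:
            raise ValueError("need at least one taper")

    @classmethod
    def emg_default(cls) -> "SpectralParams":
        return cls(band_limit=(5.0, 170.0))


@dataclass
class Spectrogram:
    """Frames × frequency power density matrix [µV²/Hz]."""

    times: np.ndarray  # frame centers, s
    freqs: np.ndarray  # Hz
    power: np.ndarray  # (n_frames, n_freqs), >= 0
    step_s: float
    window_s: float


def _tapers(n: int, params: SpectralParams) -> np.ndarray:
    """Unit-energy DPSS tapers, shape (n_tapers, n)."""
    t = dpss(n, params.time_bandwidth, Kmax=params.n_tapers)
    # scipy returns unit-norm tapers; enforce explicitly for the PSD scaling
    return t / np.sqrt((t**2).sum(axis=1, keepdims=True))


def _frame_geometry(n: int, fs: float, params: SpectralParams):
    win = int(round(params.window_s * fs))
    step = int(round(params.step_s * fs))
    if n < win:
        raise ValueError(
            f"signal of {n} samples shorter than one {params.window_s}-s window"
        )
    n_frames = (n - win) // step + 1
    return win, step, n_frames


def multitaper_spectrogram(
    signal: np.ndarray, fs: float, params: SpectralParams | None = None
) -> Spectrogram:
    """Average-over-tapers sliding power spectral density of ``signal``.

    One-sided density scaling: for white noise of variance σ² the mean
    density is 2σ²/fs across the interior of the band.
    """
    params = params or SpectralParams()
    x = np.asarray(signal, dtype=float)
    win, step, n_frames = _frame_geometry(len(x), fs, params)
    tapers = _tapers(win, params)

    frames = np.lib.stride_tricks.sliding_window_view(x, win)[::step][:n_frames]
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    keep = (freqs >= params.band_limit[0]) & (freqs <= params.band_limit[1])

    power = np.zeros((n_frames, int(keep.sum())))
    for tap in tapers:
        spec = scipy.fft.rfft(frames * tap, axis=1)[:, keep]
        power += spec.real**2 + spec.imag**2
    power *= 2.0 / (fs * params.n_tapers)
    # one-sided doubling does not apply at DC / Nyquist
    sel = np.flatnonzero(keep)
    if sel.size and freqs[sel[0]] == 0.0:
        power[:, 0] /= 2.0
    if sel.size and sel[-1] == len(freqs) - 1 and win % 2 == 0:
        power[:, -1] /= 2.0

    times = (np.arange(n_frames) * step + win / 2.0) / fs
    return Spectrogram(
        times=times,
        freqs=freqs[keep],
        power=power,
        step_s=step / fs,
        window_s=params.window_s,
    )


def _band_integral(spec: Spectrogram, lo: float, hi: float) -> np.ndarray:
    """Integrated density over [lo, hi) per frame, µV²."""
    df = spec.freqs[1] - spec.freqs[0] if len(spec.freqs) > 1 else 1.0
    sel = (spec.freqs >= lo) & (spec.freqs < hi)
    return spec.power[:, sel].sum(axis=1) * df


BAND_POWER_COLUMNS = (
    "epoch_index",
    "start_s",
    "delta",
    "theta",
    "alpha",
    "beta",
    "gamma",
    "emg_power",
)


def epoch_band_powers(
    eeg_spec: Spectrogram,
    emg_spec: Spectrogram,
    epoch_len_s: float = 5.0,
    duration_s: float | None = None,
) -> pd.DataFrame:
    """Reduce spectrograms to per-epoch band powers.

    A frame belongs to the non-overlapping epoch containing its center;
    band power is the frame-mean of the integrated density over the band.
    Epochs without any frame (edge effects, gaps) carry NaN.
    """
    if epoch_len_s <= eeg_spec.step_s:
        raise ValueError("epoch_len_s must exceed the spectrogram step")
    if duration_s is None:
        duration_s = max(
            eeg_spec.times[-1] + eeg_spec.window_s / 2,
            emg_spec.times[-1] + emg_spec.window_s / 2,
        )
    n_epochs = int(np.floor(duration_s / epoch_len_s))

    def reduce(spec: Spectrogram, series: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        idx = np.floor(spec.times / epoch_len_s).astype(int)
        ok = (idx >= 0) & (idx < n_epochs)
        counts = np.bincount(idx[ok], minlength=n_epochs).astype(float)
        out = {}
        for name, vals in series.items():
            tot = np.bincount(idx[ok], weights=vals[ok], minlength=n_epochs)
            with np.errstate(invalid="ignore"):
                out[name] = np.where(counts > 0, tot / np.maximum(counts, 1), np.nan)
        return out

    eeg_cols = reduce(
        eeg_spec, {b: _band_integral(eeg_spec, lo, hi) for b, (lo, hi) in BANDS.items()}
    )
    emg_cols = reduce(emg_spec, {"emg_power": _band_integral(emg_spec, *EMG_BAND)})

    return pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "start_s": np.arange(n_epochs) * float(epoch_len_s),
            **eeg_cols,
            **emg_cols,
        }
    )


def band_power_pipeline(
    record: SignalRecord,
    epoch_len_s: float = 5.0,
    eeg_params: SpectralParams | None = None,
    emg_params: SpectralParams | None = None,
    include_emg: bool = True,
    chunk_frames: int = 18000,
) -> pd.DataFrame:
    """Per-epoch band-power table for a full record, computed in chunks.

    Identical frame placement and taper math as
    :func:`multitaper_spectrogram` + :func:`epoch_band_powers`, but frames
    are reduced straight to band integrals (single-precision accumulation),
    so memory stays flat regardless of record length.  Set
    ``include_emg=False`` when only EEG ratios are needed (the emg_power
    column is then NaN).
    """
    eeg_params = eeg_params or SpectralParams()
    emg_params = emg_params or SpectralParams.emg_default()
    n = record.n_samples
    fs = record.fs
    n_epochs = int(np.floor(record.duration_s / epoch_len_s))

    def banded(signal: np.ndarray, params: SpectralParams, bands: dict) -> dict:
        win, step, n_frames = _frame_geometry(n, fs, params)
        tapers = _tapers(win, params).astype(np.float32)
        freqs = np.fft.rfftfreq(win, 1.0 / fs)
        df = fs / win
        # weight matrix mapping |X|^2 bins -> integrated band powers
        w = np.zeros((len(freqs), len(bands)), dtype=np.float32)
        for j, (lo, hi) in enumerate(bands.values()):
            sel = (freqs >= lo) & (freqs < hi)
            w[sel, j] = df * 2.0 / (fs * params.n_tapers)
            if sel[0]:
                w[0, j] /= 2.0
            if sel[-1] and win % 2 == 0:
                w[-1, j] /= 2.0
        # interleave for the (re, im) float view of the rfft output
        w2 = np.repeat(w, 2, axis=0)

        x = np.asarray(signal, dtype=np.float32)
        out = np.empty((n_frames, len(bands)), dtype=np.float64)
        centers = (np.arange(n_frames) * step + win / 2.0) / fs
        for i0 in range(0, n_frames, chunk_frames):
            i1 = min(i0 + chunk_frames, n_frames)
            seg = x[i0 * step : (i1 - 1) * step + win]
            frames = np.lib.stride_tricks.sliding_window_view(seg, win)[::step][
                : i1 - i0
            ]
            acc = np.zeros((i1 - i0, len(bands)), dtype=np.float32)
            for tap in tapers:
                spec = scipy.fft.rfft(frames * tap, axis=1)
                v = spec.view(np.float32)
                np.multiply(v, v, out=v)
                acc += v @ w2
            out[i0:i1] = acc
        return {"centers": centers, "bands": dict(zip(bands, out.T))}

    eeg = banded(record.eeg, eeg_params, BANDS)
    cols = {}
    idx = np.floor(eeg["centers"] / epoch_len_s).astype(int)
    ok = (idx >= 0) & (idx < n_epochs)
    counts = np.bincount(idx[ok], minlength=n_epochs).astype(float)
    for name, vals in eeg["bands"].items():
        tot = np.bincount(idx[ok], weights=vals[ok], minlength=n_epochs)
        cols[name] = np.where(counts > 0, tot / np.maximum(counts, 1), np.nan)

    if include_emg:
        emg = banded(record.emg, emg_params, {"emg_power": EMG_BAND})
        idx = np.floor(emg["centers"] / epoch_len_s).astype(int)
        ok = (idx >= 0) & (idx < n_epochs)
        counts = np.bincount(idx[ok], minlength=n_epochs).astype(float)
        tot = np.bincount(idx[ok], weights=emg["bands"]["emg_power"][ok], minlength=n_epochs)
        cols["emg_power"] = np.where(counts > 0, tot / np.maximum(counts, 1), np.nan)
    else:
        cols["emg_power"] = np.full(n_epochs, np.nan)

    return pd.DataFrame(
        {
            "epoch_index": np.arange(n_epochs),
            "start_s": np.arange(n_epochs) * float(epoch_len_s),
            **cols,
        }
    )


def robust_scale(x) -> tuple[float, float]:
    """Median and root-mean-square deviation *from the median*.

    ``s_med = sqrt(mean((x - median(x))²))`` — the spread statistic all
    staging thresholds are built on.  Reduces to the population SD for
    samples whose median equals their mean.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("robust_scale of an empty sequence")
    med = float(np.median(x))
    return med, float(np.sqrt(np.mean((x - med) ** 2)))
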