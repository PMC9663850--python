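# blastsleep

Longitudinal sleep-EEG/EMG and behavior analysis for rodent blast-injury
studies: multitaper band-power extraction, rule-based sleep staging, NREM
sleep-spindle detection and featurization, delta/alpha-ratio cohort
stratification, behavioral preference scoring with published exclusion
rules, and a nonparametric statistics battery — exercised end-to-end on a
synthetic EEG/EMG/behavior generator with full ground truth.

## Who this is for

Labs running chronic wireless EEG/EMG telemetry in mice (e.g. after
traumatic or blast injury) who need a reproducible, scriptable version of
the standard semi-automatic analysis chain: score 24-h records into
AWAKE/NREM/REM in 5-s epochs, quantify band powers and sleep
architecture, detect spindles and their features, split injured cohorts
into high- and low-delta/alpha trajectories, and test group contrasts
with rank statistics.

## The analysis in brief

* **Spectra.** Thomson multitaper spectrograms (DPSS, NW = 3, 5 tapers,
  5-s window / 0.1-s step; EEG 0–150 Hz, EMG 5–170 Hz), reduced to
  per-epoch integrated band powers: δ [2,4), θ [5,8), α [8,13),
  β [16,31), γ [32,100) Hz.
* **Staging.** Per 5-s epoch, strict precedence:
  AWAKE if γ/δ and EMG power clear their cuts; else NREM if δ/EMG does;
  else REM if θ/(δ·EMG) does; else UNDETECTABLE.  Cuts are
  `median + k·s_med` over a calibration window (first hour by default),
  with `s_med` the RMS deviation from the median; k = 0.5 (awake),
  1.0 (NREM), configurable for REM.
* **Spindles.** 10–20 Hz zero-phase FIR band-pass; selected peaks are
  extrema with |z| > 2 over the record; a spindle needs > 5 selected
  peaks, > 0.2 s span, all gaps < 0.16 s, midpoint in NREM.  Features:
  amplitude (µV, peak-to-trough), cycles, intra-spindle frequency
  (cycles/duration), symmetry (position of the largest peak), duration,
  plus density per second of NREM.
* **Cohorts.** Per-state delta/alpha ratios, baseline-normalized, and
  2-means stratification of injured subjects into SBI-HD / SBI-LD with
  controls in the clustering.
* **Statistics.** Jarque–Bera screen; Mann–Whitney U (exact for small
  tie-free samples); Kruskal–Wallis + Dunn–Bonferroni; Friedman +
  Wilcoxon–Bonferroni.

See `docs/methods.md` for assumptions, parameter defaults and numerical
choices.

## Worked example

Simulate one hour of two-channel telemetry with a planted hypnogram and
spindles, stage it, and detect spindles:

```python
import numpy as np
import blastsleep as bs

cfg = bs.SimConfig()                       # study-condition defaults
rec, truth = bs.simulate_record(cfg, seed=1, duration_h=1.0)

hyp, band_powers, cuts = bs.stage_record(rec)
agreement = np.mean(hyp.labels == truth.hypnogram.labels)
print(f"epoch agreement: {agreement:.3f}")

filt = bs.bandpass_10_20(rec.eeg, rec.fs)
events = bs.detect_spindles(filt, rec.fs, hyp)
print(f"{len(events)} spindles, "
      f"mean intra-spindle frequency {np.mean([s.intra_freq_hz for s in events]):.2f} Hz")
```

Output:

```
epoch agreement: 0.917
46 spindles, mean intra-spindle frequency 12.21 Hz
```

The agreement is against the generator's planted hypnogram (the ~8%
disagreement sits almost entirely on state-transition epochs, whose 5-s
band powers genuinely mix two states).  The detected mean intra-spindle
frequency sits near the 12.5-Hz planted carrier; at high SNR the group
mean recovers planted carriers within ±0.5 Hz.

The same steps are available from a shell:

```bash
blastsleep --seed 1 --out run1 simulate --duration-h 1
blastsleep --out run1 stage run1/record.csv
blastsleep --out run1 spindles run1/record.csv --hypnogram run1/hypnogram.csv
```

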