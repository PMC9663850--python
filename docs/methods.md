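# Methods

This note documents the models, rules and numerical choices behind
`blastsleep`, and what the synthetic test bed does and does not show about
real recordings.

## Signals and epochs

The pipeline operates on two-channel telemetry — one cortical EEG and one
nuchal/trapezoid EMG lead — sampled at 500 Hz, analyzed in
non-overlapping 5-s epochs aligned to the record start.  Animals are
housed on a reverse light cycle: 9:00–21:00 is the dark (active) phase,
21:00–9:00 the light (rest) phase; phase membership of an epoch is
derived from the record's clock-time origin `t0`.

## Multitaper band powers

Spectrograms use Thomson's multitaper estimator: DPSS tapers with
time-bandwidth product 3 and 5 tapers (all eigenvalues ≳ 0.99),
eigenvalue-unweighted averaging, a 5-s window moved in 0.1-s steps, and a
retained frequency axis of 0–150 Hz for EEG and 5–170 Hz for EMG.  The
frequency resolution of one frame is ±0.6 Hz (main-lobe half-width).

Band powers are *integrated* one-sided spectral density over the band —
µV², the sum of density bins times the 0.2-Hz bin width — rather than
mean density; a sinusoid of RMS r inside a band contributes ≈ r² to it.
Bands are half-open `[low, high)` Hz: delta [2, 4), theta [5, 8), alpha
[8, 13), beta [16, 31), gamma [32, 100).  The shared 8-Hz edge goes to
alpha; the gaps (0–2, 4–5, 13–16, 31–32 Hz) are deliberate, so the five
bands under-cover total power.  A frame belongs to the epoch containing
its center; epoch band power is the frame mean.  Because the 5-s window
reaches ±2.5 s beyond a frame's center, each epoch's estimate blends
roughly the inner half of its own epoch with the outer quarters of its
neighbors — transition epochs are therefore intrinsically mixed, which
bounds any epoch classifier's accuracy at state boundaries.

`band_power_pipeline` streams long records in chunks of frames and fuses
the band reduction into the FFT pass (single-precision accumulation, \~2%
agreement with the double-precision reference path, which is far below
the between-epoch physiological variability).  A 24-h, 500-Hz record
stages in ≈ 3 min on one CPU.

## Sleep staging

Epochs are labeled by strict precedence:

1. **AWAKE** if gamma/delta > cut *and* EMG power > cut,
2. else **NREM** if delta/EMG > cut,
3. else **REM** if theta/(delta·EMG) > cut,
4. else **UNDETECTABLE** (also any epoch with missing band powers —
   gaps are never interpolated).

Cuts are calibrated on a window of the record (default: the first hour;
a fixed reference hour or the whole record are configurable) as
`median + k·s_med` of the relevant ratio series, where
`s_med = sqrt(mean((x − median)²))` is the RMS deviation from the median.
`k` is 0.5 for gamma/delta and 1.0 for delta/EMG; the REM multiplier is a
config (`rem_k`, default 1.0) because that cut is a judgment call on real
data.  The AWAKE EMG cut is the calibration-window median EMG power.
Denominators are floored at 10⁻¹² × the record median of that quantity so
degenerate all-zero epochs classify as UNDETECTABLE rather than raising.

A structural property of `median + k·s_med` worth knowing: it assumes the
elevated class is a minority of the calibration window.  If one state
occupies more than half of the calibration hour, the median enters that
state's own mass and the cut rises into it, collapsing that state's
sensitivity.  This is a property of the rule, not of the implementation;
it is why the generator keeps the three states near one third each in the
dark phase (below).

Manual visual verification is replaced by an automated QC summary
(fraction UNDETECTABLE, state fractions, transition counts).

## Spindle detection and features

EEG is band-passed 10–20 Hz — wider than the classical 11–16 Hz because
spindle frequency drifts with age and pathology — with a zero-phase
linear-phase Kaiser FIR (2-Hz transitions, > 45 dB by 8 and 24 Hz),
applied by centered overlap-add convolution.  The filtered trace is
z-scored against its own full-record mean/SD.  *Selected peaks* are
signed local extrema with |z| > 2; consecutive selected peaks with all
gaps < 0.16 s form a group; a group is a spindle iff it has more than
five selected peaks and spans more than 0.2 s first-to-last.  Detection
runs over the whole record and events are then filtered to those whose
midpoint lies in a NREM epoch, so events are never truncated at epoch
boundaries.  Every stored event keeps its selected-peak times, making the
three acceptance rules re-checkable from the object alone.

Features: amplitude = max positive − min negative extremum of the
unnormalized filtered trace within the event (µV); cycles = positive
local maxima in the event span; intra-spindle frequency = cycles /
duration; symmetry = position of the largest positive extremum relative
to the span; duration = first-to-last selected peak.

One tie-break matters numerically: the cycle count uses the *half-open*
span `[start, end)`.  With peak-delimited events the boundary peaks'
sign combinations otherwise add on average half a peak, biasing
cycles/duration upward by ≈ 1/(2·duration) — about +1.4 Hz for 0.6-s
events — regardless of SNR.  Counting half-open makes the four boundary
cases cancel, and planted carriers of 11/13/15 Hz are recovered within
±0.5 Hz at high SNR.  Amplitude and symmetry keep the inclusive span:
they describe extremes, not rates.  Whether sub-threshold positive maxima
count toward cycles is configurable in spirit; the default counts all
positive maxima in the span so the feature tracks the oscillation rate
rather than the detection threshold.

## Delta/alpha cohort stratification

Each subject-day is scored per state (NREM, REM, AWAKE) by
mean-delta/mean-alpha over that state's epochs, divided by the same
statistic on the subject's pre-injury baseline record ("relative
units").  Injured subjects are stratified by k-means (k = 2, Euclidean,
50 random seeded restarts, best inertia) on the 3-dimensional normalized
scores of *all* subjects, controls included.  The cluster holding the
majority of controls maps to SBI-LD, the other to SBI-HD; a tie labels
the lower-mean-score cluster LD.  If every subject has identical scores
the clustering is degenerate: all injured are labeled SBI-LD with a
warning.  The reported separation statistic is the centroid distance;
90% of it is exposed as a plotting radius for QC scatter plots.
Stratification uses one post-injury day (default day 2), configurable.

## Behavioral scoring

* NOR preference = (time3/time4)/(time1/time2) — day-2 novel/familiar
  exploration corrected for day-1 object bias.  Trials with < 10 s total
  day-2 exploration are excluded (the rule is applied to summed day-2
  exploration; per-object application is configurable).
* Y-maze preference = new-arm / familiar-arm time; excluded if either
  scored arm got < 15 s, total arm visits < 7, or tracking was lost for
  more than 10% of the trial.
* Rotarod run times and beam velocities are averaged per subject-day
  (mean ± SEM; a single trial reports SEM 0), then per group and day.
  Rotarod and intra-spindle frequency are conventionally reported raw;
  everything else in relative units of the pre-injury baseline.

## Statistics

Jarque–Bera screens normality (informational; constant input counts as
non-normal).  Two groups: two-sided Mann–Whitney U, exact when the
smaller sample has ≤ 8 observations without cross-group ties, otherwise
the tie-corrected normal approximation.  Three or more groups:
Kruskal–Wallis (tie-corrected) followed by Dunn's pairwise z-tests on
mean ranks with tie-corrected variance and Bonferroni adjustment by the
number of pairs (3 for the three-group design).  Repeated measures:
Friedman across conditions then pairwise Wilcoxon signed-rank with
Bonferroni; with exactly two conditions the Friedman statistic reduces to
the sign-test chi-square.  Mid-ranks everywhere; adjusted p capped at 1.

## Synthetic test bed

The generator's purpose is ground truth, not biophysical realism.

**Hypnogram.** A semi-Markov chain over AWAKE/NREM/REM in 5-s epochs:
AWAKE→NREM; NREM→REM with p = 0.7 else AWAKE; REM→AWAKE with p = 0.75
else NREM (REM is entered only from NREM).  Mean bouts: awake 138 s
(×0.55 in the light phase), NREM 114 s, REM 162 s.  Dwell is
*shifted-geometric*: a deterministic floor of half the mean plus a
geometric tail.  The floor keeps bouts physiologically plausible and
thins the extreme bout tail that pure geometric dwell produces; without
it, a single multi-minute bout occasionally pushes one state past half of
the calibration hour, tripping the threshold-rule failure mode described
above.  Stationary time fractions follow the renewal-reward formula
π_s·m_s / Σ π·m with the embedded-chain weights; the dark phase sits near
A/N/R ≈ 0.36/0.34/0.31.  REM is deliberately over-represented relative
to real mice (where REM is ~5–10% of total time) so each hour contains
enough REM for calibration and for per-state sensitivity estimates.

**EEG/EMG.** EEG is a sum of five band-limited Gaussian noise components
(4th-order Butterworth-filtered white noise, normalized to unit RMS),
one per canonical band, with per-state RMS amplitudes (µV):

| band  | base | AWAKE | NREM | REM |
|-------|-----:|------:|-----:|----:|
| delta | 20   | ×0.4  | ×3.0 | ×0.5|
| theta | 10   | ×1.0  | ×0.8 | ×3.0|
| alpha | 8    | ×1.2  | ×0.6 | ×0.8|
| beta  | 5    | ×1.5  | ×0.6 | ×0.8|
| gamma | 4    | ×3.0  | ×0.4 | ×0.8|

plus a 1-µV broadband floor.  EMG is white noise at 40/6/4 µV RMS in
AWAKE/NREM/REM.  Gains switch at epoch boundaries.  These contrasts were
chosen once so that each staging ratio separates its target state by
roughly an order of magnitude, i.e. the "strong contrast" regime.

**Spindles.** Events are planted as a Poisson process (default 0.05/s of
NREM) wholly inside NREM episodes with a 0.25-s pad and 0.5-s minimum
gap; durations N(0.6 s, 0.08 s) clipped to [0.4, 0.9]; Hann envelope
peaking at the center (so symmetry has expectation 0.5); carrier 12.5 Hz
by default.  Peak amplitude is `amplitude_sd_mult` (default 4) times the
10–20 Hz SD of the spindle-free record — the same reference the
detector's 2-SD rule uses, making planted SNR meaningful.  "High SNR" in
the acceptance checks means `amplitude_sd_mult = 8`.

**Injury profiles.**  Multipliers on band *power* (amplitudes scale by
the square root): HD — delta ×1.5, alpha ×0.7, gamma ×0.7, sleep time
×1.2 (NREM/REM dwell up, awake dwell down), carrier −0.4 Hz, spindle
amplitude ×0.8; LD — carrier −0.3 Hz only.  Behavioral deficits scale
planted preference means (controls: NOR 1.9, Y-maze 2.0) and motor
values.  These defaults reproduce effect *directions* and rough scales,
not fitted animal data.

**What passing tests do not show.**  The generator has no 1/f background,
no artifacts, no circadian drift within phases, no inter-subject
anatomical variability, and state-switched stationary noise instead of
real EEG dynamics.  Staging accuracy on it is an upper bound: real
records add artifact epochs (handled only as UNDETECTABLE) and
non-stationary baselines (handled only via per-record calibration).

## Problem sizes in the acceptance script

Staging agreement uses one 24-h record; per-state sensitivity/specificity
averages ten 1-h records (the shortest length the default 1-h calibration
window fits); high-SNR spindle recovery uses 0.5-h records and carrier
recovery three 0.25-h records per carrier; the control-vs-injured carrier
contrast uses ten batches of 8 + 8 records of 0.15 h with spindles
planted at 0.08/s so each group mean averages ≈120 events — below that,
the per-event ±1-cycle quantization noise rather than the detector
decides the ordering; the cohort uses the 11/8/8 control/HD/LD design with 0.5-h
baseline and post records and ten clustering seeds on the fixed score
set.  These sizes keep every estimate's Monte-Carlo error well below the
margins being tested while the whole script stays in the ten-minute
range.

## Known limitations

* Boundary epochs are intrinsically mixed by the 5-s sliding window;
  epoch agreement saturates near 92–94% on clean synthetic data.
* The threshold rule's minority assumption (above) makes first-hour
  calibration sensitive to unusual hours; the whole-record calibration
  option is more stable on fragmented sleepers.
* EDF support is 16-bit, two-channel, 1-s records, whole seconds only.
* The intra-spindle frequency estimator quantizes at 1/duration; single
  events carry ±1 Hz granularity and only group means are comparable at
  0.1-Hz precision.
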