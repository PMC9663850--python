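"""Ground-truth synthetic EEG/EMG and behavior generator.

The generator emulates 24-h telemetry from group-housed-alone mice on a
reverse light cycle (dark/active 9:00-21:00), with full ground truth for
every downstream stage:

* a semi-Markov hypnogram over AWAKE/NREM/REM in 5-s epochs (geometric
  dwell times, REM entered only from NREM, longer awake bouts in the dark
  phase);
* EEG built as a sum of band-limited Gaussian noise components — one per
  canonical band, amplitude-switched by the active state — plus
  Hann-enveloped spindle bursts planted as a Poisson process inside NREM
  episodes; EMG is state-scaled white noise;
* injury profiles (delta surge, alpha/gamma suppression, more sleep,
  slower and smaller spindles) applied as multiplicative modifiers;
* behavior trial tables with planted preference/deficit effects and a
  configured fraction of trials that violate the published exclusion
  rules.

Band-limited noise was chosen over autoregressive EEG models because every
staging rule is a band-power ratio: per-band ground-truth power is then
known by construction.  Spindle bursts use a Hann envelope peaking at the
event center, so the symmetry feature has known expectation 0.5, and their
peak amplitude is expressed in units of the 10-20 Hz background SD of the
spindle-free record, which ties planted SNR directly to the detector's
2-SD selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal

from .behavior import MotorTrial, NORTrial, YMazeTrial
from .signal_io import Hypnogram, SignalRecord
from .spectral import BANDS
from .spindles import bandpass_10_20

__all__ = [
    "SimConfig",
    "InjuryProfile",
    "PlantedSpindle",
    "GroundTruth",
    "simulate_hypnogram",
    "plan_spindles",
    "simulate_signals",
    "simulate_record",
    "simulate_cohort",
    "simulate_behavior",
    "INJURY_PROFILES",
]


@dataclass
class InjuryProfile:
    """Multiplicative EEG/sleep/spindle modifiers for one injury group."""

    name: str = "none"
    band_mult: dict = field(default_factory=dict)  # e.g. {"delta": 1.5}
    sleep_time_mult: float = 1.0  # scales NREM/REM dwell, divides awake dwell
    carrier_shift_hz: float = 0.0
    spindle_amp_mult: float = 1.0
    nor_pref_mult: float = 1.0
    ymaze_pref_mult: float = 1.0
    motor_mult: float = 1.0


#: Default group profiles.  HD (high delta/alpha): delta surge, alpha and
#: gamma suppression, 20% more sleep, slower and smaller spindles, strong
#: behavioral deficits.  LD (low delta/alpha): a mild spindle slowing only.
INJURY_PROFILES = {
    "none": InjuryProfile(),
    "HD": InjuryProfile(
        name="HD",
        band_mult={"delta": 1.5, "alpha": 0.7, "gamma": 0.7},
        sleep_time_mult=1.2,
        carrier_shift_hz=-0.4,
        spindle_amp_mult=0.8,
        nor_pref_mult=0.53,
        ymaze_pref_mult=0.6,
        motor_mult=0.8,
    ),
    "LD": InjuryProfile(
        name="LD",
        carrier_shift_hz=-0.3,
        nor_pref_mult=0.85,
        ymaze_pref_mult=0.85,
        motor_mult=0.95,
    ),
}


@dataclass
class SimConfig:
    """All knobs of the generator, with study-condition defaults."""

    fs: float = 500.0
    epoch_len_s: float = 5.0
    duration_h: float = 24.0
    t0: str = "09:00"

    # semi-Markov dwell means (s) and embedded transition weights
    dwell_s: dict = field(
        default_factory=lambda: {"AWAKE": 138.0, "NREM": 114.0, "REM": 162.0}
    )
    #: awake dwell is multiplied by this during the light (rest) phase
    awake_light_dwell_mult: float = 0.55
    #: deterministic fraction of the mean bout length (shifted-geometric dwell)
    dwell_min_frac: float = 0.5
    p_nrem_to_rem: float = 0.7
    p_rem_to_awake: float = 0.75

    # per-band component RMS amplitude (µV) and per-state multipliers
    band_rms_uv: dict = field(
        default_factory=lambda: {
            "delta": 20.0,
            "theta": 10.0,
            "alpha": 8.0,
            "beta": 5.0,
            "gamma": 4.0,
        }
    )
    state_band_mult: dict = field(
        default_factory=lambda: {
            "AWAKE": {"delta": 0.4, "theta": 1.0, "alpha": 1.2, "beta": 1.5, "gamma": 3.0},
            "NREM": {"delta": 3.0, "theta": 0.8, "alpha": 0.6, "beta": 0.6, "gamma": 0.4},
            "REM": {"delta": 0.5, "theta": 3.0, "alpha": 0.8, "beta": 0.8, "gamma": 0.8},
        }
    )
    emg_rms_uv: dict = field(
        default_factory=lambda: {"AWAKE": 40.0, "NREM": 6.0, "REM": 4.0}
    )
    broadband_floor_uv: float = 1.0

    # spindles
    spindle_rate_per_s_nrem: float = 0.05
    spindle_carrier_hz: float = 12.5
    spindle_duration_mean_s: float = 0.6
    spindle_duration_sd_s: float = 0.08
    spindle_duration_clip_s: tuple = (0.4, 0.9)
    spindle_amplitude_sd_mult: float = 4.0
    spindle_min_gap_s: float = 0.5
    spindle_edge_pad_s: float = 0.25

    # behavior
    nor_pref_mean_control: float = 1.9
    ymaze_pref_mean_control: float = 2.0
    rotarod_base_s: float = 30.0
    rotarod_learning_gain_s: float = 12.0
    beam_velocity_base: float = 1.0
    behavior_noise_cv: float = 0.15
    exclusion_violation_frac: float = 0.1

    injury: InjuryProfile = field(default_factory=InjuryProfile)

    def with_injury(self, profile: str | InjuryProfile) -> "SimConfig":
        if isinstance(profile, str):
            profile = INJURY_PROFILES[profile]
        return replace(self, injury=profile)


@dataclass
class PlantedSpindle:
    start_s: float
    end_s: float
    carrier_hz: float
    amplitude_uv: float


@dataclass
class GroundTruth:
    """What the generator planted, for scoring downstream recovery."""

    hypnogram: Hypnogram | None = None
    spindles: list = field(default_factory=list)
    group: str = "none"
    behavior_effects: dict = field(default_factory=dict)


_STATES3 = ("AWAKE", "NREM", "REM")


def _dwell_epochs(cfg: SimConfig, state: str, dark: bool) -> float:
    d = cfg.dwell_s[state]
    inj = cfg.injury
    if state == "AWAKE":
        if not dark:
            d *= cfg.awake_light_dwell_mult
        d /= inj.sleep_time_mult
    else:
        d *= inj.sleep_time_mult
    return max(d / cfg.epoch_len_s, 1.0)


def _draw_dwell(rng: np.random.Generator, mean_epochs: float, min_frac: float) -> int:
    """Shifted-geometric bout length (epochs) with the requested mean.

    A deterministic floor of ``min_frac`` of the mean plus a geometric tail.
    The floor keeps bouts physiologically plausible (no 5-s sleep bouts) and
    thins the extreme bout tail that pure geometric dwell would produce,
    which stabilizes the state composition of any single hour; the mean —
    all that enters the stationary time fractions — is unchanged.
    """
    m0 = max(int(round(min_frac * mean_epochs)), 1)
    tail = max(mean_epochs - m0 + 1.0, 1.0)
    return (m0 - 1) + int(rng.geometric(1.0 / tail))


def simulate_hypnogram(
    cfg: SimConfig, seed: int, duration_h: float | None = None
) -> Hypnogram:
    """Semi-Markov state sequence in 5-s epochs.

    Bout (dwell) lengths are shifted-geometric with the configured means;
    REM is reachable only from NREM; awake bouts are longer in the dark
    (active) phase than in the light phase.  The phase is evaluated at
    bout onset.
    """
    rng = np.random.default_rng(seed)
    duration_h = cfg.duration_h if duration_h is None else duration_h
    n = int(round(duration_h * 3600.0 / cfg.epoch_len_s))
    from .signal_io import _parse_clock, DARK_START_MIN, DARK_END_MIN

    t0_min = _parse_clock(cfg.t0)
    labels = np.empty(n, dtype="U12")
    state = "AWAKE"
    i = 0
    while i < n:
        minutes = (t0_min + i * cfg.epoch_len_s / 60.0) % (24 * 60)
        dark = DARK_START_MIN <= minutes < DARK_END_MIN
        dwell = _draw_dwell(
            rng, _dwell_epochs(cfg, state, dark), cfg.dwell_min_frac
        )
        j = min(i + dwell, n)
        labels[i:j] = state
        i = j
        if state == "AWAKE":
            state = "NREM"
        elif state == "NREM":
            state = "REM" if rng.random() < cfg.p_nrem_to_rem else "AWAKE"
        else:  # REM
            state = "AWAKE" if rng.random() < cfg.p_rem_to_awake else "NREM"
    return Hypnogram(labels=labels, epoch_len_s=cfg.epoch_len_s, t0=cfg.t0)


def _nrem_episodes_s(h: Hypnogram) -> list[tuple[float, float]]:
    lab = h.labels
    runs = []
    start = None
    for i, l in enumerate(lab):
        if l == "NREM" and start is None:
            start = i
        elif l != "NREM" and start is not None:
            runs.append((start * h.epoch_len_s, i * h.epoch_len_s))
            start = None
    if start is not None:
        runs.append((start * h.epoch_len_s, len(lab) * h.epoch_len_s))
    return runs


def plan_spindles(h: Hypnogram, cfg: SimConfig, rng: np.random.Generator) -> list[PlantedSpindle]:
    """Poisson-plant spindle intervals wholly inside NREM episodes.

    Amplitudes are left at NaN here; :func:`simulate_signals` fills them in
    units of the measured 10-20 Hz background SD.
    """
    carrier = cfg.spindle_carrier_hz + cfg.injury.carrier_shift_hz
    lo, hi = cfg.spindle_duration_clip_s
    pad = cfg.spindle_edge_pad_s
    events: list[PlantedSpindle] = []
    for a, b in _nrem_episodes_s(h):
        span = b - a
        n = rng.poisson(cfg.spindle_rate_per_s_nrem * span)
        if n == 0:
            continue
        durs = np.clip(
            rng.normal(cfg.spindle_duration_mean_s, cfg.spindle_duration_sd_s, n), lo, hi
        )
        starts = []
        for d in durs:
            if span - 2 * pad - d <= 0:
                continue
            starts.append((a + pad + rng.random() * (span - 2 * pad - d), d))
        # drop overlapping events (keep earlier ones)
        starts.sort()
        t_free = -np.inf
        for s, d in starts:
            if s >= t_free + cfg.spindle_min_gap_s:
                events.append(PlantedSpindle(s, s + d, carrier, np.nan))
                t_free = s + d
    events.sort(key=lambda e: e.start_s)
    return events


def _band_component(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    x = rng.standard_normal(n).astype(np.float32)
    if lo <= 0:
        sos = scipy.signal.butter(4, hi, btype="low", fs=fs, output="sos")
    else:
        sos = scipy.signal.butter(4, (lo, hi), btype="band", fs=fs, output="sos")
    y = scipy.signal.sosfiltfilt(sos, x).astype(np.float32)
    y /= y.std() or 1.0
    return y


def simulate_signals(
    h: Hypnogram, cfg: SimConfig, seed: int
) -> tuple[SignalRecord, GroundTruth]:
    """Render EEG/EMG traces for a planted hypnogram.

    Returns the record and the ground truth (hypnogram, planted spindles
    with realized amplitudes, group label).
    """
    rng = np.random.default_rng(seed)
    fs = cfg.fs
    n = int(round(h.duration_s * fs))
    epoch_samples = int(round(cfg.epoch_len_s * fs))

    state_idx = {s: i for i, s in enumerate(_STATES3)}
    lab_idx = np.array([state_idx.get(l, 0) for l in h.labels])

    eeg = np.zeros(n, dtype=np.float32)
    for band, (lo, hi) in BANDS.items():
        comp = _band_component(rng, n, fs, lo, hi)
        mult = np.array(
            [cfg.state_band_mult[s][band] for s in _STATES3], dtype=np.float32
        )
        # injury profile multipliers are band-POWER ratios (a delta x1.5
        # surge means 50% more delta power), hence sqrt on the amplitude
        inj = np.sqrt(cfg.injury.band_mult.get(band, 1.0))
        gain = np.repeat(cfg.band_rms_uv[band] * inj * mult[lab_idx], epoch_samples)[:n]
        eeg += gain * comp
        del comp, gain
    if cfg.broadband_floor_uv > 0:
        eeg += cfg.broadband_floor_uv * rng.standard_normal(n).astype(np.float32)

    # spindle SNR reference: 10-20 Hz SD of the spindle-free record
    sigma_f = float(bandpass_10_20(eeg, fs).std())
    events = plan_spindles(h, cfg, rng)
    amp = cfg.spindle_amplitude_sd_mult * sigma_f * cfg.injury.spindle_amp_mult
    for ev in events:
        ev.amplitude_uv = amp
        i0, i1 = int(round(ev.start_s * fs)), int(round(ev.end_s * fs))
        i1 = min(i1, n)
        m = i1 - i0
        if m <= 0:
            continue
        tau = np.arange(m, dtype=np.float32) / fs
        dur = m / fs
        env = 0.5 * (1.0 - np.cos(2.0 * np.pi * tau / dur))
        phase = rng.uniform(0, 2 * np.pi)
        eeg[i0:i1] += (amp * env * np.sin(2 * np.pi * ev.carrier_hz * tau + phase)).astype(
            np.float32
        )

    emg_rms = np.array([cfg.emg_rms_uv[s] for s in _STATES3], dtype=np.float32)
    emg_gain = np.repeat(emg_rms[lab_idx], epoch_samples)[:n]
    emg = emg_gain * rng.standard_normal(n).astype(np.float32)

    rec = SignalRecord(eeg=eeg, emg=emg, fs=fs, t0=h.t0)
    truth = GroundTruth(hypnogram=h, spindles=events, group=cfg.injury.name)
    return rec, truth


def simulate_record(
    cfg: SimConfig, seed: int, duration_h: float | None = None
) -> tuple[SignalRecord, GroundTruth]:
    """Hypnogram + signals in one call (independent sub-streams of ``seed``)."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_hyp, s_sig = ss.spawn(2)
    h = simulate_hypnogram(cfg, s_hyp, duration_h=duration_h)
    return simulate_signals(h, cfg, s_sig)


@dataclass
class CohortSubject:
    subject_id: str
    group: str  # control / HD / LD
    baseline_seed: int
    post_seed: int


@dataclass
class CohortSim:
    """Lazy cohort: subject roster plus on-demand record generation."""

    subjects: list
    cfg: SimConfig
    duration_h: float

    def labels(self) -> dict:
        return {s.subject_id: s.group for s in self.subjects}

    def records(self, subj: CohortSubject):
        """(baseline, post) record+truth pairs for one subject."""
        base = simulate_record(
            self.cfg.with_injury("none"), subj.baseline_seed, self.duration_h
        )
        post = simulate_record(
            self.cfg.with_injury(subj.group if subj.group != "control" else "none"),
            subj.post_seed,
            self.duration_h,
        )
        return base, post


def simulate_cohort(
    n_control: int = 11,
    n_hd: int = 8,
    n_ld: int = 8,
    cfg: SimConfig | None = None,
    seed: int = 0,
    duration_h: float = 24.0,
) -> CohortSim:
    """Roster a control/HD/LD cohort (default sizes 11/8/8).

    Records are generated lazily per subject so full cohorts never live in
    memory at once.
    """
    cfg = cfg or SimConfig()
    ss = np.random.SeedSequence(seed)
    groups = ["control"] * n_control + ["HD"] * n_hd + ["LD"] * n_ld
    children = ss.spawn(2 * len(groups))
    subjects = [
        CohortSubject(
            subject_id=f"{g}{i:02d}",
            group=g,
            baseline_seed=children[2 * i],
            post_seed=children[2 * i + 1],
        )
        for i, g in enumerate(groups)
    ]
    return CohortSim(subjects=subjects, cfg=cfg, duration_h=duration_h)


# ---------------------------------------------------------------------------
# Behavior tables
# ---------------------------------------------------------------------------


def _profile(group: str) -> InjuryProfile:
    return INJURY_PROFILES["none"] if group == "control" else INJURY_PROFILES[group]


def simulate_behavior(
    assignment: dict,
    cfg: SimConfig | None = None,
    seed: int = 0,
    n_motor_days: int = 5,
    n_motor_trials_per_day: int = 5,
) -> dict:
    """Behavior trial tables for ``assignment`` (subject_id -> group).

    Each subject consumes its own RNG stream and the group deficit enters
    only as a multiplier on that stream's draws, so a deficit multiplier of
    1.0 reproduces the control distribution draw-for-draw under the same
    seed.  A configured fraction of trials is corrupted to violate the
    published exclusion rules (short exploration, few visits, lost
    tracking), exercising the trial filters.
    """
    cfg = cfg or SimConfig()
    ss = np.random.SeedSequence(seed)
    streams = {sid: np.random.default_rng(s) for sid, s in
               zip(sorted(assignment), ss.spawn(len(assignment)))}
    cv = cfg.behavior_noise_cv
    nor_rows, ym_rows, motor_rows = [], [], []
    effects = {}

    for sid in sorted(assignment):
        rng = streams[sid]
        prof = _profile(assignment[sid])
        effects[sid] = {
            "nor_pref": cfg.nor_pref_mean_control * prof.nor_pref_mult,
            "ymaze_pref": cfg.ymaze_pref_mean_control * prof.ymaze_pref_mult,
            "motor_mult": prof.motor_mult,
        }

        # --- NOR ---
        t1 = max(rng.normal(30, 5), 5.0)
        t2 = max(rng.normal(30, 5), 5.0)
        t4 = max(rng.normal(20, 4), 8.0)
        pref = cfg.nor_pref_mean_control * rng.lognormal(0.0, cv) * prof.nor_pref_mult
        t3 = pref * (t1 / t2) * t4
        loss = float(rng.beta(1, 60))
        if rng.random() < cfg.exclusion_violation_frac:
            scale = 8.0 / (t3 + t4)  # day-2 exploration below the 10-s rule
            t3, t4 = t3 * scale, t4 * scale
        nor_rows.append(
            NORTrial(subject_id=sid, time1=t1, time2=t2, time3=t3, time4=t4,
                     tracking_loss_frac=loss)
        )

        # --- Y maze ---
        fam = max(rng.normal(40, 8), 16.0)
        ratio = cfg.ymaze_pref_mean_control * rng.lognormal(0.0, cv) * prof.ymaze_pref_mult
        new = max(ratio * fam, 16.0)
        visits = int(rng.poisson(12)) + 7
        loss = float(rng.beta(1, 60))
        if rng.random() < cfg.exclusion_violation_frac:
            rule = rng.integers(3)
            if rule == 0:
                fam = 10.0
            elif rule == 1:
                visits = int(rng.integers(0, 7))
            else:
                loss = 0.11 + 0.3 * rng.random()
        ym_rows.append(
            YMazeTrial(subject_id=sid, time_new=new, time_familiar=fam,
                       visits_total=visits, tracking_loss_frac=loss)
        )

        # --- motor: rotarod run times and beam velocities ---
        for day in range(n_motor_days):
            learn = 1.0 - np.exp(-(day + 1) / 2.0)
            for kind, base, gain in (
                ("rotarod", cfg.rotarod_base_s, cfg.rotarod_learning_gain_s),
                ("beam", cfg.beam_velocity_base, 0.4 * cfg.beam_velocity_base),
            ):
                for _ in range(n_motor_trials_per_day):
                    val = (base + gain * learn) * prof.motor_mult * rng.lognormal(0.0, cv / 2)
                    motor_rows.append(
                        MotorTrial(subject_id=sid, day_index=day, kind=kind,
                                   value=float(val))
                    )

    return {
        "nor": nor_rows,
        "ymaze": ym_rows,
        "motor": motor_rows,
        "effects": effects,
    }
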