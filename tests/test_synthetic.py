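"""Generator contracts: determinism, planted structure, ground-truth math."""

import numpy as np
import pytest

from blastsleep.spectral import band_power_pipeline
from blastsleep.synthetic import (
    INJURY_PROFILES,
    SimConfig,
    plan_spindles,
    simulate_behavior,
    simulate_cohort,
    simulate_hypnogram,
    simulate_record,
)
from blastsleep.behavior import filter_trials


def expected_state_fractions(cfg: SimConfig, dark: bool) -> dict:
    """Closed-form stationary time fractions of the semi-Markov chain.

    Embedded chain: AWAKE->NREM; NREM->REM w.p. p, else AWAKE;
    REM->AWAKE w.p. q, else NREM.  Time fraction of state s is
    pi_s * m_s / sum(pi * m) with m the mean dwell (renewal reward).
    """
    p, q = cfg.p_nrem_to_rem, cfg.p_rem_to_awake
    pi_n = 1.0
    pi_r = p
    pi_a = (1 - p) + q * p
    m = dict(cfg.dwell_s)
    if not dark:
        m["AWAKE"] *= cfg.awake_light_dwell_mult
    w = {"AWAKE": pi_a * m["AWAKE"], "NREM": pi_n * m["NREM"], "REM": pi_r * m["REM"]}
    tot = sum(w.values())
    return {k: v / tot for k, v in w.items()}


class TestSimulateHypnogram:
    def test_same_seed_identical(self, sim_cfg):
        a = simulate_hypnogram(sim_cfg, 42, duration_h=2.0)
        b = simulate_hypnogram(sim_cfg, 42, duration_h=2.0)
        assert np.array_equal(a.labels, b.labels)

    def test_epoch_length_is_five_seconds(self, sim_cfg):
        h = simulate_hypnogram(sim_cfg, 0, duration_h=1.0)
        assert h.epoch_len_s == 5.0
        assert h.n_epochs == 720

    def test_rem_entered_only_from_nrem(self, sim_cfg):
        h = simulate_hypnogram(sim_cfg, 3, duration_h=24.0)
        lab = h.labels
        into_rem = np.flatnonzero((lab[1:] == "REM") & (lab[:-1] != "REM"))
        assert len(into_rem) > 0
        assert np.all(lab[into_rem] == "NREM")

    def test_time_fractions_match_stationary_oracle(self, sim_cfg):
        # dark-phase fractions over 10 seeds vs the renewal-reward formula
        fracs = []
        for seed in range(10):
            h = simulate_hypnogram(sim_cfg, seed, duration_h=24.0)
            dark = np.array(
                [sim_cfg.t0 == "09:00" and (t % 86400) < 43200 for t in h.epoch_starts()]
            )
            fracs.append([np.mean(h.labels[dark] == s) for s in ("AWAKE", "NREM", "REM")])
        mean_frac = np.array(fracs).mean(axis=0)
        exp = expected_state_fractions(sim_cfg, dark=True)
        for i, s in enumerate(("AWAKE", "NREM", "REM")):
            assert mean_frac[i] == pytest.approx(exp[s], rel=0.10)

    def test_dark_phase_has_more_wake_than_light(self, sim_cfg):
        h = simulate_hypnogram(sim_cfg, 5, duration_h=24.0)
        dark = (h.epoch_starts() % 86400) < 43200  # t0 09:00 -> first 12 h dark
        awake = h.labels == "AWAKE"
        assert awake[dark].mean() > awake[~dark].mean()


class TestPlantedSpindles:
    def test_all_events_inside_nrem_episodes(self, sim_cfg, rng):
        h = simulate_hypnogram(sim_cfg, 11, duration_h=24.0)
        events = plan_spindles(h, sim_cfg, rng)
        nrem = h.labels == "NREM"
        for ev in events:
            first = int(ev.start_s // h.epoch_len_s)
            last = int((ev.end_s - 1e-9) // h.epoch_len_s)
            assert nrem[first : last + 1].all()

    def test_poisson_count_concentration(self, sim_cfg):
        h = simulate_hypnogram(sim_cfg, 13, duration_h=24.0)
        nrem_s = float(np.sum(h.labels == "NREM")) * h.epoch_len_s
        expected = sim_cfg.spindle_rate_per_s_nrem * nrem_s
        counts = [
            len(plan_spindles(h, sim_cfg, np.random.default_rng(s))) for s in range(5)
        ]
        # events dropped near episode edges make this slightly conservative
        for c in counts:
            assert abs(c - expected) <= 3 * np.sqrt(expected) + 0.1 * expected

    def test_events_never_overlap(self, sim_cfg, rng):
        h = simulate_hypnogram(sim_cfg, 17, duration_h=12.0)
        ev = plan_spindles(h, sim_cfg, rng)
        for a, b in zip(ev[:-1], ev[1:]):
            assert b.start_s >= a.end_s


class TestSimulateSignals:
    def test_record_shape_and_rate(self, short_record):
        rec, truth = short_record
        assert rec.fs == 500.0
        assert rec.n_samples == int(0.2 * 3600 * 500)
        assert len(rec.eeg) == len(rec.emg)

    def test_determinism(self, sim_cfg):
        a, _ = simulate_record(sim_cfg, 9, duration_h=0.05)
        b, _ = simulate_record(sim_cfg, 9, duration_h=0.05)
        np.testing.assert_array_equal(a.eeg, b.eeg)
        np.testing.assert_array_equal(a.emg, b.emg)

    def test_nrem_delta_dominates_awake_delta(self, short_record):
        rec, truth = short_record
        bp = band_power_pipeline(rec, include_emg=False)
        lab = truth.hypnogram.labels[: len(bp)]
        interior = np.ones(len(lab), bool)
        interior[1:] &= lab[1:] == lab[:-1]
        interior[:-1] &= lab[:-1] == lab[1:]
        nrem_delta = bp["delta"][(lab == "NREM") & interior]
        awake_delta = bp["delta"][(lab == "AWAKE") & interior]
        thresh = np.quantile(awake_delta, 0.95)
        assert np.mean(nrem_delta > thresh) >= 0.95

    def test_hd_profile_multiplier_construction(self):
        hd = INJURY_PROFILES["HD"]
        assert hd.band_mult["delta"] / hd.band_mult["alpha"] == pytest.approx(1.5 / 0.7)
        assert INJURY_PROFILES["LD"].band_mult == {}


class TestSimulateCohort:
    def test_default_sizes_match_study_design(self, sim_cfg):
        sim = simulate_cohort(cfg=sim_cfg, seed=0, duration_h=0.1)
        groups = [s.group for s in sim.subjects]
        assert groups.count("control") == 11
        assert groups.count("HD") == 8
        assert groups.count("LD") == 8

    def test_baseline_is_uninjured_and_post_carries_group(self, sim_cfg):
        sim = simulate_cohort(n_control=1, n_hd=1, n_ld=0, cfg=sim_cfg,
                              seed=1, duration_h=0.05)
        hd_subj = [s for s in sim.subjects if s.group == "HD"][0]
        (_, base_truth), (_, post_truth) = sim.records(hd_subj)
        assert base_truth.group == "none"
        assert post_truth.group == "HD"


class TestSimulateBehavior:
    def _assignment(self, n_c=6, n_hd=6):
        a = {f"c{i:02d}": "control" for i in range(n_c)}
        a.update({f"h{i:02d}": "HD" for i in range(n_hd)})
        return a

    def test_null_effect_identical_in_law(self, sim_cfg):
        # same subject ids, same seed: control vs a unit-multiplier profile
        import dataclasses

        from blastsleep.synthetic import InjuryProfile

        null_inj = InjuryProfile(name="HD")  # all multipliers 1.0
        import blastsleep.synthetic as syn

        ids = [f"s{i}" for i in range(5)]
        out_c = simulate_behavior({i: "control" for i in ids}, sim_cfg, seed=3)
        saved = syn.INJURY_PROFILES["HD"]
        syn.INJURY_PROFILES["HD"] = null_inj
        try:
            out_i = simulate_behavior({i: "HD" for i in ids}, sim_cfg, seed=3)
        finally:
            syn.INJURY_PROFILES["HD"] = saved
        for a, b in zip(out_c["nor"], out_i["nor"]):
            assert (a.time1, a.time2, a.time3, a.time4) == (
                b.time1, b.time2, b.time3, b.time4,
            )

    def test_planted_exclusion_fraction_recovered(self, sim_cfg):
        import dataclasses

        cfg = dataclasses.replace(sim_cfg, exclusion_violation_frac=0.2)
        assignment = {f"s{i:03d}": "control" for i in range(100)}
        out = simulate_behavior(assignment, cfg, seed=5)
        _, log = filter_trials(out["nor"], "nor")
        assert abs(len(log) - 20) <= 8

    def test_planted_preference_scale(self, sim_cfg):
        from blastsleep.behavior import nor_preference

        out = simulate_behavior({f"c{i:03d}": "control" for i in range(200)},
                                sim_cfg, seed=7)
        kept, _ = filter_trials(out["nor"], "nor")
        prefs = [nor_preference(t) for t in kept]
        assert np.mean(prefs) == pytest.approx(
            sim_cfg.nor_pref_mean_control, rel=0.15
        )

    def test_hd_deficit_lowers_preference(self, sim_cfg):
        out = simulate_behavior(self._assignment(50, 50), sim_cfg, seed=2)
        from blastsleep.behavior import nor_preference

        kept, _ = filter_trials(out["nor"], "nor")
        ctrl = [nor_preference(t) for t in kept if t.subject_id.startswith("c")]
        hd = [nor_preference(t) for t in kept if t.subject_id.startswith("h")]
        assert np.mean(hd) < np.mean(ctrl)
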