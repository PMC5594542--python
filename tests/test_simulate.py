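"""Generator: session plans, determinism, graded ERD, EMG bursts."""

import numpy as np
import pytest
from scipy import signal

from mfload import (GeneratorConfig, plan_sessions, simulate_subject,
                    synthesize_recording)
from mfload.errors import ConfigError
from mfload.preprocess import epoch, select_channels
from tests.conftest import emg_config, fast_config


def band_power(x, fs, band):
    """Welch estimate of mean power spectral density inside a band."""
    f, p = signal.welch(x, fs=fs, nperseg=min(len(x), 512))
    sel = (f >= band[0]) & (f <= band[1])
    return p[sel].mean()


def c3_band_powers(rec, band, segment, fs):
    """Per-trial C3 band power over a segment vs the pre-cue baseline."""
    cm = select_channels(rec)
    idx = cm.labels.index("C3")
    seg_p, base_p = [], []
    for _, ev in rec.events[rec.events["segment"] == segment].iterrows():
        i0 = int(round(ev["onset_s"] * fs))
        i1 = int(round((ev["onset_s"] + ev["duration_s"]) * fs))
        seg_p.append(band_power(cm.data[idx, i0:i1], fs, band))
    for _, ev in rec.events[rec.events["segment"] == "cue"].iterrows():
        j1 = int(round(ev["onset_s"] * fs))
        j0 = j1 - int(round(2.0 * fs))
        base_p.append(band_power(cm.data[idx, j0:j1], fs, band))
    return np.array(seg_p), np.array(base_p)


class TestPlans:
    def test_five_sessions_with_stated_trial_structure(self):
        plans = plan_sessions(0)
        assert [p.session_id for p in plans] == [1, 2, 3, 4, 5]
        for p in plans[:3]:
            assert len(p.blocks) == 2
            for block in p.blocks:
                assert len(block) == 10
                assert block.count("high") == 5
                assert block.count("low") == 5
        s4 = plans[3]
        assert s4.n_trials == 30
        assert all(lb == "relaxed" for b in s4.blocks for lb in b)
        s5 = plans[4]
        assert len(s5.blocks) == 4
        for block in s5.blocks:
            assert len(block) == 12
            for lb in ("high", "low", "relaxed"):
                assert block.count(lb) == 4

    @pytest.mark.parametrize("seed", [0, 7])
    def test_trial_durations(self, seed):
        plans = plan_sessions(seed)
        for p in plans[:3]:
            assert p.trial_duration == 22.0
        for p in plans[3:]:
            assert p.trial_duration == 12.0

    def test_plans_reproducible_and_randomized(self):
        a, b = plan_sessions(3), plan_sessions(3)
        assert a == b
        c = plan_sessions(4)
        assert any(x.blocks != y.blocks for x, y in zip(a, c))


class TestSynthesis:
    def test_bit_identical_for_identical_seed_and_config(self):
        cfg = fast_config()
        plan = plan_sessions(0)[4]
        r1 = synthesize_recording(plan, cfg, 11)
        r2 = synthesize_recording(plan, cfg, 11)
        np.testing.assert_array_equal(r1.data, r2.data)
        r3 = synthesize_recording(plan, cfg, 12)
        assert not np.array_equal(r1.data, r3.data)

    def test_event_labels_match_plan(self):
        cfg = fast_config()
        plan = plan_sessions(2)[0]
        rec = synthesize_recording(plan, cfg, 2)
        mi = rec.events[rec.events["segment"] == "MI"]
        assert list(mi["label"]) == [lb for b in plan.blocks for lb in b]

    def test_unknown_focus_channel_rejected(self):
        with pytest.raises(ConfigError):
            fast_config(erd_focus="C99")

    def test_depth_ordering_validated(self):
        with pytest.raises(ConfigError):
            fast_config(erd_depth_high=0.2, erd_depth_low=0.5)

    def test_null_effect_config_mi_matches_rest(self):
        """With both depths zero, MI band power is indistinguishable from
        the baseline across >= 30 trials (two-sample test at alpha=0.01)."""
        from scipy import stats

        cfg = fast_config(erd_depth_high=0.0, erd_depth_low=0.0,
                          amp_jitter=0.0)
        plan = plan_sessions(1)[4]  # 48 trials
        rec = synthesize_recording(plan, cfg, 21)
        mi_p, base_p = c3_band_powers(rec, cfg.mu_band, "MI", cfg.fs)
        assert len(mi_p) >= 30
        _, p = stats.ttest_ind(np.log(mi_p), np.log(base_p))
        assert p > 0.01

    def test_mu_power_ratio_recovers_squared_attenuation(self):
        """depth 0.5 -> MI/baseline mu power ratio near (1-0.5)^2 = 0.25
        (within 20%) at the focus channel over 40+ high-load trials."""
        cfg = fast_config()
        plans = plan_sessions(5)
        ratios = []
        for sid in (1, 2, 3):  # 2 x 10 trials each, half 'high'
            rec = synthesize_recording(plans[sid - 1], cfg, 5)
            mi = rec.events["segment"] == "MI"
            high_mask = (rec.events["label"] == "high")[mi].to_numpy()
            mi_p, base_p = c3_band_powers(rec, cfg.mu_band, "MI", cfg.fs)
            ratios.append(mi_p[high_mask].mean() / base_p.mean())
        ratio = np.mean(ratios)
        assert 0.25 * 0.8 <= ratio <= 0.25 * 1.2

    def test_mi_power_ratio_monotone_in_depth(self):
        """C3 mu MI/baseline power decreases as ERD depth grows."""
        ratios = []
        for depth in (0.0, 0.25, 0.5):
            cfg = fast_config(erd_depth_high=depth, erd_depth_low=0.0)
            plans = plan_sessions(3)
            vals = []
            for sid in (1, 2, 3):
                rec = synthesize_recording(plans[sid - 1], cfg, 31)
                mi = rec.events["segment"] == "MI"
                hm = (rec.events["label"] == "high")[mi].to_numpy()
                mi_p, base_p = c3_band_powers(rec, cfg.mu_band, "MI", cfg.fs)
                vals.append(mi_p[hm].mean() / base_p.mean())
            ratios.append(np.mean(vals))
        assert ratios[0] > ratios[1] > ratios[2]

    def test_erd_decays_away_from_focus(self):
        """Attenuation is strongest at C3 and fades at distant channels."""
        cfg = fast_config(amp_jitter=0.0, erd_depth_jitter=0.0,
                          mirror_gain=0.0)
        plans = plan_sessions(9)
        rec = synthesize_recording(plans[0], cfg, 9)
        cm = select_channels(rec)

        def ratio_at(label):
            idx = cm.labels.index(label)
            mi_p, base_p = [], []
            for _, ev in rec.events[(rec.events["segment"] == "MI")
                                    & (rec.events["label"] == "high")
                                    ].iterrows():
                i0 = int(round(ev["onset_s"] * cfg.fs))
                i1 = int(round((ev["onset_s"] + 6.0) * cfg.fs))
                mi_p.append(band_power(cm.data[idx, i0:i1], cfg.fs,
                                       cfg.mu_band))
                base_p.append(band_power(cm.data[idx, i0 - 1200:i0 - 400],
                                         cfg.fs, cfg.mu_band))
            return np.mean(mi_p) / np.mean(base_p)

        assert ratio_at("C3") < ratio_at("C1") < ratio_at("P4")


class TestEmgChannel:
    def test_me_iemg_dominates_mi_on_every_trial(self):
        from mfload.emg import iemg_table

        cfg = emg_config()
        plan = plan_sessions(0)[0]
        rec = synthesize_recording(plan, cfg, 0)
        table = iemg_table(rec)
        me = table[table["condition"].isin(["MEH", "MEL"])]
        mi = table[table["condition"].isin(["MIH", "MIL"])]
        merged = me.merge(mi, on="trial", suffixes=("_me", "_mi"))
        assert len(merged) == plan.n_trials
        assert (merged["iemg_me"] / merged["iemg_mi"] >= 5.0).all()

    def test_no_bursts_outside_me_when_amplitude_zero(self):
        cfg = emg_config(emg_burst_amplitude=0.0)
        plan = plan_sessions(0)[0]
        rec = synthesize_recording(plan, cfg, 0)
        emg = rec.channel("EMG")
        me = rec.events[rec.events["segment"] == "ME"].iloc[0]
        i0 = int(me["onset_s"] * cfg.fs)
        seg = emg[i0:i0 + 6000]
        rest = emg[:2000]
        assert seg.std() == pytest.approx(rest.std(), rel=0.25)


def test_simulate_subject_returns_requested_sessions():
    cfg = fast_config()
    recs = simulate_subject(cfg, 0, sessions=(4, 5))
    assert sorted(recs) == [4, 5]
    assert recs[5].events["session"].nunique() == 1
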