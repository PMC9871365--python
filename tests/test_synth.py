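import numpy as np
import pytest
from scipy.signal import welch

from stressmux.synth import (
    EffectSpec,
    RenderConfig,
    default_effect_specs,
    null_effect_specs,
    render_trial,
    simulate_beat_timeline,
    simulate_measure_panel,
    simulate_study,
    truth_profile,
)
from stressmux.synth.effects import default_eeg_band_effects


class TestEffectSpec:
    def test_h_bounds(self):
        with pytest.raises(ValueError):
            EffectSpec("X", 1.0, habituation_ratio=0.0)
        with pytest.raises(ValueError):
            EffectSpec("X", 1.0, habituation_ratio=1.2)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            EffectSpec("X", 1.0, noise_sd=-1.0)

    def test_truth_profile_control_is_flat(self, specs, protocol):
        prof = truth_profile(specs["HR"], protocol, trial=1, condition="control")
        assert np.allclose(prof, specs["HR"].baseline_level)

    def test_truth_profile_habituation_ratio(self, specs, protocol):
        s = specs["HR"]
        p1 = truth_profile(s, protocol, 1, "treatment")
        p5 = truth_profile(s, protocol, 5, "treatment")
        d1 = p1[100] - s.baseline_level
        d5 = p5[100] - s.baseline_level
        assert d5 / d1 == pytest.approx(s.habituation_ratio**4)

    def test_evoked_confined_to_immersion_and_rampout(self, specs, protocol):
        s = specs["LVET"]  # no anticipatory delta
        prof = truth_profile(s, protocol, 1, "treatment")
        assert np.allclose(prof[:65], s.baseline_level)
        assert np.allclose(prof[170:], s.baseline_level)  # after ramp-out
        assert prof[120] == pytest.approx(s.baseline_level + s.evoked_delta)


class TestBeatTimeline:
    def test_constant_hr_gives_unit_ibis(self, protocol):
        specs = {"HR": EffectSpec("HR", 60.0), "HF": EffectSpec("HF", -30.0)}
        bt = simulate_beat_timeline(specs, protocol, seed=0)
        ibis = np.diff(bt.r_times)
        assert np.allclose(ibis, 1.0, atol=1e-3)

    def test_hr_step_changes_beat_density(self, protocol):
        specs = {
            "HR": EffectSpec("HR", 60.0, evoked_delta=30.0, onset_lag_s=0, ramp_s=0),
            "HF": EffectSpec("HF", -30.0),
        }
        bt = simulate_beat_timeline(specs, protocol, condition="treatment", seed=0)
        rr = np.diff(bt.r_times)
        mid = (bt.r_times[:-1] + bt.r_times[1:]) / 2
        rr_before = rr[(mid > 5) & (mid < 60)].mean()
        rr_during = rr[(mid > 75) & (mid < 150)].mean()
        assert rr_before / rr_during == pytest.approx(90.0 / 60.0, rel=0.02)

    def test_determinism(self, specs, protocol):
        a = simulate_beat_timeline(specs, protocol, seed=42, rr_jitter_sd=0.01)
        b = simulate_beat_timeline(specs, protocol, seed=42, rr_jitter_sd=0.01)
        assert np.array_equal(a.r_times, b.r_times)
        assert np.array_equal(a.pep_ms, b.pep_ms)

    def test_nonpositive_rate_rejected(self, protocol):
        specs = {"HR": EffectSpec("HR", 10.0, evoked_delta=-20.0)}
        with pytest.raises(ValueError, match="positive"):
            simulate_beat_timeline(specs, protocol, condition="treatment", seed=0)


class TestRenderTrial:
    def test_channels_span_protocol(self, clean_trial, protocol):
        for name, ch in clean_trial.channels().items():
            n_expected = int(round(protocol.total_duration * ch.fs))
            length = ch.data.shape[-1]
            assert length == n_expected, name

    def test_b_lands_pep_after_q(self, beat_truth, clean_trial):
        # By construction B = Q + PEP; verify via the rendered dZ/dt onset.
        fs = clean_trial.dzdt.fs
        cfg = RenderConfig()
        k = 40
        r = beat_truth.r_times[k]
        q = r - cfg.q_offset_s
        b_expected = q + beat_truth.pep_ms[k] / 1000.0
        i0 = int((b_expected - 0.03) * fs)
        i1 = int((b_expected + 0.03) * fs)
        seg = clean_trial.dzdt.data[i0:i1]
        onset = i0 + np.flatnonzero(seg > 1e-6)[0]
        assert abs(onset / fs - b_expected) <= 1.5 / fs

    def test_blink_rate_zero_no_missing(self, clean_trial):
        assert not np.isnan(clean_trial.pupil_left.data).any()
        assert not np.isnan(clean_trial.pupil_right.data).any()

    def test_blinks_produce_missing_samples(self, noisy_trial):
        assert np.isnan(noisy_trial.pupil_left.data).any()

    def test_doubled_alpha_quadruples_welch_power(self, beat_truth, protocol):
        effs = default_eeg_band_effects()
        n_ch = len(RenderConfig().eeg_channels)
        base = {b: np.full((n_ch, 195), e.baseline_amp) for b, e in effs.items()}
        doubled = {b: a.copy() for b, a in base.items()}
        doubled["alpha"][3] *= 2.0
        ts_a = render_trial(beat_truth, protocol, seed=9, band_amp_truth=base)
        ts_b = render_trial(beat_truth, protocol, seed=9, band_amp_truth=doubled)
        fs = ts_a.eeg.fs
        f, p_a = welch(ts_a.eeg.data[3], fs=fs, nperseg=int(4 * fs))
        _, p_b = welch(ts_b.eeg.data[3], fs=fs, nperseg=int(4 * fs))
        sel = (f >= 9.5) & (f <= 10.5)
        ratio = p_b[sel].sum() / p_a[sel].sum()
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_eeg_rate_below_nyquist_rejected(self, beat_truth, protocol):
        cfg = RenderConfig(fs_eeg=30.0)
        with pytest.raises(ValueError, match="Nyquist"):
            render_trial(beat_truth, protocol, cfg, seed=0)

    def test_render_determinism(self, beat_truth, protocol):
        a = render_trial(beat_truth, protocol, seed=7)
        b = render_trial(beat_truth, protocol, seed=7)
        assert np.array_equal(a.ecg.data, b.ecg.data)
        assert np.array_equal(a.eeg.data, b.eeg.data)


class TestSimulateStudy:
    def test_bookkeeping(self, small_study):
        sessions, truth = small_study
        assert len(sessions) == 4  # 2 subjects x 2 conditions
        assert len(truth.cells()) == 2 * 2 * 5
        for sess in sessions:
            assert len(sess.trials) == 5

    def test_counterbalancing_and_start_times(self, small_study):
        sessions, truth = small_study
        orders = [truth.condition_order[s] for s in sorted(truth.condition_order)]
        assert orders[0] != orders[1]
        starts = {s.subject: s.start_time for s in sessions}
        assert set(starts.values()) == {"AM", "PM"}

    def test_t1_vs_t5_evoked_ratio(self, small_study):
        _, truth = small_study
        s = truth.specs["HR"]
        p1 = truth.profiles[("s000", "treatment", 1)]["HR"]
        p5 = truth.profiles[("s000", "treatment", 5)]["HR"]
        base = truth.subject_offsets["s000"]["HR"] + s.baseline_level
        assert (p5[110] - base) / (p1[110] - base) == pytest.approx(
            s.habituation_ratio**4
        )

    def test_pain_structure(self, small_study):
        sessions, _ = small_study
        for sess in sessions:
            assert all(0 <= p <= 100 for p in sess.pain_ratings)
            if sess.condition == "control":
                assert max(sess.pain_ratings) <= 5

    def test_cortisol_positive(self, small_study):
        sessions, _ = small_study
        for sess in sessions:
            assert len(sess.cortisol_samples) == 3
            assert all(c > 0 for c in sess.cortisol_samples)

    def test_n_subjects_minimum(self):
        with pytest.raises(ValueError):
            simulate_study(1, seed=0)

    def test_truth_only_mode(self):
        sessions, truth = simulate_study(2, seed=1, render=False)
        assert sessions == []
        assert len(truth.cells()) == 20


class TestMeasurePanelSim:
    def test_shapes_and_truth(self, null_specs):
        panel, truth = simulate_measure_panel("HR", 6, null_specs, seed=3)
        assert panel.values.shape == (6, 2, 5, 195)
        assert truth.shape == panel.values.shape
        resid = panel.values - truth
        assert abs(resid.mean()) < 0.1
        assert np.std(resid) == pytest.approx(null_specs["HR"].noise_sd, rel=0.05)

    def test_null_config_conditions_identically_distributed(self, null_specs):
        panel, truth = simulate_measure_panel("HR", 20, null_specs, seed=4)
        # truth identical across conditions under the null config
        assert np.array_equal(truth[:, 0], truth[:, 1])

    def test_determinism(self, specs):
        a, _ = simulate_measure_panel("HR", 4, specs, seed=9)
        b, _ = simulate_measure_panel("HR", 4, specs, seed=9)
        assert np.array_equal(a.values, b.values)


def test_construction_consistency_noiseless(clean_trial, beat_truth):
    """Extracting fiducials from a noiseless render recovers truth."""
    from stressmux import cardio
    from .conftest import per_beat_truth_errors

    fs = clean_trial.ecg.fs
    r = cardio.detect_r_peaks(clean_trial.ecg.data, fs)
    assert abs(r.size - beat_truth.n_beats) <= 1
    fid = cardio.locate_fiducials(clean_trial.ecg.data, clean_trial.dzdt.data, r, fs)
    pep_err, lvet_err = per_beat_truth_errors(fid, beat_truth)
    sample_ms = 1000.0 / fs
    assert np.max(pep_err) <= sample_ms
    assert np.max(lvet_err) <= sample_ms
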