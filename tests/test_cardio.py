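import numpy as np
import pytest

from stressmux import cardio
from stressmux.core import ContinuousMeasure
from stressmux.synth import BeatTruth, RenderConfig, render_trial

from .conftest import per_beat_truth_errors
from .oracles import moving_average


def _flat_truth(pep=80.0, lvet=290.0, sv=40.0, rr=0.9):
    r = np.arange(5.0, 190.0, rr)
    n = r.size
    return BeatTruth(
        r_times=r,
        pep_ms=np.full(n, pep),
        lvet_ms=np.full(n, lvet),
        sv_ml=np.full(n, sv),
        profiles={},
    )


@pytest.fixture(scope="module")
def flat_trial(protocol, clean_cfg):
    truth = _flat_truth()
    return truth, render_trial(truth, protocol, clean_cfg, seed=0)


class TestDetectRPeaks:
    def test_recovers_true_beats(self, clean_trial, beat_truth):
        fs = clean_trial.ecg.fs
        r = cardio.detect_r_peaks(clean_trial.ecg.data, fs)
        assert abs(r.size - beat_truth.n_beats) <= 1
        err = np.abs(r[:, None] - beat_truth.r_times[None, :]).min(axis=1)
        assert err.max() <= 1.0 / fs + 1e-9

    def test_flatline_returns_empty(self):
        assert cardio.detect_r_peaks(np.zeros(250 * 40), 250.0).size == 0

    def test_polarity_robust(self, clean_trial):
        fs = clean_trial.ecg.fs
        r_pos = cardio.detect_r_peaks(clean_trial.ecg.data, fs)
        r_neg = cardio.detect_r_peaks(-clean_trial.ecg.data, fs)
        assert np.array_equal(r_pos, r_neg)

    def test_refractory_spacing(self, noisy_trial):
        r = cardio.detect_r_peaks(noisy_trial.ecg.data, noisy_trial.ecg.fs)
        assert np.all(np.diff(r) >= cardio.REFRACTORY_S - 1e-9)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="30 s"):
            cardio.detect_r_peaks(np.zeros(250 * 10), 250.0)


class TestLocateFiducials:
    def test_noiseless_recovery_within_one_sample(self, flat_trial):
        truth, ts = flat_trial
        fs = ts.ecg.fs
        r = cardio.detect_r_peaks(ts.ecg.data, fs)
        fid = cardio.locate_fiducials(ts.ecg.data, ts.dzdt.data, r, fs)
        pep_err, lvet_err = per_beat_truth_errors(fid, truth)
        assert np.max(pep_err) <= 1000.0 / fs
        assert np.max(lvet_err) <= 1000.0 / fs

    def test_edge_beat_invalid(self, flat_trial):
        truth, ts = flat_trial
        fs = ts.ecg.fs
        # A fake beat at the very start has no Q window -> invalid.
        fid = cardio.locate_fiducials(ts.ecg.data, ts.dzdt.data, np.array([0.01]), fs)
        assert not fid.loc[0, "valid"]

    def test_invalid_rows_carry_nan(self, flat_trial):
        truth, ts = flat_trial
        fid = cardio.locate_fiducials(
            ts.ecg.data, ts.dzdt.data, np.array([0.01]), ts.ecg.fs
        )
        assert np.isnan(fid.loc[0, "pep_ms"])

    def test_ordering_invariant(self, noisy_trial):
        fs = noisy_trial.ecg.fs
        r = cardio.detect_r_peaks(noisy_trial.ecg.data, fs)
        fid = cardio.locate_fiducials(noisy_trial.ecg.data, noisy_trial.dzdt.data, r, fs)
        ok = fid[fid["valid"]]
        assert (ok["q_time"] < ok["b_time"]).all()
        assert (ok["b_time"] < ok["x_time"]).all()


class TestMovingEnsemble:
    def test_identical_beats_give_template_values(self, flat_trial):
        truth, ts = flat_trial
        fs = ts.ecg.fs
        r = cardio.detect_r_peaks(ts.ecg.data, fs)
        ens = cardio.moving_ensemble(ts.ecg.data, ts.dzdt.data, r, fs)
        mid = ens.loc[30:160]
        assert mid["valid"].all()
        assert np.allclose(mid["pep_ms"], 80.0, atol=1000.0 / fs)
        assert np.allclose(mid["lvet_ms"], 290.0, atol=2 * 1000.0 / fs)

    def test_alternating_pep_averages_out(self, protocol, clean_cfg):
        # +/-4 ms alternation stays within the template's smoothing width,
        # so the ensemble reads the mean level.
        truth = _flat_truth()
        truth.pep_ms[::2] = 76.0
        truth.pep_ms[1::2] = 84.0
        ts = render_trial(truth, protocol, clean_cfg, seed=1)
        fs = ts.ecg.fs
        r = cardio.detect_r_peaks(ts.ecg.data, fs)
        ens = cardio.moving_ensemble(ts.ecg.data, ts.dzdt.data, r, fs)
        mid = ens.loc[30:160]
        assert np.nanmean(mid["pep_ms"]) == pytest.approx(80.0, abs=1.5 * 1000 / fs)

    def test_step_is_monotone_and_bounded(self, protocol, clean_cfg):
        truth = _flat_truth()
        step_at = 100.0
        truth.pep_ms[truth.r_times >= step_at] = 84.0
        truth.pep_ms[truth.r_times < step_at] = 76.0
        ts = render_trial(truth, protocol, clean_cfg, seed=2)
        fs = ts.ecg.fs
        r = cardio.detect_r_peaks(ts.ecg.data, fs)
        ens = cardio.moving_ensemble(ts.ecg.data, ts.dzdt.data, r, fs)
        window = ens.loc[90:110, "pep_ms"].to_numpy()
        tol = 1.2 * 1000.0 / fs
        assert window.min() >= 76.0 - tol
        assert window.max() <= 84.0 + tol
        assert ens.loc[85, "pep_ms"] < ens.loc[115, "pep_ms"]

    def test_mask_when_too_few_beats(self, protocol, clean_cfg):
        truth = _flat_truth()
        ts = render_trial(truth, protocol, clean_cfg, seed=3)
        fs = ts.ecg.fs
        # Only one beat provided -> every window below 2 beats.
        ens = cardio.moving_ensemble(
            ts.ecg.data, ts.dzdt.data, np.array([100.0]), fs
        )
        assert not ens["valid"].any()

    def test_tracks_moving_average_of_per_beat_pep(self, noisy_trial, beat_truth):
        fs = noisy_trial.ecg.fs
        r = cardio.detect_r_peaks(noisy_trial.ecg.data, fs)
        ens = cardio.moving_ensemble(noisy_trial.ecg.data, noisy_trial.dzdt.data, r, fs)
        oracle = moving_average(
            beat_truth.r_times, beat_truth.pep_ms, np.arange(195), 15.0
        )
        sel = ens["valid"].to_numpy() & np.isfinite(oracle)
        diff = np.abs(ens["pep_ms"].to_numpy()[sel] - oracle[sel])
        assert np.median(diff) <= 4.0  # within noise of the truth average


class TestBeatMeasures:
    def test_co_formula(self):
        import pandas as pd

        table = pd.DataFrame(
            dict(
                r_time=[1.0, 2.0, 3.0],
                q_time=[0.95, 1.95, 2.95],
                b_time=[1.03, 2.03, 3.03],
                x_time=[1.32, 2.32, 3.32],
                pep_ms=[80.0] * 3,
                lvet_ms=[290.0] * 3,
                dzdt_max=[1.0] * 3,
                valid=[True] * 3,
            )
        )
        fs = 250.0
        z0 = np.full(int(4 * fs), 30.0)
        cal = cardio.CalibrationConstants()
        out = cardio.beat_measures(table, None, z0, fs, cal)
        # HR = 60 bpm everywhere (RR = 1 s)
        assert out["hr"].iloc[0] == pytest.approx(60.0)
        sv = cal.rho_ohm_cm * (cal.electrode_l_cm / 30.0) ** 2 * 0.29 * 1.0
        assert out["sv_ml"].iloc[0] == pytest.approx(sv)
        assert out["co_lmin"].iloc[0] == pytest.approx(60.0 * sv / 1000.0)

    def test_sv_linear_in_dzdt_max(self):
        cal = cardio.CalibrationConstants()
        sv1 = cardio.kubicek_sv(290.0, 1.0, 30.0, cal)
        sv2 = cardio.kubicek_sv(290.0, 2.0, 30.0, cal)
        assert sv2 == pytest.approx(2 * sv1)

    def test_hr_sv_co_conservation(self, flat_trial):
        truth, ts = flat_trial
        fs = ts.ecg.fs
        r = cardio.detect_r_peaks(ts.ecg.data, fs)
        fid = cardio.locate_fiducials(ts.ecg.data, ts.dzdt.data, r, fs)
        out = cardio.beat_measures(fid, ts.dzdt.data, ts.z0.data, fs)
        ok = out["valid"] & np.isfinite(out["co_lmin"])
        assert np.allclose(
            out.loc[ok, "co_lmin"],
            out.loc[ok, "hr"] * out.loc[ok, "sv_ml"] / 1000.0,
        )

    def test_sv_recovery_against_generator(self, flat_trial):
        truth, ts = flat_trial
        fs = ts.ecg.fs
        r = cardio.detect_r_peaks(ts.ecg.data, fs)
        fid = cardio.locate_fiducials(ts.ecg.data, ts.dzdt.data, r, fs)
        out = cardio.beat_measures(fid, ts.dzdt.data, ts.z0.data, fs)
        ok = out["valid"] & np.isfinite(out["sv_ml"])
        assert np.nanmedian(out.loc[ok, "sv_ml"]) == pytest.approx(40.0, rel=0.05)


class TestPressureMeasures:
    def test_map_formula(self):
        assert 60 + (120 - 60) / 3.0 == 80.0  # MAP identity used below
        fs = 250.0
        t = np.arange(int(fs * 40)) / fs
        bp = 60 + 60 * 0.5 * (1 - np.cos(2 * np.pi * 1.0 * t))  # 1 Hz pulses
        pulses = cardio.pressure_measures(bp, fs)
        ok = pulses[pulses["valid"]]
        assert np.allclose(ok["sbp"], 120.0, atol=0.1)
        assert np.allclose(ok["dbp"], 60.0, atol=0.1)
        assert np.allclose(ok["map"], 80.0, atol=0.1)

    def test_tpr_formula(self):
        m = ContinuousMeasure("MAP", np.full(195, 80.0), np.ones(195, bool))
        c = ContinuousMeasure("CO", np.full(195, 2.0), np.ones(195, bool))
        tpr = cardio.tpr_series(m, c)
        assert np.allclose(tpr.values[tpr.mask], 3200.0)

    def test_constant_map_profile_recovered(self, flat_trial, protocol):
        truth, ts = flat_trial
        fs = ts.bp.fs
        pulses = cardio.pressure_measures(ts.bp.data, fs)
        ok = pulses[pulses["valid"]]
        m = cardio.window_average_series(
            ok["t"].to_numpy(), ok["map"].to_numpy(), protocol, name="MAP"
        )
        assert np.allclose(m.values[m.mask][5:-5], 80.0, atol=0.5)


class TestRespiration:
    def test_phase_advances_2pi_per_cycle(self):
        fs = 250.0
        t = np.arange(int(fs * 120)) / fs
        z0 = 30 + 0.2 * np.sin(2 * np.pi * 0.25 * t)
        resp, _ = cardio.estimate_respiration(z0, fs)
        from scipy.signal import hilbert

        phase = np.unwrap(np.angle(hilbert(resp)))
        seg = phase[int(20 * fs) : int(100 * fs)]
        rate = (seg[-1] - seg[0]) / 80.0
        assert rate == pytest.approx(2 * np.pi * 0.25, rel=0.02)

    def test_state_zscored(self):
        fs = 250.0
        t = np.arange(int(fs * 195)) / fs
        z0 = 30 + 0.2 * np.sin(2 * np.pi * 0.25 * t)
        r_times = np.arange(1.0, 190.0, 0.8)
        _, st = cardio.estimate_respiration(z0, fs, r_times)
        assert st.state.mean() == pytest.approx(0.0, abs=1e-9)
        assert st.state.std() == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_doubles_magnitude(self):
        fs = 250.0
        t = np.arange(int(fs * 195)) / fs
        r_times = np.arange(1.0, 190.0, 0.8)
        _, st1 = cardio.estimate_respiration(
            30 + 0.2 * np.sin(2 * np.pi * 0.25 * t), fs, r_times
        )
        _, st2 = cardio.estimate_respiration(
            30 + 0.4 * np.sin(2 * np.pi * 0.25 * t), fs, r_times
        )
        ratio = st2.magnitude.mean() / st1.magnitude.mean()
        assert ratio == pytest.approx(2.0, rel=0.02)
        # Phase unchanged.
        assert np.allclose(st1.phase, st2.phase, atol=1e-6)

    def test_constant_z0_warns(self):
        with pytest.warns(UserWarning, match="constant Z0"):
            resp, st = cardio.estimate_respiration(np.full(250 * 70, 30.0), 250.0)
        assert st is None

    def test_short_z0_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            cardio.estimate_respiration(np.zeros(250 * 30), 250.0)


class TestRespirationCorrect:
    def test_exact_linear_removal(self):
        rng = np.random.default_rng(0)
        state = rng.normal(size=200)
        state -= state.mean()  # states are z-scored in practice
        series = 2.0 * state + 5.0
        out = cardio.respiration_correct(series, state)
        assert np.allclose(out, 5.0, atol=1e-10)

    def test_orthogonal_state_no_change(self):
        rng = np.random.default_rng(1)
        series = rng.normal(size=500)
        state = rng.normal(size=500)
        out = cardio.respiration_correct(series, state)
        # With near-orthogonal state the change is tiny.
        assert np.corrcoef(out, series)[0, 1] > 0.99

    def test_residual_uncorrelated_with_state(self):
        rng = np.random.default_rng(2)
        state = rng.normal(size=300)
        series = 1.5 + 0.8 * state + rng.normal(0, 0.1, 300)
        out = cardio.respiration_correct(series, state)
        assert abs(np.corrcoef(out, state)[0, 1]) < 1e-8
        assert out.mean() == pytest.approx(series.mean())

    def test_constant_state_warns(self):
        series = np.arange(20.0)
        with pytest.warns(UserWarning, match="constant"):
            out = cardio.respiration_correct(series, np.ones(20))
        assert np.array_equal(out, series)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="10"):
            cardio.respiration_correct(np.ones(5), np.arange(5.0))


class TestResample1Hz:
    def test_length_195(self, protocol):
        out = cardio.resample_1hz(np.array([0.0, 100.0, 194.0]), np.ones(3), protocol)
        assert len(out) == 195

    def test_identity_on_grid(self, protocol):
        t = np.arange(195.0)
        v = np.sin(t / 10)
        out = cardio.resample_1hz(t, v, protocol)
        assert np.allclose(out.values[out.mask], v)

    def test_linear_ramp_exact(self, protocol):
        t = np.array([0.0, 194.0])
        out = cardio.resample_1hz(t, 2.0 * t + 1.0, protocol)
        grid = np.arange(195.0)
        assert np.allclose(out.values, 2.0 * grid + 1.0)

    def test_extrapolation_masked(self, protocol):
        out = cardio.resample_1hz(np.array([50.0, 100.0]), np.array([1.0, 2.0]), protocol)
        assert not out.mask[:50].any()
        assert not out.mask[101:].any()
        assert out.mask[50:101].all()

    def test_too_few_points_fully_masked(self, protocol):
        out = cardio.resample_1hz(np.array([50.0]), np.array([1.0]), protocol)
        assert not out.mask.any()


def test_noisy_fiducial_mae(noisy_trial, beat_truth):
    """Default-noise recovery: median absolute error <= 4 ms."""
    fs = noisy_trial.ecg.fs
    r = cardio.detect_r_peaks(noisy_trial.ecg.data, fs)
    fid = cardio.locate_fiducials(noisy_trial.ecg.data, noisy_trial.dzdt.data, r, fs)
    pep_err, lvet_err = per_beat_truth_errors(fid, beat_truth)
    assert np.median(pep_err) <= 4.0
    assert np.median(lvet_err) <= 4.0
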