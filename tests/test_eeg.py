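import numpy as np
import pytest

from stressmux.eeg import (
    BANDS,
    PERIODS,
    EEGRecording,
    RecordingRejectedError,
    compute_ersp,
    detect_bad_channels,
    preprocess_raw,
    reduce_band_period,
    rereference_interpolate,
    spherical_spline_interpolate,
    standard_positions,
)
from stressmux.synth import DEFAULT_EEG_CHANNELS


@pytest.fixture(scope="module")
def clean_rec(noisy_trial):
    return EEGRecording(
        names=tuple(noisy_trial.eeg_channels),
        data=noisy_trial.eeg.data.copy(),
        fs=noisy_trial.eeg.fs,
    )


class TestBadChannels:
    def test_clean_montage_empty(self, clean_rec):
        assert detect_bad_channels(clean_rec) == []

    def test_flatline_flagged(self, clean_rec):
        data = clean_rec.data.copy()
        fs = int(clean_rec.fs)
        data[2, 10 * fs : 16 * fs] = data[2, 10 * fs]  # 6-s flat run
        rec = EEGRecording(clean_rec.names, data, clean_rec.fs)
        assert clean_rec.names[2] in detect_bad_channels(rec)

    def test_amplitude_outlier_flagged(self, clean_rec):
        data = clean_rec.data.copy()
        data[5] *= 10.0
        rec = EEGRecording(clean_rec.names, data, clean_rec.fs)
        assert clean_rec.names[5] in detect_bad_channels(rec)

    def test_decorrelated_channel_flagged(self, clean_rec):
        rng = np.random.default_rng(0)
        data = clean_rec.data.copy()
        data[7] = rng.normal(0, data[7].std(), data.shape[1])
        rec = EEGRecording(clean_rec.names, data, clean_rec.fs)
        assert clean_rec.names[7] in detect_bad_channels(rec)

    def test_deterministic(self, clean_rec):
        data = clean_rec.data.copy()
        data[5] *= 10.0
        rec = EEGRecording(clean_rec.names, data, clean_rec.fs)
        assert detect_bad_channels(rec) == detect_bad_channels(rec)

    def test_too_few_channels_rejected(self):
        rec = EEGRecording(("Fz", "Cz", "Pz"), np.zeros((3, 100)), 250.0)
        with pytest.raises(ValueError, match="8 channels"):
            detect_bad_channels(rec)


class TestRereferenceInterpolate:
    def test_good_channel_mean_zero(self, clean_rec):
        out = rereference_interpolate(clean_rec, [])
        assert np.allclose(out.data.mean(axis=0), 0.0, atol=1e-9)

    def test_constant_field_interpolation(self):
        names = DEFAULT_EEG_CHANNELS
        data = np.full((len(names), 500), 5.0)
        data[3] = 99.0  # corrupted channel amid a uniform field
        rec = EEGRecording(names, data, 250.0)
        out = rereference_interpolate(rec, [names[3]])
        # After average-referencing the field is 0; interpolation must match.
        assert np.allclose(out.data[3], out.data[0], atol=1e-6)

    def test_smooth_gradient_leave_one_out(self):
        names = DEFAULT_EEG_CHANNELS
        pos = standard_positions(names)
        rng = np.random.default_rng(1)
        w = rng.normal(size=3)
        field = pos @ w  # smooth linear-in-xyz scalp field
        data = np.tile(field[:, None], (1, 200))
        held_out = 7
        interp = spherical_spline_interpolate(
            np.delete(pos, held_out, axis=0),
            pos[held_out : held_out + 1],
            np.delete(data, held_out, axis=0),
        )
        err = np.abs(interp[0] - field[held_out]).max()
        scale = np.abs(field).max()
        assert err < 0.15 * scale

    def test_majority_bad_rejected(self, clean_rec):
        bads = list(clean_rec.names[:9])
        with pytest.raises(RecordingRejectedError):
            rereference_interpolate(clean_rec, bads)


class TestERSP:
    def test_pure_tone_concentration(self):
        fs = 250.0
        t = np.arange(int(fs * 195)) / fs
        data = np.tile(5.0 * np.sin(2 * np.pi * 10.0 * t), (8, 1))
        rec = EEGRecording(DEFAULT_EEG_CHANNELS[:8], data, fs)
        grid = compute_ersp(rec)
        p = np.nanmean(grid.power[0], axis=-1)
        i10 = int(np.flatnonzero(grid.freqs == 10.0)[0])
        far = p[np.abs(grid.freqs - 10.0) > 3]
        assert 10 * np.log10(p[i10] / far.max()) > 20.0

    def test_stationary_signal_near_zero_db(self, clean_rec):
        # For a stationary signal the mean-power ratio to baseline is ~1
        # (0 dB); per-frame log values scatter below it by the usual
        # log-of-chi-square bias, so the ratio of means is the contract.
        grid = compute_ersp(clean_rec)
        post = np.nanmean(grid.power[:, :, 41:], axis=-1)
        base = np.nanmean(grid.power[:, :, 1:41], axis=-1)
        db = 10 * np.log10(post / base)
        assert abs(np.nanmean(db)) < 0.5

    def test_doubled_alpha_reads_6db(self, beat_truth, protocol):
        from stressmux.synth import render_trial
        from stressmux.synth.effects import default_eeg_band_effects

        effs = default_eeg_band_effects()
        amp = {b: np.full((16, 195), e.baseline_amp) for b, e in effs.items()}
        amp["alpha"][0, 65:155] *= 2.0
        ts = render_trial(beat_truth, protocol, seed=21, band_amp_truth=amp)
        rec = EEGRecording(tuple(ts.eeg_channels), ts.eeg.data, ts.eeg.fs)
        grid = compute_ersp(rec, protocol)
        i10 = int(np.flatnonzero(grid.freqs == 10.0)[0])
        base = float(np.nanmean(grid.power[0, i10, 1:41]))
        db_imm = 10 * np.log10(np.nanmean(grid.power[0, i10, 65:155]) / base)
        db_elsewhere = 10 * np.log10(np.nanmean(grid.power[0, i10, 41:60]) / base)
        assert db_imm == pytest.approx(10 * np.log10(4.0), abs=0.5)
        assert abs(db_elsewhere) < 0.75

    def test_low_rate_rejected(self):
        rec = EEGRecording(DEFAULT_EEG_CHANNELS[:8], np.zeros((8, 50 * 40)), 50.0)
        with pytest.raises(ValueError, match="Nyquist"):
            compute_ersp(rec)


class TestReduceBandPeriod:
    def test_band_and_period_bin_counts(self):
        assert BANDS["alpha"] == (8, 14)  # 7 bins
        freqs = np.arange(1, 31)
        assert ((freqs >= 8) & (freqs <= 14)).sum() == 7
        lo, hi = PERIODS["early"]
        assert hi - lo + 1 == 30

    def test_constant_grid(self, clean_rec):
        grid = compute_ersp(clean_rec)
        grid.power[:] = 10.0
        grid.db[:] = 3.0
        df = reduce_band_period(grid)
        non_base = df[df.period != "baseline"]
        assert np.allclose(non_base["value"], 3.0)
        base = df[df.period == "baseline"]
        assert np.allclose(base["value"], 10.0)  # 10*log10(10)

    def test_row_count(self, clean_rec):
        df = reduce_band_period(compute_ersp(clean_rec))
        assert len(df) == len(clean_rec.names) * len(BANDS) * len(PERIODS)


class TestFilters:
    def test_notch_removes_60hz(self):
        fs = 250.0
        t = np.arange(int(fs * 60)) / fs
        data = np.tile(
            np.sin(2 * np.pi * 60.0 * t) + np.sin(2 * np.pi * 10.0 * t), (8, 1)
        )
        rec = EEGRecording(DEFAULT_EEG_CHANNELS[:8], data, fs)
        out = preprocess_raw(rec, highpass_hz=0.0)
        spec = np.abs(np.fft.rfft(out.data[0]))
        freqs = np.fft.rfftfreq(out.data.shape[1], 1 / fs)
        p60 = spec[np.argmin(np.abs(freqs - 60.0))]
        p10 = spec[np.argmin(np.abs(freqs - 10.0))]
        assert p60 < 0.05 * p10

    def test_highpass_removes_drift(self):
        fs = 250.0
        t = np.arange(int(fs * 60)) / fs
        data = np.tile(50.0 * t / t.max() + np.sin(2 * np.pi * 10.0 * t), (8, 1))
        rec = EEGRecording(DEFAULT_EEG_CHANNELS[:8], data, fs)
        out = preprocess_raw(rec, notch_hz=0.0)
        # Drift gone: mean of first vs last quarter nearly equal.
        q = out.data.shape[1] // 4
        assert abs(out.data[0][:q].mean() - out.data[0][-q:].mean()) < 0.5
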