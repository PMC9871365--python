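"""End-to-end extraction: raw trial signals -> 1-Hz measure panels.

Per trial: R-peak detection, 15-s moving-ensemble fiducials, Kubicek
stroke volume, pulse-pressure measures, trailing-window HF, pupil
binning. Per subject: respiratory state pooled across every trial of both
sessions and regressed out of each cardiovascular series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cardio, eeg, hrv, pupil
from .core import CONDITIONS, ContinuousMeasure, MeasurePanel
from .protocol import ProtocolDefinition, make_default_protocol
from .synth.render import TrialSignalSet
from .synth.study import SessionDataset

__all__ = ["ExtractionConfig", "extract_trial", "extract_study", "eeg_band_panel"]

CARDIO_MEASURES = ("HR", "PEP", "LVET", "SV", "CO", "MAP", "SBP", "DBP", "TPR", "HF")


@dataclass(frozen=True)
class ExtractionConfig:
    cal: cardio.CalibrationConstants = field(
        default_factory=cardio.CalibrationConstants
    )
    respiration_corrected: tuple[str, ...] = CARDIO_MEASURES
    hf_window_s: float = 32.0
    hf_band: tuple[float, float] = hrv.HF_BAND
    hf_min_beats: int = 8
    ensemble_window_s: float = 15.0


def _grid_state(
    state: cardio.RespirationState | None, protocol: ProtocolDefinition
) -> np.ndarray | None:
    """Beat-level respiratory state linearly interpolated onto the 1-Hz grid."""
    if state is None or state.state is None:
        return None
    grid = np.arange(protocol.n_seconds, dtype=float)
    return np.interp(grid, state.r_times, state.state)


def extract_trial(
    trial_set: TrialSignalSet,
    protocol: ProtocolDefinition | None = None,
    config: ExtractionConfig | None = None,
) -> tuple[dict[str, ContinuousMeasure], np.ndarray | None]:
    """All 1-Hz measures for one trial, before respiration correction.

    Returns ``(measures, respiration_state_on_grid)``. A trial whose ECG
    yields no beats produces fully masked series.
    """
    protocol = protocol or make_default_protocol()
    cfg = config or ExtractionConfig()
    fs = trial_set.ecg.fs
    n_sec = protocol.n_seconds
    empty = lambda name, units="": ContinuousMeasure(  # noqa: E731
        name, np.full(n_sec, np.nan), np.zeros(n_sec, bool), units
    )
    out: dict[str, ContinuousMeasure] = {}

    r_times = cardio.detect_r_peaks(trial_set.ecg.data, fs)
    if r_times.size < 2:
        for m in CARDIO_MEASURES:
            out[m] = empty(m)
        out["PUPIL"] = pupil.preprocess_pupil(
            pupil.PupilTrace(
                trial_set.pupil_left.data,
                trial_set.pupil_right.data,
                trial_set.pupil_left.fs,
            ),
            protocol,
        )
        return out, None

    ens = cardio.moving_ensemble(
        trial_set.ecg.data,
        trial_set.dzdt.data,
        r_times,
        fs,
        protocol,
        window_s=cfg.ensemble_window_s,
    )
    valid = ens["valid"].to_numpy()
    z0 = trial_set.z0.data
    # Windowed Z0 mean per grid second for the Kubicek formula.
    half = cfg.ensemble_window_s / 2.0
    z0_t = np.arange(z0.size) / fs
    z0_win = np.array(
        [
            float(np.mean(z0[(z0_t >= t - half) & (z0_t < t + half)]))
            for t in range(n_sec)
        ]
    )
    hr = ens["hr"].to_numpy()
    sv = np.where(
        valid,
        cardio.kubicek_sv(
            ens["lvet_ms"].to_numpy(), ens["dzdt_max"].to_numpy(), z0_win, cfg.cal
        ),
        np.nan,
    )
    co = hr * sv / 1000.0
    hr_mask = np.isfinite(hr)
    out["HR"] = ContinuousMeasure("HR", hr, hr_mask, "bpm")
    out["PEP"] = ContinuousMeasure("PEP", ens["pep_ms"].to_numpy(), valid, "ms")
    out["LVET"] = ContinuousMeasure("LVET", ens["lvet_ms"].to_numpy(), valid, "ms")
    out["SV"] = ContinuousMeasure("SV", sv, valid, "mL")
    out["CO"] = ContinuousMeasure("CO", co, valid & hr_mask, "L/min")

    pulses = cardio.pressure_measures(trial_set.bp.data, fs)
    pulses = pulses[pulses["valid"]]
    for name, col, units in (
        ("SBP", "sbp", "mmHg"),
        ("DBP", "dbp", "mmHg"),
        ("MAP", "map", "mmHg"),
    ):
        out[name] = cardio.window_average_series(
            pulses["t"].to_numpy(),
            pulses[col].to_numpy(),
            protocol,
            window_s=cfg.ensemble_window_s,
            name=name,
            units=units,
        )
    out["TPR"] = cardio.tpr_series(out["MAP"], out["CO"])

    out["HF"] = hrv.hf_timecourse(
        r_times,
        protocol,
        window_s=cfg.hf_window_s,
        band=cfg.hf_band,
        min_beats=cfg.hf_min_beats,
    )

    out["PUPIL"] = pupil.preprocess_pupil(
        pupil.PupilTrace(
            trial_set.pupil_left.data,
            trial_set.pupil_right.data,
            trial_set.pupil_left.fs,
        ),
        protocol,
    )

    _, resp_state = cardio.estimate_respiration(z0, fs, r_times)
    return out, _grid_state(resp_state, protocol)


def extract_study(
    sessions: list[SessionDataset],
    protocol: ProtocolDefinition | None = None,
    config: ExtractionConfig | None = None,
) -> dict[str, MeasurePanel]:
    """Extract every session into per-measure subject panels.

    Respiration correction is applied per subject per measure by pooling
    that subject's trials from both sessions into one OLS fit.
    """
    protocol = protocol or make_default_protocol()
    cfg = config or ExtractionConfig()
    n_sec = protocol.n_seconds
    subjects = sorted({s.subject for s in sessions})
    s_idx = {s: i for i, s in enumerate(subjects)}
    measures = CARDIO_MEASURES + ("PUPIL",)
    vals = {
        m: np.full((len(subjects), 2, 5, n_sec), np.nan) for m in measures
    }
    states = np.full((len(subjects), 2, 5, n_sec), np.nan)

    for sess in sessions:
        si = s_idx[sess.subject]
        ci = CONDITIONS.index(sess.condition)
        for trial_set in sess.trials:
            ms, state = extract_trial(trial_set, protocol, cfg)
            k = trial_set.trial - 1
            for m in measures:
                vals[m][si, ci, k] = ms[m].values
            if state is not None:
                states[si, ci, k] = state

    # Correct the primary series, then re-derive CO and TPR from their
    # corrected parents so CO = HR*SV/1000 and TPR = 80*MAP/CO stay exact.
    derived = {"CO", "TPR"}
    for m in cfg.respiration_corrected:
        if m not in vals or m in derived:
            continue
        for si in range(len(subjects)):
            v = vals[m][si].ravel()
            st = states[si].ravel()
            ok = np.isfinite(v) & np.isfinite(st)
            if ok.sum() >= 10 and np.std(st[ok]) > 1e-12:
                vals[m][si] = cardio.respiration_correct(v, st).reshape(
                    vals[m][si].shape
                )
    vals["CO"] = np.where(
        np.isfinite(vals["CO"]), vals["HR"] * vals["SV"] / 1000.0, np.nan
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        vals["TPR"] = np.where(
            np.isfinite(vals["TPR"]), 80.0 * vals["MAP"] / vals["CO"], np.nan
        )

    return {
        m: MeasurePanel(measure=m, values=vals[m], subjects=subjects)
        for m in measures
    }


def eeg_band_panel(
    sessions: list[SessionDataset],
    protocol: ProtocolDefinition | None = None,
    run_qc: bool = True,
) -> pd.DataFrame:
    """Tidy EEG band x period panel across a study.

    Per trial: optional bad-channel QC, average-reference +
    spherical-spline interpolation, ERSP, band/period reduction.
    """
    protocol = protocol or make_default_protocol()
    rows = []
    for sess in sessions:
        for trial_set in sess.trials:
            rec = eeg.EEGRecording(
                names=tuple(trial_set.eeg_channels),
                data=trial_set.eeg.data,
                fs=trial_set.eeg.fs,
            )
            bads = eeg.detect_bad_channels(rec) if run_qc else []
            rec = eeg.rereference_interpolate(rec, bads)
            grid = eeg.compute_ersp(rec, protocol)
            df = eeg.reduce_band_period(grid)
            df.insert(0, "subject", sess.subject)
            df.insert(1, "condition", sess.condition)
            df.insert(2, "trial", trial_set.trial)
            rows.append(df)
    return pd.concat(rows, ignore_index=True)
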