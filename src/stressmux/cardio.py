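"""Beat-level cardiovascular extraction from ECG / impedance / pressure.

Fiducial rules: R peaks by adaptive-threshold peak picking with a 250-ms
refractory period; Q as the local ECG minimum in a short window before R;
B as the maximal second derivative of dZ/dt between R and the dZ/dt peak;
X as the global dZ/dt minimum (incisura) after the peak. Stroke volume uses
the Kubicek formula SV = rho * (L/Z0)^2 * LVET * max(dZ/dt). A 15-s moving
ensemble average yields continuous 1-Hz estimates; respiration state
(phase x magnitude of the band-passed Z0) is regressed out of every
cardiovascular series per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .core import ContinuousMeasure
from .protocol import ProtocolDefinition, make_default_protocol

__all__ = [
    "CalibrationConstants",
    "RespirationState",
    "detect_r_peaks",
    "locate_fiducials",
    "moving_ensemble",
    "beat_measures",
    "pressure_measures",
    "tpr_series",
    "estimate_respiration",
    "respiration_correct",
    "resample_1hz",
    "window_average_series",
    "kubicek_sv",
]

REFRACTORY_S = 0.25


@dataclass(frozen=True)
class CalibrationConstants:
    """Kubicek stroke-volume calibration."""

    rho_ohm_cm: float = 135.0
    electrode_l_cm: float = 30.0

    def __post_init__(self) -> None:
        if self.rho_ohm_cm <= 0 or self.electrode_l_cm <= 0:
            raise ValueError("calibration constants must be positive")


@dataclass
class RespirationState:
    """Per-beat respiratory covariate: z-scored phase x magnitude."""

    r_times: np.ndarray
    phase: np.ndarray
    magnitude: np.ndarray
    state: np.ndarray | None  # None when respiration was degenerate


def kubicek_sv(
    lvet_ms: float | np.ndarray,
    dzdt_max: float | np.ndarray,
    z0_ohm: float | np.ndarray,
    cal: CalibrationConstants,
) -> float | np.ndarray:
    return (
        cal.rho_ohm_cm
        * (cal.electrode_l_cm / z0_ohm) ** 2
        * (np.asarray(lvet_ms) / 1000.0)
        * dzdt_max
    )


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak times (s), polarity-robust, >= 250 ms apart.

    Returns an empty array (flagged trial) when no peak clears the adaptive
    threshold.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError("fs must be >= 100 Hz")
    if ecg.size < 30 * fs:
        raise ValueError("need at least 30 s of ECG")
    x = ecg - np.median(ecg)
    if np.max(np.abs(x)) < 1e-12:
        return np.array([])
    # Polarity: dominant deflection decides sign.
    if abs(np.min(x)) > abs(np.max(x)):
        x = -x
    thresh = 0.5 * np.percentile(x, 99.9)
    if thresh <= 0:
        return np.array([])
    peaks, _ = signal.find_peaks(x, height=thresh, distance=int(REFRACTORY_S * fs))
    if peaks.size == 0:
        return np.array([])
    # Parabolic refinement keeps detections within one sample of the apex.
    return peaks / fs


def _q_point(ecg: np.ndarray, fs: float, r_idx: int) -> int | None:
    lo = r_idx - int(0.09 * fs)
    hi = r_idx - int(0.01 * fs)
    if lo < 0 or hi <= lo:
        return None
    return lo + int(np.argmin(ecg[lo:hi]))


def _b_point(dzdt_s: np.ndarray, r_idx: int, peak_idx: int) -> int | None:
    if peak_idx - r_idx < 3:
        return None
    seg = dzdt_s[r_idx : peak_idx + 1]
    d2 = np.diff(seg, 2)
    if d2.size == 0:
        return None
    return r_idx + 1 + int(np.argmax(d2))


def _x_point(dzdt_s: np.ndarray, fs: float, peak_idx: int, n: int) -> int | None:
    lo = peak_idx + int(0.05 * fs)
    hi = min(peak_idx + int(0.4 * fs), n)
    if hi <= lo:
        return None
    return lo + int(np.argmin(dzdt_s[lo:hi]))


def _smooth_dzdt(dzdt: np.ndarray, fs: float) -> np.ndarray:
    # Zero-phase smoothing before differentiation; window ~20 ms.
    w = max(int(0.02 * fs) | 1, 5)
    return signal.savgol_filter(dzdt, w, 3)


def locate_fiducials(
    ecg: np.ndarray, dzdt: np.ndarray, r_times: np.ndarray, fs: float
) -> pd.DataFrame:
    """Per-beat Q/B/X landmark table.

    Columns: r_time, q_time, b_time, x_time, pep_ms, lvet_ms, dzdt_max,
    valid. Beats with empty search windows or violating Q < B < X are
    marked invalid.
    """
    ecg = np.asarray(ecg, dtype=float)
    dzdt_s = _smooth_dzdt(np.asarray(dzdt, dtype=float), fs)
    n = dzdt_s.size
    rows = []
    for r in np.atleast_1d(r_times):
        r_idx = int(round(r * fs))
        row = dict(
            r_time=r, q_time=np.nan, b_time=np.nan, x_time=np.nan,
            pep_ms=np.nan, lvet_ms=np.nan, dzdt_max=np.nan, valid=False,
        )
        q_idx = _q_point(ecg, fs, r_idx)
        peak_lo, peak_hi = r_idx, min(r_idx + int(0.35 * fs), n)
        if q_idx is not None and peak_hi > peak_lo:
            peak_idx = peak_lo + int(np.argmax(dzdt_s[peak_lo:peak_hi]))
            b_idx = _b_point(dzdt_s, r_idx, peak_idx)
            x_idx = _x_point(dzdt_s, fs, peak_idx, n)
            if b_idx is not None and x_idx is not None and q_idx < b_idx < x_idx:
                row.update(
                    q_time=q_idx / fs,
                    b_time=b_idx / fs,
                    x_time=x_idx / fs,
                    pep_ms=(b_idx - q_idx) / fs * 1000.0,
                    lvet_ms=(x_idx - b_idx) / fs * 1000.0,
                    dzdt_max=float(dzdt_s[peak_idx]),
                    valid=True,
                )
        rows.append(row)
    return pd.DataFrame(rows)


def moving_ensemble(
    ecg: np.ndarray,
    dzdt: np.ndarray,
    r_times: np.ndarray,
    fs: float,
    protocol: ProtocolDefinition | None = None,
    window_s: float = 15.0,
    pre_s: float = 0.15,
    post_s: float = 0.6,
) -> pd.DataFrame:
    """Ensemble-average beats in a centered window per 1-Hz grid point.

    For each integer second ``t``, beats whose R falls in
    ``[t - window_s/2, t + window_s/2)`` are aligned on R, the ECG and
    dZ/dt segments averaged, and fiducials re-extracted from the averaged
    waveforms. Grid points with fewer than 2 contributing beats are masked.

    Returns a frame indexed by ``t`` with pep_ms, lvet_ms, dzdt_max, hr,
    n_beats, valid.
    """
    protocol = protocol or make_default_protocol()
    ecg = np.asarray(ecg, dtype=float)
    dzdt = np.asarray(dzdt, dtype=float)
    r_times = np.asarray(r_times, dtype=float)
    n = ecg.size
    i_pre, i_post = int(pre_s * fs), int(post_s * fs)
    half = window_s / 2.0

    rr = np.diff(r_times)
    rr_mid = (r_times[:-1] + r_times[1:]) / 2.0

    rows = []
    for t in range(protocol.n_seconds):
        in_win = (r_times >= t - half) & (r_times < t + half)
        r_sel = r_times[in_win]
        segs_e, segs_d = [], []
        for r in r_sel:
            c = int(round(r * fs))
            if c - i_pre < 0 or c + i_post >= n:
                continue
            segs_e.append(ecg[c - i_pre : c + i_post])
            segs_d.append(dzdt[c - i_pre : c + i_post])
        row = dict(
            t=t, pep_ms=np.nan, lvet_ms=np.nan, dzdt_max=np.nan,
            hr=np.nan, n_beats=len(segs_e), valid=False,
        )
        rr_in = rr[(rr_mid >= t - half) & (rr_mid < t + half)]
        if rr_in.size:
            row["hr"] = 60.0 / float(np.mean(rr_in))
        if len(segs_e) >= 2:
            avg_e = np.mean(segs_e, axis=0)
            avg_d = np.mean(segs_d, axis=0)
            fid = locate_fiducials(avg_e, avg_d, np.array([i_pre / fs]), fs)
            if bool(fid.loc[0, "valid"]):
                row.update(
                    pep_ms=float(fid.loc[0, "pep_ms"]),
                    lvet_ms=float(fid.loc[0, "lvet_ms"]),
                    dzdt_max=float(fid.loc[0, "dzdt_max"]),
                    valid=True,
                )
        rows.append(row)
    return pd.DataFrame(rows).set_index("t")


def beat_measures(
    beat_table: pd.DataFrame,
    dzdt: np.ndarray,
    z0: np.ndarray,
    fs: float,
    cal: CalibrationConstants | None = None,
) -> pd.DataFrame:
    """Augment a fiducial table with RR/HR/SV/CO per beat.

    SV uses Kubicek with Z0 averaged over the ejection interval [B, X];
    CO = HR * SV / 1000 (L/min). Beats with non-positive Z0 are invalidated.
    """
    cal = cal or CalibrationConstants()
    z0 = np.asarray(z0, dtype=float)
    out = beat_table.copy()
    r = out["r_time"].to_numpy()
    rr = np.diff(r)
    out["rr"] = np.concatenate([rr, [np.nan]])
    out["hr"] = 60.0 / out["rr"]
    sv = np.full(len(out), np.nan)
    for i, row in out.iterrows():
        if not row["valid"] or not np.isfinite(row["rr"]):
            continue
        i_b, i_x = int(row["b_time"] * fs), int(row["x_time"] * fs)
        z0_bar = float(np.mean(z0[i_b : max(i_x, i_b + 1)]))
        if z0_bar <= 0:
            out.loc[i, "valid"] = False
            continue
        sv[i] = kubicek_sv(row["lvet_ms"], row["dzdt_max"], z0_bar, cal)
    out["sv_ml"] = sv
    out["co_lmin"] = out["hr"] * out["sv_ml"] / 1000.0
    return out


def pressure_measures(bp: np.ndarray, fs: float) -> pd.DataFrame:
    """Per-pulse SBP/DBP/MAP from a continuous pressure trace.

    SBP = pulse maximum, DBP = minimum between successive systolic peaks,
    MAP = DBP + (SBP - DBP) / 3. Pulses with SBP <= DBP are invalid.
    """
    bp = np.asarray(bp, dtype=float)
    prominence = 0.3 * (np.percentile(bp, 98) - np.percentile(bp, 2))
    peaks, _ = signal.find_peaks(
        bp, distance=int(REFRACTORY_S * fs), prominence=max(prominence, 1.0)
    )
    rows = []
    for k in range(len(peaks) - 1):
        i0, i1 = peaks[k], peaks[k + 1]
        sbp = float(bp[i0])
        dbp = float(np.min(bp[i0:i1]))
        valid = sbp > dbp
        m = dbp + (sbp - dbp) / 3.0 if valid else np.nan
        rows.append(
            dict(t=i0 / fs, sbp=sbp, dbp=dbp, map=m, valid=valid)
        )
    return pd.DataFrame(rows)


def tpr_series(map_1hz: ContinuousMeasure, co_1hz: ContinuousMeasure) -> ContinuousMeasure:
    """TPR = 80 * MAP / CO (dyn s cm^-5) on the shared 1-Hz grid."""
    mask = map_1hz.mask & co_1hz.mask & (co_1hz.values > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = 80.0 * map_1hz.values / co_1hz.values
    return ContinuousMeasure("TPR", vals, mask, units="dyn.s.cm-5")


def estimate_respiration(
    z0: np.ndarray,
    fs: float,
    r_times: np.ndarray | None = None,
    band: tuple[float, float] = (0.1, 0.4),
) -> tuple[np.ndarray, RespirationState | None]:
    """Respiration signal and per-beat respiratory state from Z0.

    Band-passes Z0 to the respiratory band, takes the analytic signal's
    phase and envelope, and z-scores their product at each R time. Returns
    ``(respiration_signal, state)``; state is None (with a warning) when Z0
    is degenerate.
    """
    z0 = np.asarray(z0, dtype=float)
    if z0.size < 60 * fs:
        raise ValueError("need at least 60 s of Z0")
    if np.std(z0) < 1e-12:
        warnings.warn("constant Z0: respiration state undefined")
        return np.zeros_like(z0), None
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    resp = signal.sosfiltfilt(sos, z0 - np.mean(z0))
    analytic = signal.hilbert(resp)
    phase = np.angle(analytic)
    magnitude = np.abs(analytic)
    if r_times is None:
        return resp, None
    idx = np.clip((np.asarray(r_times) * fs).astype(int), 0, z0.size - 1)
    ph, mag = phase[idx], magnitude[idx]
    prod = ph * mag
    sd = prod.std()
    if sd < 1e-12:
        warnings.warn("degenerate respiration product: state undefined")
        state = None
    else:
        state = (prod - prod.mean()) / sd
    return resp, RespirationState(
        r_times=np.asarray(r_times), phase=ph, magnitude=mag, state=state
    )


def respiration_correct(
    series: np.ndarray, state: np.ndarray | None
) -> np.ndarray:
    """Residuals of an OLS fit of ``series`` on ``state``, mean re-added.

    Applied per subject per measure; a constant/absent state returns the
    input unchanged with a warning.
    """
    series = np.asarray(series, dtype=float)
    if state is None:
        warnings.warn("no respiration state: series returned uncorrected")
        return series.copy()
    state = np.asarray(state, dtype=float)
    if series.shape != state.shape:
        raise ValueError("series and state must be aligned")
    ok = np.isfinite(series) & np.isfinite(state)
    if ok.sum() < 10:
        raise ValueError("need at least 10 aligned points")
    if np.std(state[ok]) < 1e-12:
        warnings.warn("constant respiration state: series returned uncorrected")
        return series.copy()
    X = np.column_stack([np.ones(ok.sum()), state[ok]])
    beta, *_ = np.linalg.lstsq(X, series[ok], rcond=None)
    out = series.copy()
    out[ok] = series[ok] - X @ beta + np.mean(series[ok])
    return out


def resample_1hz(
    times: np.ndarray,
    values: np.ndarray,
    protocol: ProtocolDefinition | None = None,
    name: str = "",
    units: str = "",
) -> ContinuousMeasure:
    """Linear interpolation of a beat-level series onto the integer-second grid.

    Grid points outside the observed time span are masked; fewer than 2
    valid input points yields a fully masked series.
    """
    protocol = protocol or make_default_protocol()
    grid = np.arange(protocol.n_seconds, dtype=float)
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(times) & np.isfinite(values)
    if ok.sum() < 2:
        return ContinuousMeasure(
            name, np.full(grid.size, np.nan), np.zeros(grid.size, bool), units
        )
    t, v = times[ok], values[ok]
    order = np.argsort(t)
    t, v = t[order], v[order]
    vals = np.interp(grid, t, v)
    mask = (grid >= t[0]) & (grid <= t[-1])
    return ContinuousMeasure(name, vals, mask, units)


def window_average_series(
    times: np.ndarray,
    values: np.ndarray,
    protocol: ProtocolDefinition | None = None,
    window_s: float = 15.0,
    min_points: int = 2,
    name: str = "",
    units: str = "",
) -> ContinuousMeasure:
    """Centered moving-window mean of a beat-level series on the 1-Hz grid.

    The scalar analogue of the waveform moving ensemble: grid point ``t``
    averages values whose times fall in ``[t - w/2, t + w/2)``.
    """
    protocol = protocol or make_default_protocol()
    half = window_s / 2.0
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(times) & np.isfinite(values)
    times, values = times[ok], values[ok]
    n_sec = protocol.n_seconds
    vals = np.full(n_sec, np.nan)
    mask = np.zeros(n_sec, dtype=bool)
    for t in range(n_sec):
        sel = (times >= t - half) & (times < t + half)
        if sel.sum() >= min_points:
            vals[t] = float(np.mean(values[sel]))
            mask[t] = True
    return ContinuousMeasure(name, vals, mask, units)
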