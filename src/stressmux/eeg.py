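"""EEG channel QC, referencing, time-frequency reduction.

Bad channels are those that flatline for 5 s or longer, whose SD exceeds
four times the channel-population median SD, or that fail to correlate at
r > 0.85 with a distance-weighted reconstruction from the other channels.
Good channels supply the average reference; bad ones are rebuilt by
spherical-spline interpolation. The time-frequency decomposition uses
Hann-tapered 1-s windows hopped at 1 s (1 Hz x 1 s resolution, 1-30 Hz,
optional moving average across frequency bins), and is reduced to band x
period cell means (dB re. the trial's own 1-40 s baseline for
post-baseline periods, raw log power for the baseline period itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from scipy.special import eval_legendre

from .protocol import ProtocolDefinition, make_default_protocol

__all__ = [
    "EEGRecording",
    "ERSPGrid",
    "RecordingRejectedError",
    "standard_positions",
    "detect_bad_channels",
    "rereference_interpolate",
    "spherical_spline_interpolate",
    "preprocess_raw",
    "compute_ersp",
    "reduce_band_period",
    "BANDS",
    "PERIODS",
]

BANDS: dict[str, tuple[int, int]] = {
    "delta": (1, 3),
    "theta": (4, 7),
    "alpha": (8, 14),
    "beta": (15, 30),
}

# Inclusive second ranges on the trial grid.
PERIODS: dict[str, tuple[int, int]] = {
    "baseline": (1, 40),
    "early": (65, 94),
    "mid": (95, 124),
    "late": (125, 154),
    "recovery": (155, 190),
}

# Approximate 10-20 positions as (inclination from vertex, azimuth from
# nose, both degrees; azimuth positive toward the right ear).
_TEN_TWENTY: dict[str, tuple[float, float]] = {
    "Fpz": (90, 0), "Fp1": (90, -18), "Fp2": (90, 18),
    "AFz": (69, 0),
    "Fz": (46, 0), "F3": (50, -39), "F4": (50, 39),
    "F7": (90, -54), "F8": (90, 54),
    "FC1": (31, -45), "FC2": (31, 45), "FC5": (69, -69), "FC6": (69, 69),
    "Cz": (0, 0), "C3": (46, -90), "C4": (46, 90),
    "T7": (90, -90), "T8": (90, 90),
    "CP1": (31, -135), "CP2": (31, 135), "CP5": (69, -111), "CP6": (69, 111),
    "Pz": (46, 180), "P3": (50, -141), "P4": (50, 141),
    "P7": (90, -126), "P8": (90, 126),
    "POz": (69, 180),
    "O1": (90, -162), "O2": (90, 162), "Oz": (90, 180),
}


def standard_positions(names: tuple[str, ...] | list[str]) -> np.ndarray:
    """Unit-sphere xyz coordinates for 10-20 channel names."""
    out = np.empty((len(names), 3))
    for i, name in enumerate(names):
        if name not in _TEN_TWENTY:
            raise KeyError(f"no stored position for channel {name!r}")
        incl, az = np.deg2rad(_TEN_TWENTY[name])
        out[i] = (
            np.sin(incl) * np.sin(az),  # x: toward right ear
            np.sin(incl) * np.cos(az),  # y: toward nose
            np.cos(incl),               # z: vertex
        )
    return out


class RecordingRejectedError(ValueError):
    """Raised when more than half the montage is bad."""


@dataclass
class EEGRecording:
    names: tuple[str, ...]
    data: np.ndarray  # (n_channels, n_samples), uV
    fs: float
    bads: list[str] = field(default_factory=list)
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if len(set(self.names)) != len(self.names):
            raise ValueError("channel names must be unique")
        if self.data.shape[0] != len(self.names):
            raise ValueError("data rows must match channel names")
        if self.positions is None:
            self.positions = standard_positions(self.names)


def preprocess_raw(
    rec: EEGRecording, highpass_hz: float = 1.0, notch_hz: float = 60.0
) -> EEGRecording:
    """Zero-phase 1-Hz high-pass and 60-Hz notch."""
    data = rec.data
    if highpass_hz:
        sos = signal.butter(4, highpass_hz, btype="highpass", fs=rec.fs, output="sos")
        data = signal.sosfiltfilt(sos, data, axis=-1)
    if notch_hz and notch_hz < rec.fs / 2:
        b, a = signal.iirnotch(notch_hz, Q=30.0, fs=rec.fs)
        data = signal.filtfilt(b, a, data, axis=-1)
    return EEGRecording(rec.names, data, rec.fs, list(rec.bads), rec.positions)


def _flatline_channels(data: np.ndarray, fs: float, min_s: float, floor: float):
    flagged = []
    max_run = int(min_s * fs)
    flat = np.abs(np.diff(data, axis=-1)) < floor
    for c in range(data.shape[0]):
        run, longest = 0, 0
        for v in flat[c]:
            run = run + 1 if v else 0
            longest = max(longest, run)
            if longest >= max_run:
                break
        if longest >= max_run:
            flagged.append(c)
    return flagged


def _reconstruction_weights(positions: np.ndarray) -> np.ndarray:
    """Inverse-squared-distance weights, zero diagonal, rows normalized."""
    d2 = np.sum((positions[:, None, :] - positions[None, :, :]) ** 2, axis=-1)
    with np.errstate(divide="ignore"):
        w = 1.0 / d2
    np.fill_diagonal(w, 0.0)
    return w / w.sum(axis=1, keepdims=True)


def detect_bad_channels(
    rec: EEGRecording,
    flat_s: float = 5.0,
    flat_floor_uv: float = 1e-3,
    sd_factor: float = 4.0,
    corr_threshold: float = 0.85,
) -> list[str]:
    """Bad-channel list by flatline, amplitude-SD and reconstruction rules."""
    if len(rec.names) < 8:
        raise ValueError("need at least 8 channels for population QC")
    data = rec.data
    bad_idx: set[int] = set(_flatline_channels(data, rec.fs, flat_s, flat_floor_uv))

    sds = data.std(axis=-1)
    med = np.median(sds)
    bad_idx |= set(np.flatnonzero(sds > sd_factor * med))

    # Reconstruction rule uses only channels that survived the cheap rules.
    candidates = [c for c in range(len(rec.names)) if c not in bad_idx]
    if len(candidates) >= 3:
        weights = _reconstruction_weights(rec.positions)
        sub = np.array(candidates)
        w = weights[np.ix_(sub, sub)]
        w = w / w.sum(axis=1, keepdims=True)
        recon = w @ data[sub]
        for i, c in enumerate(candidates):
            x, y = data[c], recon[i]
            denom = x.std() * y.std()
            r = 0.0 if denom == 0 else float(np.corrcoef(x, y)[0, 1])
            if r < corr_threshold:
                bad_idx.add(c)
    return [rec.names[c] for c in sorted(bad_idx)]


def _spline_g(cosang: np.ndarray, order: int = 4, n_terms: int = 20) -> np.ndarray:
    l = np.arange(1, n_terms + 1)
    coef = (2 * l + 1) / (l * (l + 1.0)) ** order
    out = np.zeros_like(cosang, dtype=float)
    for li, c in zip(l, coef):
        out += c * eval_legendre(li, cosang)
    return out / (4 * np.pi)


def spherical_spline_interpolate(
    good_pos: np.ndarray,
    bad_pos: np.ndarray,
    good_data: np.ndarray,
    order: int = 4,
    reg: float = 1e-8,
) -> np.ndarray:
    """Interpolate signals at ``bad_pos`` from ``good_data`` at ``good_pos``.

    Spherical-spline (thin-plate on the sphere) interpolation with a
    constant term; ``good_data`` is (n_good, n_samples).
    """
    cos_gg = np.clip(good_pos @ good_pos.T, -1.0, 1.0)
    cos_bg = np.clip(bad_pos @ good_pos.T, -1.0, 1.0)
    G = _spline_g(cos_gg, order) + reg * np.eye(len(good_pos))
    n = len(good_pos)
    A = np.zeros((n + 1, n + 1))
    A[:n, :n] = G
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    rhs = np.vstack([good_data, np.zeros((1, good_data.shape[1]))])
    sol = np.linalg.solve(A, rhs)
    c, c0 = sol[:n], sol[n]
    return _spline_g(cos_bg, order) @ c + c0


def rereference_interpolate(
    rec: EEGRecording, bads: list[str] | None = None
) -> EEGRecording:
    """Average-reference to the good channels, then rebuild the bad ones.

    The mean of the good channels is subtracted from every channel; bad
    channels are replaced with spherical-spline interpolations from the
    referenced good channels. Raises :class:`RecordingRejectedError` when
    more than 50% of channels are bad.
    """
    bads = rec.bads if bads is None else bads
    bad_set = set(bads)
    good_idx = [i for i, n in enumerate(rec.names) if n not in bad_set]
    bad_idx = [i for i, n in enumerate(rec.names) if n in bad_set]
    if not good_idx:
        raise RecordingRejectedError("no good channels")
    if len(bad_idx) > 0.5 * len(rec.names):
        raise RecordingRejectedError(
            f"{len(bad_idx)}/{len(rec.names)} channels bad: recording rejected"
        )
    data = rec.data - rec.data[good_idx].mean(axis=0, keepdims=True)
    if bad_idx:
        data[bad_idx] = spherical_spline_interpolate(
            rec.positions[good_idx], rec.positions[bad_idx], data[good_idx]
        )
    return EEGRecording(rec.names, data, rec.fs, bads=[], positions=rec.positions)


@dataclass
class ERSPGrid:
    """channel x frequency (1-Hz bins) x time (1-s frames) power grids."""

    names: tuple[str, ...]
    freqs: np.ndarray
    times: np.ndarray
    power: np.ndarray  # raw, >= 0
    db: np.ndarray  # 10*log10(power / per-channel-frequency baseline mean)


def compute_ersp(
    rec: EEGRecording,
    protocol: ProtocolDefinition | None = None,
    f_min: int = 1,
    f_max: int = 30,
    freq_smooth_bins: int = 1,
    baseline_s: tuple[int, int] = (1, 40),
) -> ERSPGrid:
    """Hann-windowed 1 s x 1 Hz power grid.

    The dB variant divides each channel x frequency row by its own mean
    over the trial's baseline seconds before log-scaling.
    ``freq_smooth_bins > 1`` averages power over that many neighbouring
    frequency bins first (off by default: smoothing biases narrowband
    power ratios toward the broadband background).
    """
    protocol = protocol or make_default_protocol()
    if rec.fs < 2 * f_max:
        raise ValueError("sampling rate below Nyquist for requested band")
    n_sec = protocol.n_seconds
    spf = int(round(rec.fs))  # samples per 1-s frame
    usable = min(rec.data.shape[1] // spf, n_sec)
    frames = rec.data[:, : usable * spf].reshape(len(rec.names), usable, spf)
    win = signal.windows.hann(spf, sym=False)
    spec = np.fft.rfft(frames * win, axis=-1)
    power = (np.abs(spec) ** 2) * (2.0 / np.sum(win**2))
    freqs_all = np.fft.rfftfreq(spf, d=1.0 / rec.fs)
    sel = (freqs_all >= f_min) & (freqs_all <= f_max)
    power = power[:, :, sel].transpose(0, 2, 1)  # (ch, freq, time)
    freqs = freqs_all[sel]
    if usable < n_sec:
        pad = np.full((power.shape[0], power.shape[1], n_sec - usable), np.nan)
        power = np.concatenate([power, pad], axis=-1)
    if freq_smooth_bins > 1:
        kernel = np.ones(freq_smooth_bins) / freq_smooth_bins
        power = np.apply_along_axis(
            lambda v: np.convolve(v, kernel, mode="same"), 1, power
        )
    b0, b1 = baseline_s
    base = np.nanmean(power[:, :, b0 : b1 + 1], axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(power / base)
    return ERSPGrid(
        names=rec.names,
        freqs=freqs,
        times=np.arange(n_sec),
        power=power,
        db=db,
    )


def reduce_band_period(
    ersp: ERSPGrid,
    bands: dict[str, tuple[int, int]] | None = None,
    periods: dict[str, tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Mean power per channel x band x period.

    Post-baseline periods average the baseline-normalized dB grid; the
    baseline period averages raw log power (no self-division). Band and
    period bounds are inclusive.
    """
    bands = bands or BANDS
    periods = periods or PERIODS
    with np.errstate(divide="ignore", invalid="ignore"):
        raw_log = 10.0 * np.log10(ersp.power)
    rows = []
    for band, (f_lo, f_hi) in bands.items():
        f_sel = (ersp.freqs >= f_lo) & (ersp.freqs <= f_hi)
        for period, (t_lo, t_hi) in periods.items():
            grid = raw_log if period == "baseline" else ersp.db
            cell = np.nanmean(
                np.nanmean(grid[:, f_sel, :], axis=1)[:, t_lo : t_hi + 1], axis=1
            )
            for c, name in enumerate(ersp.names):
                rows.append(
                    dict(channel=name, band=band, period=period, value=float(cell[c]))
                )
    return pd.DataFrame(rows)
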