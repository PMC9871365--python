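"""Waveform rendering: geometric beat templates with controllable landmarks.

Channels are rendered so the extraction modules can recover the generator's
truth: the ECG Q trough sits ``q_offset`` before each R spike, the dZ/dt
onset (B, the maximal-second-derivative point) sits PEP after Q, the
incisura minimum (X) sits LVET after B, and the dZ/dt lobe amplitude is the
Kubicek-formula inverse of the true stroke volume. Z0 carries a respiration
sinusoid, BP a pulse waveform consistent with SBP/DBP around the MAP
profile, the pupil channels carry the pupil profile with optional blink
dropouts, and EEG channels carry 1/f noise plus band-limited oscillators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..protocol import ProtocolDefinition, make_default_protocol
from .effects import EEGBandEffect, default_eeg_band_effects
from .timeline import RESPIRATION_HZ, BeatTruth

__all__ = [
    "Channel",
    "TrialSignalSet",
    "RenderConfig",
    "render_trial",
    "DEFAULT_EEG_CHANNELS",
    "kubicek_dzdt_max",
]

DEFAULT_EEG_CHANNELS = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz", "C3",
    "C4", "Cz", "T7", "T8", "P3", "P4", "Pz", "Oz",
)


@dataclass
class Channel:
    data: np.ndarray
    fs: float
    units: str = ""

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass
class TrialSignalSet:
    """All raw channels for one trial."""

    trial: int
    ecg: Channel
    dzdt: Channel
    z0: Channel
    bp: Channel
    pupil_left: Channel
    pupil_right: Channel
    eeg: Channel  # (n_channels, n_samples)
    eeg_channels: tuple[str, ...]

    def channels(self) -> dict[str, Channel]:
        return {
            "ecg": self.ecg,
            "dzdt": self.dzdt,
            "z0": self.z0,
            "bp": self.bp,
            "pupil_left": self.pupil_left,
            "pupil_right": self.pupil_right,
            "eeg": self.eeg,
        }


@dataclass(frozen=True)
class RenderConfig:
    """Rendering rates, template geometry, calibration and noise levels."""

    fs_physio: float = 250.0
    fs_eeg: float = 250.0
    fs_pupil: float = 500.0
    q_offset_s: float = 0.048
    r_amp_mv: float = 1.0
    q_amp_mv: float = -0.25
    t_amp_mv: float = 0.3
    rho_ohm_cm: float = 135.0
    electrode_l_cm: float = 30.0
    z0_base_ohm: float = 30.0
    respiration_amp_ohm: float = 0.2
    respiration_hz: float = RESPIRATION_HZ
    pulse_pressure_mmhg: float = 40.0
    blink_rate_hz: float = 0.05
    blink_duration_s: float = 0.3
    ecg_noise_mv: float = 0.01
    dzdt_noise_rel: float = 0.01
    z0_noise_ohm: float = 0.002
    bp_noise_mmhg: float = 0.3
    pupil_noise: float = 4.0
    eeg_shared_uv: float = 20.0  # spatially shared background, keeps channels correlated
    eeg_pink_uv: float = 3.0
    eeg_channels: tuple[str, ...] = DEFAULT_EEG_CHANNELS


def kubicek_dzdt_max(
    sv_ml: float, lvet_s: float, z0_ohm: float, rho: float, length_cm: float
) -> float:
    """Invert the Kubicek stroke-volume formula for the dZ/dt lobe peak."""
    return sv_ml / (rho * (length_cm / z0_ohm) ** 2 * lvet_s)


def _add_gauss(y: np.ndarray, fs: float, center_s: float, sigma_s: float, amp: float):
    lo = max(int((center_s - 4 * sigma_s) * fs), 0)
    hi = min(int((center_s + 4 * sigma_s) * fs) + 1, y.size)
    if hi <= lo:
        return
    t = np.arange(lo, hi) / fs
    y[lo:hi] += amp * np.exp(-0.5 * ((t - center_s) / sigma_s) ** 2)


def _render_ecg(truth: BeatTruth, n: int, cfg: RenderConfig, rng) -> np.ndarray:
    y = np.zeros(n)
    fs = cfg.fs_physio
    for r in truth.r_times:
        _add_gauss(y, fs, r, 0.008, cfg.r_amp_mv)
        _add_gauss(y, fs, r - cfg.q_offset_s, 0.006, cfg.q_amp_mv)
        _add_gauss(y, fs, r + 0.25, 0.04, cfg.t_amp_mv)
    if cfg.ecg_noise_mv > 0:
        y += rng.normal(0.0, cfg.ecg_noise_mv, n)
    return y


def _render_z0(n: int, cfg: RenderConfig, rng, noise: bool = True) -> np.ndarray:
    t = np.arange(n) / cfg.fs_physio
    y = cfg.z0_base_ohm + cfg.respiration_amp_ohm * np.sin(
        2 * np.pi * cfg.respiration_hz * t
    )
    if noise and cfg.z0_noise_ohm > 0:
        y = y + rng.normal(0.0, cfg.z0_noise_ohm, n)
    return y


def _render_dzdt(
    truth: BeatTruth, z0_clean: np.ndarray, n: int, cfg: RenderConfig, rng
) -> np.ndarray:
    y = np.zeros(n)
    fs = cfg.fs_physio
    for r, pep, lvet, sv in zip(
        truth.r_times, truth.pep_ms, truth.lvet_ms, truth.sv_ml
    ):
        b = (r - cfg.q_offset_s) + pep / 1000.0
        lvet_s = lvet / 1000.0
        x = b + lvet_s
        i_b, i_x = int(b * fs), int(x * fs)
        if i_b < 0 or i_x + int(0.2 * lvet_s * fs) + 2 >= n:
            continue  # truncated beat at trial edge
        z0_bar = float(np.mean(z0_clean[i_b : max(i_x, i_b + 1)]))
        amp = kubicek_dzdt_max(sv, lvet_s, z0_bar, cfg.rho_ohm_cm, cfg.electrode_l_cm)
        # Positive half-sine lobe from B, returning to zero at B + 0.85 LVET.
        lobe_frac = 0.85
        lobe_end = b + lobe_frac * lvet_s
        i_le = int(lobe_end * fs)
        tt = np.arange(i_b, i_le + 1) / fs
        y[i_b : i_le + 1] += amp * np.sin(
            np.pi * np.clip((tt - b) / (lobe_frac * lvet_s), 0, 1)
        )
        # Narrow negative notch with its minimum exactly at X = B + LVET;
        # narrowness keeps the incisura sharp under additive noise.
        notch_w = 2.0 * (1.0 - lobe_frac) * lvet_s
        notch_end = b + lvet_s + notch_w / 2.0
        i_ne = min(int(notch_end * fs), n - 1)
        tt = np.arange(i_le + 1, i_ne + 1) / fs
        y[i_le + 1 : i_ne + 1] += -0.35 * amp * np.sin(
            np.pi * np.clip((tt - lobe_end) / notch_w, 0, 1)
        )
    if cfg.dzdt_noise_rel > 0:
        scale = cfg.dzdt_noise_rel * max(np.max(np.abs(y)), 1e-12)
        y += rng.normal(0.0, scale, n)
    return y


def _render_bp(truth: BeatTruth, n: int, cfg: RenderConfig, rng) -> np.ndarray:
    fs = cfg.fs_physio
    map_profile = truth.profiles.get("MAP")
    if map_profile is None:
        map_profile = np.full(int(np.ceil(n / fs)), 80.0)
    grid = np.arange(map_profile.size, dtype=float)
    pp = cfg.pulse_pressure_mmhg
    y = np.empty(n)
    t_all = np.arange(n) / fs
    # Flat DBP outside rendered pulses, so per-beat minima stay at DBP.
    y[:] = np.interp(t_all, grid, map_profile) - pp / 3.0
    r = truth.r_times
    for k in range(len(r) - 1):
        i0, i1 = int(r[k] * fs), int(r[k + 1] * fs)
        if i1 <= i0 or i1 > n:
            continue
        m = float(np.interp(r[k], grid, map_profile))
        sbp, dbp = m + 2 * pp / 3.0, m - pp / 3.0
        u = (np.arange(i0, i1) - i0) / (i1 - i0)
        y[i0:i1] = dbp + (sbp - dbp) * 0.5 * (1 - np.cos(2 * np.pi * u))
    if cfg.bp_noise_mmhg > 0:
        y += rng.normal(0.0, cfg.bp_noise_mmhg, n)
    return y


def _render_pupil(
    profile: np.ndarray, duration: float, cfg: RenderConfig, rng
) -> tuple[np.ndarray, np.ndarray]:
    fs = cfg.fs_pupil
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    grid = np.arange(profile.size, dtype=float)
    eyes = []
    for eye_offset in (-5.0, 5.0):
        y = np.interp(t, grid, profile) + eye_offset
        if cfg.pupil_noise > 0:
            y = y + rng.normal(0.0, cfg.pupil_noise, n)
        # Blink dropouts: Poisson-spaced NaN gaps.
        if cfg.blink_rate_hz > 0:
            n_blinks = rng.poisson(cfg.blink_rate_hz * duration)
            starts = rng.uniform(0, duration, n_blinks)
            w = int(cfg.blink_duration_s * fs)
            for s in starts:
                i0 = int(s * fs)
                y[i0 : i0 + w] = np.nan
        eyes.append(y)
    return eyes[0], eyes[1]


def _pink_noise(n: int, rng) -> np.ndarray:
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1] if n > 1 else 1.0
    spec = spec / np.sqrt(f / f[1])
    y = np.fft.irfft(spec, n=n)
    return y / (y.std() or 1.0)


def _render_eeg(
    band_amp_truth: dict[str, np.ndarray] | None,
    band_effects: dict[str, EEGBandEffect],
    duration: float,
    cfg: RenderConfig,
    rng,
) -> np.ndarray:
    """``band_amp_truth[band]`` is (n_channels, n_seconds) amplitude in uV."""
    fs = cfg.fs_eeg
    max_f = max(eff.center_hz for eff in band_effects.values())
    if fs < 2 * max_f:
        raise ValueError(f"fs_eeg={fs} below Nyquist for {max_f} Hz oscillator")
    n = int(round(duration * fs))
    n_ch = len(cfg.eeg_channels)
    t = np.arange(n) / fs
    shared = cfg.eeg_shared_uv * _pink_noise(n, rng)
    gains = rng.uniform(0.9, 1.1, n_ch)
    data = np.empty((n_ch, n))
    for c in range(n_ch):
        data[c] = gains[c] * shared + cfg.eeg_pink_uv * _pink_noise(n, rng)
    for band, eff in band_effects.items():
        phases = rng.uniform(0, 2 * np.pi, n_ch)
        for c in range(n_ch):
            if band_amp_truth is not None and band in band_amp_truth:
                amp_prof = band_amp_truth[band][c]
                amp = np.interp(t, np.arange(amp_prof.size, dtype=float), amp_prof)
            else:
                amp = eff.baseline_amp
            data[c] += amp * np.sin(2 * np.pi * eff.center_hz * t + phases[c])
    return data


def render_trial(
    truth: BeatTruth,
    protocol: ProtocolDefinition | None = None,
    config: RenderConfig | None = None,
    seed: int | np.random.Generator | None = None,
    trial: int = 1,
    band_amp_truth: dict[str, np.ndarray] | None = None,
    band_effects: dict[str, EEGBandEffect] | None = None,
    pupil_profile: np.ndarray | None = None,
) -> TrialSignalSet:
    """Render all raw channels for one trial from the beat-level truth."""
    protocol = protocol or make_default_protocol()
    cfg = config or RenderConfig()
    if cfg.fs_physio < 100:
        raise ValueError("fs_physio below the minimum for ECG template rendering")
    rng = np.random.default_rng(seed)
    duration = protocol.total_duration
    n = int(round(duration * cfg.fs_physio))

    z0_clean = _render_z0(n, cfg, rng, noise=False)
    ecg = _render_ecg(truth, n, cfg, rng)
    dzdt = _render_dzdt(truth, z0_clean, n, cfg, rng)
    z0 = z0_clean + (
        rng.normal(0.0, cfg.z0_noise_ohm, n) if cfg.z0_noise_ohm > 0 else 0.0
    )
    bp = _render_bp(truth, n, cfg, rng)

    if pupil_profile is None:
        pupil_profile = np.full(protocol.n_seconds, 1000.0)
    pl, pr = _render_pupil(pupil_profile, duration, cfg, rng)

    eeg = _render_eeg(
        band_amp_truth, band_effects or default_eeg_band_effects(), duration, cfg, rng
    )

    return TrialSignalSet(
        trial=trial,
        ecg=Channel(ecg, cfg.fs_physio, "mV"),
        dzdt=Channel(dzdt, cfg.fs_physio, "Ohm/s"),
        z0=Channel(z0, cfg.fs_physio, "Ohm"),
        bp=Channel(bp, cfg.fs_physio, "mmHg"),
        pupil_left=Channel(pl, cfg.fs_pupil, "a.u."),
        pupil_right=Channel(pr, cfg.fs_pupil, "a.u."),
        eeg=Channel(eeg, cfg.fs_eeg, "uV"),
        eeg_channels=cfg.eeg_channels,
    )
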