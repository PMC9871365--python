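"""Continuous high-frequency heart-rate-variability estimation.

Each 1-Hz estimate is trained on the trailing 32 s of R points: the
mean-centered RR deviations (ms) in that window go through a least-squares
(Lomb-Scargle) spectral estimate, power is integrated over the HF band
(0.15-0.40 Hz) and log-transformed. Grid points earlier than one full
window, or whose window holds too few beats, are masked — so 80% of a 40-s
baseline epoch carries no estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import lombscargle

from .cardio import respiration_correct
from .core import ContinuousMeasure
from .protocol import ProtocolDefinition, make_default_protocol

__all__ = ["RRSeries", "hf_band_power", "hf_timecourse", "hf_correct"]

HF_BAND = (0.15, 0.40)
RR_MIN_S, RR_MAX_S = 0.25, 3.0


@dataclass
class RRSeries:
    """R-point times with inter-beat intervals at interval midpoints."""

    r_times: np.ndarray
    rr_s: np.ndarray
    mid_times: np.ndarray
    flagged: np.ndarray  # physiologically implausible intervals

    @classmethod
    def from_r_times(cls, r_times: np.ndarray) -> "RRSeries":
        r_times = np.asarray(r_times, dtype=float)
        if np.any(np.diff(r_times) <= 0):
            raise ValueError("r_times must be strictly increasing")
        rr = np.diff(r_times)
        mid = (r_times[:-1] + r_times[1:]) / 2.0
        flagged = (rr <= RR_MIN_S) | (rr >= RR_MAX_S)
        return cls(r_times=r_times, rr_s=rr, mid_times=mid, flagged=flagged)


def hf_band_power(
    times: np.ndarray,
    rr_ms: np.ndarray,
    band: tuple[float, float] = HF_BAND,
    window_s: float = 32.0,
) -> float:
    """Band-integrated power (ms^2) of unevenly sampled RR deviations.

    Least-squares periodogram evaluated on a grid spaced at the window's
    natural resolution 1/T; bins scaled so a pure in-band sinusoid of
    amplitude ``a`` ms integrates to ~a^2/2 ms^2.
    """
    n = times.size
    df = 1.0 / window_s
    freqs = np.arange(band[0], band[1] + 0.5 * df, df)
    y = rr_ms - rr_ms.mean()
    if np.allclose(y, 0.0):
        return 0.0
    p = lombscargle(times, y, 2.0 * np.pi * freqs)
    return float(np.sum(p) * 2.0 / n)


def hf_timecourse(
    rr: RRSeries | np.ndarray,
    protocol: ProtocolDefinition | None = None,
    window_s: float = 32.0,
    band: tuple[float, float] = HF_BAND,
    min_beats: int = 8,
    epsilon: float = 1e-6,
) -> ContinuousMeasure:
    """Trailing-window log HF power on the 1-Hz grid.

    For each integer second ``t >= window_s`` the RR deviations whose
    interval midpoints fall in ``(t - window_s, t]`` are analyzed; earlier
    grid points and windows with fewer than ``min_beats`` intervals are
    masked. Values are ``log(HF + epsilon)`` with HF in ms^2.
    """
    if not isinstance(rr, RRSeries):
        rr = RRSeries.from_r_times(rr)
    protocol = protocol or make_default_protocol()
    n_sec = protocol.n_seconds
    vals = np.full(n_sec, np.nan)
    mask = np.zeros(n_sec, dtype=bool)
    good = ~rr.flagged
    times = rr.mid_times[good]
    rr_ms = rr.rr_s[good] * 1000.0
    for t in range(n_sec):
        if t < window_s:
            continue
        sel = (times > t - window_s) & (times <= t)
        if sel.sum() < min_beats:
            continue
        hf = hf_band_power(times[sel], rr_ms[sel], band, window_s)
        vals[t] = np.log(hf + epsilon)
        mask[t] = True
    return ContinuousMeasure("HF", vals, mask, units="log ms^2")


def hf_correct(
    hf: ContinuousMeasure, state: np.ndarray | None
) -> ContinuousMeasure:
    """Respiration-correct the log-HF series (per-subject OLS residuals).

    ``state`` must already be aligned to the 1-Hz grid (e.g. the beat-level
    respiratory state interpolated onto integer seconds).
    """
    if state is None:
        warnings.warn("no respiration state: HF returned uncorrected")
        return ContinuousMeasure(hf.name, hf.values.copy(), hf.mask.copy(), hf.units)
    vals = respiration_correct(hf.values, np.asarray(state, dtype=float))
    return ContinuousMeasure(hf.name, vals, hf.mask.copy(), hf.units)
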