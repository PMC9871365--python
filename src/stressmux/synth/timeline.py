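"""Beat-by-beat ground truth: an inhomogeneous heartbeat sequence.

Beats are laid down sequentially with inter-beat intervals driven by the
1-Hz HR truth profile, modulated by respiratory sinus arrhythmia at the
respiration frequency with a depth set by the HF truth profile (log band
power in ms^2 -> sinusoidal RR modulation amplitude), plus optional white
RR jitter. Per-beat PEP/LVET/SV truths are sampled from their profiles at
each beat time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..protocol import ProtocolDefinition, make_default_protocol
from .effects import EffectSpec, truth_profile

__all__ = ["BeatTruth", "simulate_beat_timeline", "hf_log_to_rr_amplitude"]

RESPIRATION_HZ = 0.25


def hf_log_to_rr_amplitude(hf_log: np.ndarray | float) -> np.ndarray | float:
    """RR modulation amplitude (s) whose band power matches exp(hf_log) ms^2.

    A sinusoid of amplitude ``a`` ms carries a^2/2 ms^2 of power, so
    ``a = sqrt(2 exp(hf_log))`` ms.
    """
    return np.sqrt(2.0 * np.exp(np.asarray(hf_log, dtype=float))) / 1000.0


@dataclass
class BeatTruth:
    """True beat times and per-beat cardiodynamic values for one trial."""

    r_times: np.ndarray  # s
    pep_ms: np.ndarray
    lvet_ms: np.ndarray
    sv_ml: np.ndarray
    profiles: dict[str, np.ndarray]  # 1-Hz truth profiles used

    @property
    def n_beats(self) -> int:
        return self.r_times.size


def _profile_at(profile: np.ndarray, t: float | np.ndarray) -> np.ndarray:
    grid = np.arange(profile.size, dtype=float)
    return np.interp(t, grid, profile)


def simulate_beat_timeline(
    specs: dict[str, EffectSpec],
    protocol: ProtocolDefinition | None = None,
    trial: int = 1,
    condition: str = "treatment",
    seed: int | np.random.Generator | None = None,
    subject_offsets: dict[str, float] | None = None,
    rr_jitter_sd: float = 0.0,
    respiration_hz: float = RESPIRATION_HZ,
    measure_noise: bool = False,
) -> BeatTruth:
    """Generate true beat times plus per-beat PEP/LVET/SV for one trial.

    ``subject_offsets`` maps measure name to a per-subject additive offset.
    With ``measure_noise=True`` per-beat values get Gaussian jitter at each
    spec's ``noise_sd``.
    """
    protocol = protocol or make_default_protocol()
    rng = np.random.default_rng(seed)
    offsets = subject_offsets or {}

    profiles = {
        name: truth_profile(
            specs[name], protocol, trial, condition, offsets.get(name, 0.0)
        )
        for name in ("HR", "PEP", "LVET", "SV", "MAP", "HF")
        if name in specs
    }
    hr = profiles["HR"]
    if np.any(hr <= 0):
        raise ValueError("HR profile must be positive")

    duration = protocol.total_duration
    rsa_amp = hf_log_to_rr_amplitude(profiles["HF"]) if "HF" in profiles else None

    times = []
    t = float(rng.uniform(0.0, 0.5)) if rr_jitter_sd > 0 else 0.2
    while t < duration:
        times.append(t)
        rr = 60.0 / _profile_at(hr, t)
        if rsa_amp is not None:
            rr += float(_profile_at(rsa_amp, t)) * np.sin(
                2.0 * np.pi * respiration_hz * t
            )
        if rr_jitter_sd > 0:
            rr += float(rng.normal(0.0, rr_jitter_sd))
        rr = max(rr, 0.3)
        t += rr
    r_times = np.asarray(times)

    def per_beat(name: str, default: float) -> np.ndarray:
        if name not in profiles:
            return np.full(r_times.size, default)
        vals = _profile_at(profiles[name], r_times)
        if measure_noise and specs[name].noise_sd > 0:
            vals = vals + rng.normal(0.0, specs[name].noise_sd, vals.shape)
        return vals

    return BeatTruth(
        r_times=r_times,
        pep_ms=per_beat("PEP", 83.0),
        lvet_ms=per_beat("LVET", 288.0),
        sv_ml=per_beat("SV", 37.6),
        profiles=profiles,
    )
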