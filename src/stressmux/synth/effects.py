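"""Effect specifications and noiseless ground-truth profiles.

Each measure carries a baseline level, an anticipatory delta (active during
baseline+prep under treatment), an evoked delta (active during immersion
under treatment, ramping in after an onset lag and ramping out in
recovery), and a per-trial multiplicative habituation ratio ``h`` so that
trial ``k`` expresses ``delta * h**(k-1)``.

Default magnitudes are loosely calibrated to the resting means used
elsewhere in the package (HR ~66 bpm, PEP ~83 ms, LVET ~288 ms, SV ~38 mL,
MAP ~80 mmHg, log-HF ~6.35) and are illustrative, not fitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..protocol import ProtocolDefinition, make_default_protocol

__all__ = ["EffectSpec", "default_effect_specs", "null_effect_specs", "truth_profile"]


@dataclass(frozen=True)
class EffectSpec:
    """Condition/habituation effect structure for one measure."""

    measure: str
    baseline_level: float
    anticipatory_delta: float = 0.0
    evoked_delta: float = 0.0
    habituation_ratio: float = 1.0
    anticipatory_habituation_ratio: float | None = None
    onset_lag_s: float = 2.0
    ramp_s: float = 8.0
    between_subject_sd: float = 0.0
    noise_sd: float = 0.0
    units: str = ""

    def __post_init__(self) -> None:
        h = self.habituation_ratio
        if not (0.0 < h <= 1.0):
            raise ValueError(f"habituation_ratio must be in (0, 1], got {h}")
        ha = self.anticipatory_habituation_ratio
        if ha is not None and not (0.0 < ha <= 1.0):
            raise ValueError("anticipatory_habituation_ratio must be in (0, 1]")
        if self.between_subject_sd < 0 or self.noise_sd < 0:
            raise ValueError("SDs must be >= 0")

    @property
    def h_anticipatory(self) -> float:
        ha = self.anticipatory_habituation_ratio
        return self.habituation_ratio if ha is None else ha


def default_effect_specs() -> dict[str, EffectSpec]:
    """Documented default study configuration (treatment-only deltas)."""
    specs = [
        EffectSpec("HR", 66.0, 2.0, 12.0, 0.85, None, 2.0, 8.0, 7.0, 1.5, "bpm"),
        EffectSpec("PEP", 83.0, -3.0, -8.0, 0.85, None, 2.0, 8.0, 8.0, 1.5, "ms"),
        EffectSpec("LVET", 288.0, 0.0, -15.0, 0.85, None, 2.0, 8.0, 18.0, 2.5, "ms"),
        EffectSpec("SV", 37.6, 0.0, -5.0, 0.85, None, 2.0, 8.0, 7.0, 1.2, "mL"),
        EffectSpec("MAP", 80.0, 3.0, 10.0, 0.85, None, 2.0, 8.0, 8.0, 1.5, "mmHg"),
        EffectSpec("HF", 6.35, 0.3, -0.8, 0.85, None, 2.0, 8.0, 0.8, 0.25, "log ms^2"),
        EffectSpec(
            "PUPIL", 1000.0, 50.0, 200.0, 0.85, None, 1.0, 4.0, 80.0, 15.0, "a.u."
        ),
        EffectSpec("PAIN", 0.0, 0.0, 60.0, 0.9, None, 0.0, 0.0, 8.0, 6.0, "0-100"),
    ]
    return {s.measure: s for s in specs}


def null_effect_specs() -> dict[str, EffectSpec]:
    """Defaults with every condition/habituation delta zeroed (null config)."""
    return {
        name: replace(spec, anticipatory_delta=0.0, evoked_delta=0.0)
        for name, spec in default_effect_specs().items()
    }


def _evoked_shape(t: np.ndarray, protocol: ProtocolDefinition, lag: float, ramp: float):
    """Ramp-in/plateau/ramp-out window over the immersion epoch, in [0, 1]."""
    i_start, i_stop = protocol.epoch_interval("immersion")
    s = np.zeros_like(t)
    on = i_start + lag
    if ramp > 0:
        s = np.clip((t - on) / ramp, 0.0, 1.0)
        s = np.minimum(s, np.clip(1.0 - (t - i_stop) / ramp, 0.0, 1.0))
    else:
        s = ((t >= on) & (t < i_stop)).astype(float)
    s[t < on] = 0.0
    return s


def truth_profile(
    spec: EffectSpec,
    protocol: ProtocolDefinition | None = None,
    trial: int = 1,
    condition: str = "treatment",
    subject_offset: float = 0.0,
) -> np.ndarray:
    """Noiseless 1-Hz truth profile for one subject x condition x trial.

    ``trial`` is 1-based; deltas apply under treatment only and decay as
    ``h**(trial-1)``.
    """
    protocol = protocol or make_default_protocol()
    t = np.arange(protocol.n_seconds, dtype=float)
    profile = np.full_like(t, spec.baseline_level + subject_offset)
    if condition == "treatment":
        k = trial - 1
        i_start = protocol.epoch_interval("immersion")[0]
        antic = spec.anticipatory_delta * spec.h_anticipatory**k
        profile[t < i_start] += antic
        evoked = spec.evoked_delta * spec.habituation_ratio**k
        profile += evoked * _evoked_shape(t, protocol, spec.onset_lag_s, spec.ramp_s)
    elif condition != "control":
        raise ValueError(f"unknown condition {condition!r}")
    return profile


@dataclass(frozen=True)
class EEGBandEffect:
    """Band-oscillator amplitude structure for the synthetic EEG montage."""

    band: str
    center_hz: float
    baseline_amp: float  # uV, all channels
    evoked_delta: float = 0.0  # uV, at target channels, treatment immersion
    habituation_ratio: float = 1.0
    target_channels: tuple[str, ...] = ()


def default_eeg_band_effects() -> dict[str, EEGBandEffect]:
    return {
        "delta": EEGBandEffect("delta", 2.0, 6.0),
        "theta": EEGBandEffect("theta", 5.5, 5.0),
        "alpha": EEGBandEffect(
            "alpha",
            10.0,
            8.0,
            evoked_delta=6.0,
            habituation_ratio=0.85,
            target_channels=("C3", "C4", "Cz", "CP1", "CP2", "Pz"),
        ),
        "beta": EEGBandEffect("beta", 20.0, 3.0),
    }
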