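"""Whole-study simulation: paired treatment/control sessions plus truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import CONDITIONS, N_TRIALS
from ..protocol import ProtocolDefinition, make_default_protocol
from .effects import (
    EEGBandEffect,
    EffectSpec,
    default_eeg_band_effects,
    default_effect_specs,
    truth_profile,
)
from .render import RenderConfig, TrialSignalSet, render_trial
from .timeline import BeatTruth, simulate_beat_timeline

__all__ = ["SessionDataset", "GroundTruthTables", "simulate_study"]


@dataclass
class SessionDataset:
    """One subject's five-trial session in one condition."""

    subject: str
    condition: str
    start_time: str  # "AM" or "PM"
    trials: list[TrialSignalSet]
    pain_ratings: list[int]
    cortisol_samples: list[float]  # ug/dL at pre-T1, pre-T3, post-T5

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if len(self.trials) != N_TRIALS:
            raise ValueError("a session holds exactly 5 trials")
        if any(not (0 <= p <= 100) for p in self.pain_ratings):
            raise ValueError("pain ratings must lie in [0, 100]")
        if any(c <= 0 for c in self.cortisol_samples):
            raise ValueError("cortisol must be positive")


@dataclass
class GroundTruthTables:
    """Generator truth per subject x condition x trial, for recovery tests."""

    master_seed: int
    specs: dict[str, EffectSpec]
    band_effects: dict[str, EEGBandEffect]
    # keys: (subject, condition, trial 1-based)
    profiles: dict[tuple[str, str, int], dict[str, np.ndarray]] = field(
        default_factory=dict
    )
    beats: dict[tuple[str, str, int], BeatTruth] = field(default_factory=dict)
    band_amps: dict[tuple[str, str, int], dict[str, np.ndarray]] = field(
        default_factory=dict
    )
    subject_offsets: dict[str, dict[str, float]] = field(default_factory=dict)
    pain: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    cortisol: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    condition_order: dict[str, tuple[str, str]] = field(default_factory=dict)

    def cells(self) -> list[tuple[str, str, int]]:
        return sorted(self.profiles.keys())

    def profiles_frame(self) -> pd.DataFrame:
        rows = []
        for (subj, cond, trial), profs in self.profiles.items():
            for measure, vals in profs.items():
                rows.append(
                    pd.DataFrame(
                        {
                            "subject": subj,
                            "condition": cond,
                            "trial": trial,
                            "measure": measure,
                            "t": np.arange(vals.size),
                            "value": vals,
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def _pain_ratings(
    spec: EffectSpec, condition: str, rng: np.random.Generator
) -> np.ndarray:
    """Integer 0-100 ratings; treatment habituates, control sits near zero."""
    ratings = np.zeros(N_TRIALS)
    for k in range(N_TRIALS):
        if condition == "treatment":
            mu = spec.evoked_delta * spec.habituation_ratio**k
            ratings[k] = rng.normal(mu, spec.noise_sd)
        else:
            ratings[k] = abs(rng.normal(0.0, 1.0))  # small jitter around 0
    return np.clip(np.rint(ratings), 0, 100).astype(int)


def _cortisol_samples(
    condition: str,
    rng: np.random.Generator,
    base: float = 0.25,
    decline: float = 0.04,
    condition_offset: float = 0.05,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Session-declining cortisol (ug/dL) with a treatment offset."""
    out = np.empty(3)
    for i in range(3):
        mu = base - decline * i
        if condition == "treatment":
            mu += condition_offset
        out[i] = max(rng.normal(mu, noise_sd), 0.01)
    return out


def _band_amp_truth(
    band_effects: dict[str, EEGBandEffect],
    channels: tuple[str, ...],
    protocol: ProtocolDefinition,
    trial: int,
    condition: str,
) -> dict[str, np.ndarray]:
    n_sec = protocol.n_seconds
    imm = protocol.epoch_slice("immersion")
    out = {}
    for band, eff in band_effects.items():
        amp = np.full((len(channels), n_sec), eff.baseline_amp, dtype=float)
        if condition == "treatment" and eff.evoked_delta:
            delta = eff.evoked_delta * eff.habituation_ratio ** (trial - 1)
            for c, name in enumerate(channels):
                if name in eff.target_channels:
                    amp[c, imm] += delta
        out[band] = amp
    return out


def simulate_study(
    n_subjects: int,
    specs: dict[str, EffectSpec] | None = None,
    seed: int = 0,
    protocol: ProtocolDefinition | None = None,
    render_config: RenderConfig | None = None,
    band_effects: dict[str, EEGBandEffect] | None = None,
    render: bool = True,
    rr_jitter_sd: float = 0.01,
) -> tuple[list[SessionDataset], GroundTruthTables]:
    """Simulate a counterbalanced paired-condition study.

    Every subject contributes one treatment and one control session; the
    order alternates across subjects, as does the AM/PM start time.
    With ``render=False`` only the ground truth (beat timelines, profiles,
    scalars) is produced and the returned session list is empty.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    protocol = protocol or make_default_protocol()
    specs = specs or default_effect_specs()
    band_effects = band_effects or default_eeg_band_effects()
    cfg = render_config or RenderConfig()

    sessions: list[SessionDataset] = []
    truth = GroundTruthTables(master_seed=seed, specs=specs, band_effects=band_effects)

    for s in range(n_subjects):
        subject = f"s{s:03d}"
        rng_subj = np.random.default_rng([seed, s])
        offsets = {
            name: float(rng_subj.normal(0.0, spec.between_subject_sd))
            for name, spec in specs.items()
        }
        truth.subject_offsets[subject] = offsets
        order = (
            ("treatment", "control") if s % 2 == 0 else ("control", "treatment")
        )
        truth.condition_order[subject] = order
        start_time = "AM" if s % 2 == 0 else "PM"

        for cond in CONDITIONS:
            rng_sess = np.random.default_rng([seed, s, CONDITIONS.index(cond)])
            pain = _pain_ratings(specs["PAIN"], cond, rng_sess) if "PAIN" in specs \
                else np.zeros(N_TRIALS, dtype=int)
            cortisol = _cortisol_samples(cond, rng_sess)
            truth.pain[(subject, cond)] = pain
            truth.cortisol[(subject, cond)] = cortisol

            trials: list[TrialSignalSet] = []
            for k in range(1, N_TRIALS + 1):
                cell_rng = np.random.default_rng(
                    [seed, s, CONDITIONS.index(cond), k]
                )
                beat = simulate_beat_timeline(
                    specs,
                    protocol,
                    trial=k,
                    condition=cond,
                    seed=cell_rng,
                    subject_offsets=offsets,
                    rr_jitter_sd=rr_jitter_sd,
                    measure_noise=True,
                )
                profiles = dict(beat.profiles)
                if "PUPIL" in specs:
                    profiles["PUPIL"] = truth_profile(
                        specs["PUPIL"], protocol, k, cond, offsets.get("PUPIL", 0.0)
                    )
                band_amps = _band_amp_truth(
                    band_effects, cfg.eeg_channels, protocol, k, cond
                )
                key = (subject, cond, k)
                truth.profiles[key] = profiles
                truth.beats[key] = beat
                truth.band_amps[key] = band_amps
                if render:
                    trials.append(
                        render_trial(
                            beat,
                            protocol,
                            cfg,
                            seed=cell_rng,
                            trial=k,
                            band_amp_truth=band_amps,
                            band_effects=band_effects,
                            pupil_profile=profiles.get("PUPIL"),
                        )
                    )
            if render:
                sessions.append(
                    SessionDataset(
                        subject=subject,
                        condition=cond,
                        start_time=start_time,
                        trials=trials,
                        pain_ratings=[int(p) for p in pain],
                        cortisol_samples=[float(c) for c in cortisol],
                    )
                )
    return sessions, truth
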