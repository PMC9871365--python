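"""Panel-level simulation: 1-Hz measure panels straight from truth profiles.

For calibration and power studies the waveform rendering/extraction loop is
unnecessary overhead: the statistical framework only sees 1-Hz panels. This
shortcut draws panels as truth profile + between-subject offset + white
within-trial noise, with exactly the effect structure the full generator
embeds.
"""

from __future__ import annotations

import numpy as np

from ..core import CONDITIONS, N_TRIALS, MeasurePanel
from ..protocol import ProtocolDefinition, make_default_protocol
from .effects import EffectSpec, default_effect_specs, truth_profile

__all__ = ["simulate_measure_panel"]


def simulate_measure_panel(
    measure: str,
    n_subjects: int,
    specs: dict[str, EffectSpec] | None = None,
    seed: int | np.random.Generator | None = None,
    protocol: ProtocolDefinition | None = None,
    noise_ar: float = 0.0,
) -> tuple[MeasurePanel, np.ndarray]:
    """Draw a subjects x 2 x 5 x n_seconds panel plus its noiseless truth.

    ``noise_ar`` > 0 adds AR(1) temporal correlation to the within-trial
    noise (innovations scaled to keep the marginal SD at ``noise_sd``).

    Returns ``(panel, truth)`` where ``truth[s, c, k, t]`` is the noiseless
    profile including the subject offset.
    """
    protocol = protocol or make_default_protocol()
    specs = specs or default_effect_specs()
    spec = specs[measure]
    rng = np.random.default_rng(seed)
    n_t = protocol.n_seconds

    truth = np.empty((n_subjects, 2, N_TRIALS, n_t))
    offsets = rng.normal(0.0, spec.between_subject_sd, n_subjects)
    for s in range(n_subjects):
        for ci, cond in enumerate(CONDITIONS):
            for k in range(N_TRIALS):
                truth[s, ci, k] = truth_profile(
                    spec, protocol, k + 1, cond, float(offsets[s])
                )
    noise = rng.normal(0.0, 1.0, truth.shape)
    if noise_ar > 0:
        phi = noise_ar
        for t in range(1, n_t):
            noise[..., t] = phi * noise[..., t - 1] + np.sqrt(1 - phi**2) * noise[..., t]
    values = truth + spec.noise_sd * noise
    panel = MeasurePanel(measure=measure, values=values, units=spec.units)
    return panel, truth
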