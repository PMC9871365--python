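import numpy as np
import pytest

from stressmux.protocol import make_default_protocol
from stressmux.synth import (
    RenderConfig,
    default_effect_specs,
    null_effect_specs,
    render_trial,
    simulate_beat_timeline,
    simulate_study,
)


@pytest.fixture(scope="session")
def protocol():
    return make_default_protocol()


@pytest.fixture(scope="session")
def specs():
    return default_effect_specs()


@pytest.fixture(scope="session")
def null_specs():
    return null_effect_specs()


@pytest.fixture(scope="session")
def clean_cfg():
    """Renderer with every noise source disabled."""
    return RenderConfig(
        ecg_noise_mv=0.0,
        dzdt_noise_rel=0.0,
        z0_noise_ohm=0.0,
        bp_noise_mmhg=0.0,
        pupil_noise=0.0,
        blink_rate_hz=0.0,
    )


@pytest.fixture(scope="session")
def beat_truth(specs, protocol):
    return simulate_beat_timeline(
        specs, protocol, trial=1, condition="treatment", seed=11,
        rr_jitter_sd=0.01, measure_noise=True,
    )


@pytest.fixture(scope="session")
def clean_trial(beat_truth, protocol, clean_cfg):
    return render_trial(beat_truth, protocol, clean_cfg, seed=12)


@pytest.fixture(scope="session")
def noisy_trial(beat_truth, protocol):
    return render_trial(beat_truth, protocol, seed=12)


@pytest.fixture(scope="session")
def small_study():
    """Two-subject fully rendered study (shared; ~10 s to build)."""
    sessions, truth = simulate_study(2, seed=5)
    return sessions, truth


def per_beat_truth_errors(fid, beat_truth):
    """Match detected beats to generator truth; absolute PEP/LVET errors (ms)."""
    ok = fid["valid"].to_numpy()
    true_pep = np.interp(fid["r_time"], beat_truth.r_times, beat_truth.pep_ms)
    true_lvet = np.interp(fid["r_time"], beat_truth.r_times, beat_truth.lvet_ms)
    pep_err = np.abs(fid["pep_ms"].to_numpy() - true_pep)[ok]
    lvet_err = np.abs(fid["lvet_ms"].to_numpy() - true_lvet)[ok]
    return pep_err, lvet_err
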