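"""Pointwise permutation statistics on 1-Hz measure panels.

The two-way condition x trial ANOVA (with permutation nulls) runs at every
in-scope second of the trial; significant interactions gate within-condition
pairwise trial contrasts (T1vT5, T1vT3, T3vT5). The raw analysis covers the
pre-immersion window (0-65 s), the baseline-corrected analysis covers
immersion and recovery (65 s onward). A three-way variant adds a
pre/post-baseline factor over 65-140 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..core import CONDITIONS, MeasurePanel
from ..protocol import ProtocolDefinition, make_default_protocol
from .anova import paired_t, rm_anova_2way, rm_anova_3way
from .permutation import (
    condition_swaps,
    null_f_condition_swap,
    null_f_trial_shuffle,
)

__all__ = [
    "SignificanceTracks",
    "baseline_correct",
    "pointwise_framework",
    "baseline_shift_anova",
    "CONTRASTS",
]

# Trial-pair contrasts, 0-based trial indices (T1..T5 -> 0..4).
CONTRASTS: dict[str, tuple[int, int]] = {
    "T1vT5": (0, 4),
    "T1vT3": (0, 2),
    "T3vT5": (2, 4),
}


@dataclass
class SignificanceTracks:
    """Per-timepoint boolean outcome tracks.

    ``anova[effect][t]`` flags a significant permutation-ANOVA effect;
    ``pairwise[(condition, contrast)][t]`` flags a gated trial contrast.
    Out-of-scope or excluded timepoints are False everywhere and listed in
    ``in_scope`` / ``excluded``.
    """

    n_time: int
    alpha: float
    anova: dict[str, np.ndarray] = field(default_factory=dict)
    pairwise: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    in_scope: np.ndarray | None = None
    excluded: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": np.arange(self.n_time), "in_scope": self.in_scope}
        for eff, track in self.anova.items():
            cols[eff] = track
        for (cond, contrast), track in self.pairwise.items():
            cols[f"{cond}_{contrast}"] = track
        return pd.DataFrame(cols)


def baseline_correct(
    panel: MeasurePanel,
    protocol: ProtocolDefinition | None = None,
    window_s: float = 15.0,
) -> MeasurePanel:
    """Subtract each trial's late-baseline mean from its full time course.

    The reference is the mean over the final ``window_s`` seconds of the
    baseline epoch (seconds [25, 40) under the default protocol), computed
    per subject x condition x trial. Trials whose reference window is fully
    masked become fully masked.
    """
    protocol = protocol or make_default_protocol()
    b_start, b_stop = protocol.epoch_interval("baseline")
    if b_stop - b_start < window_s:
        raise ValueError("baseline epoch shorter than correction window")
    lo, hi = int(round(b_stop - window_s)), int(round(b_stop))
    out = panel.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        ref = np.nanmean(
            np.where(out.mask[..., lo:hi], out.values[..., lo:hi], np.nan), axis=-1
        )
    out.values = out.values - ref[..., None]
    out.mask = out.mask & np.isfinite(out.values)
    out.values = np.where(out.mask, out.values, np.nan)
    return out


def _scope_timepoints(
    analysis: str, protocol: ProtocolDefinition
) -> np.ndarray:
    imm_start = int(round(protocol.epoch_interval("immersion")[0]))
    if analysis == "raw":
        return np.arange(0, imm_start)
    if analysis in ("corrected", "baseline-corrected"):
        return np.arange(imm_start, protocol.n_seconds)
    raise ValueError(f"unknown analysis {analysis!r}")


def _rng_at(seed, t: int) -> np.random.Generator:
    # Per-timepoint stream: deterministic, independent across timepoints.
    return np.random.default_rng([0 if seed is None else seed, t])


def _complete_subjects(Yt: np.ndarray) -> np.ndarray:
    return np.isfinite(Yt).all(axis=(1, 2))


def pointwise_framework(
    panel: MeasurePanel,
    protocol: ProtocolDefinition | None = None,
    analysis: str = "corrected",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    effects: tuple[str, ...] = ("condition", "trial", "interaction"),
    gate_pairwise: bool = True,
    max_masked_frac: float = 0.25,
    min_run_s: int = 0,
    timepoints: np.ndarray | None = None,
) -> tuple[SignificanceTracks, pd.DataFrame]:
    """Run the pointwise permutation ANOVA framework over one panel.

    For ``analysis='corrected'`` the panel is baseline-corrected first and
    tests run over immersion+recovery; ``'raw'`` tests the pre-immersion
    window on the panel as given. Where the condition x trial interaction is
    significant, within-condition sign-flip paired contrasts are added.
    Timepoints masked for more than ``max_masked_frac`` of subjects are
    excluded. ``min_run_s > 0`` applies a contiguity filter to the tracks.
    ``timepoints`` further restricts the tested seconds (intersected with
    the analysis scope).

    Returns the boolean tracks and a long results frame (one row per
    timepoint x effect).
    """
    protocol = protocol or make_default_protocol()
    if analysis in ("corrected", "baseline-corrected"):
        panel = baseline_correct(panel, protocol)
    tps = _scope_timepoints(analysis, protocol)
    if timepoints is not None:
        tps = np.intersect1d(tps, np.asarray(timepoints, dtype=int))
    n_time = protocol.n_seconds
    V = panel.values
    n_subj = V.shape[0]
    if n_subj < 3:
        raise ValueError("need at least 3 subjects")

    tracks = SignificanceTracks(n_time=n_time, alpha=alpha)
    tracks.in_scope = np.zeros(n_time, dtype=bool)
    tracks.in_scope[tps] = True
    for eff in effects:
        tracks.anova[eff] = np.zeros(n_time, dtype=bool)
    if gate_pairwise and "interaction" in effects:
        for cond in CONDITIONS:
            for contrast in CONTRASTS:
                tracks.pairwise[(cond, contrast)] = np.zeros(n_time, dtype=bool)

    rows: list[dict] = []
    for t in tps:
        Yt = V[..., t]  # (n, 2, 5)
        complete = _complete_subjects(Yt)
        if (~complete).sum() > max_masked_frac * n_subj:
            tracks.excluded.append(int(t))
            tracks.in_scope[t] = False
            continue
        Yc = Yt[complete]
        if Yc.shape[0] < 3:
            tracks.excluded.append(int(t))
            tracks.in_scope[t] = False
            continue
        rng = _rng_at(seed, int(t))
        obs = rm_anova_2way(Yc, effects=effects)
        swap_effects = tuple(e for e in effects if e != "trial")
        nulls = {}
        if swap_effects:
            nulls.update(null_f_condition_swap(Yc, n_perm, rng, effects=swap_effects))
        if "trial" in effects:
            nulls["trial"] = null_f_trial_shuffle(Yc, n_perm, rng)
        p_int = None
        for eff in effects:
            p = float(np.mean(nulls[eff] >= obs[eff].F))
            if eff == "interaction":
                p_int = p
            tracks.anova[eff][t] = p < alpha
            rows.append(
                dict(
                    t=int(t),
                    effect=eff,
                    statistic=float(obs[eff].F),
                    df1=obs[eff].df1,
                    df2=obs[eff].df2,
                    eta_p_sq=float(obs[eff].eta_p_sq),
                    p_null=p,
                    flagged=p < alpha,
                )
            )
        if gate_pairwise and p_int is not None and p_int < alpha:
            for ci, cond in enumerate(CONDITIONS):
                for contrast, (i, j) in CONTRASTS.items():
                    d = Yc[:, ci, i] - Yc[:, ci, j]
                    t_obs, df = paired_t(d)
                    signs = rng.choice((1.0, -1.0), size=(n_perm, d.size))
                    null_t, _ = paired_t(signs * d, axis=-1)
                    p = float(np.mean(np.abs(null_t) >= abs(t_obs)))
                    tracks.pairwise[(cond, contrast)][t] = p < alpha
                    rows.append(
                        dict(
                            t=int(t),
                            effect=f"{cond}_{contrast}",
                            statistic=float(t_obs),
                            df1=1,
                            df2=df,
                            eta_p_sq=np.nan,
                            p_null=p,
                            flagged=p < alpha,
                        )
                    )
    if min_run_s > 1:
        for track in list(tracks.anova.values()) + list(tracks.pairwise.values()):
            _apply_min_run(track, min_run_s)
    return tracks, pd.DataFrame(rows)


def _apply_min_run(track: np.ndarray, k: int) -> None:
    """Zero out flagged runs shorter than ``k`` samples, in place."""
    n = track.size
    i = 0
    while i < n:
        if track[i]:
            j = i
            while j < n and track[j]:
                j += 1
            if j - i < k:
                track[i:j] = False
            i = j
        else:
            i += 1


def _swap_axis(Y: np.ndarray, flips: np.ndarray, axis: int) -> np.ndarray:
    """Per-subject 2-level axis swap. Y (n, ...), flips (P, n) -> (P, n, ...)."""
    shape = [flips.shape[0], flips.shape[1]] + [1] * (Y.ndim - 1)
    f = flips.reshape(shape)
    sl = [slice(None)] * Y.ndim
    sl[axis] = slice(None, None, -1)
    return np.where(f, Y[tuple(sl)], Y)


def baseline_shift_anova(
    panel: MeasurePanel,
    protocol: ProtocolDefinition | None = None,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
    window_s: float = 15.0,
    t_stop: int = 141,
    max_masked_frac: float = 0.25,
) -> tuple[SignificanceTracks, pd.DataFrame]:
    """Three-way baseline(2) x condition(2) x trial(5) pointwise ANOVA.

    The baseline factor pairs each trial's late-baseline mean (final
    ``window_s`` s of the baseline epoch) with a trailing ``window_s``-s
    moving average of the raw series starting at each timepoint, evaluated
    from immersion onset up to (exclusive) ``t_stop``. Permutation nulls
    swap the condition labels for condition-bearing effects, the baseline
    labels for remaining baseline-bearing effects, and shuffle trial labels
    for the trial main effect.
    """
    protocol = protocol or make_default_protocol()
    b_start, b_stop = protocol.epoch_interval("baseline")
    lo, hi = int(round(b_stop - window_s)), int(round(b_stop))
    V = panel.values
    pre = np.nanmean(V[..., lo:hi], axis=-1)  # (n, 2, 5)
    imm_start = int(round(protocol.epoch_interval("immersion")[0]))
    tps = np.arange(imm_start, t_stop)
    w = int(round(window_s))

    n_time = protocol.n_seconds
    effects = (
        "baseline",
        "condition",
        "trial",
        "baseline:condition",
        "baseline:trial",
        "condition:trial",
        "baseline:condition:trial",
    )
    tracks = SignificanceTracks(n_time=n_time, alpha=alpha)
    tracks.in_scope = np.zeros(n_time, dtype=bool)
    tracks.in_scope[tps] = True
    for eff in effects:
        tracks.anova[eff] = np.zeros(n_time, dtype=bool)

    rows: list[dict] = []
    n_subj = V.shape[0]
    for t in tps:
        post = np.nanmean(V[..., t : t + w], axis=-1)  # (n, 2, 5)
        Y = np.stack([pre, post], axis=1)  # (n, 2=baseline, 2=cond, 5=trial)
        complete = np.isfinite(Y).all(axis=(1, 2, 3))
        if (~complete).sum() > max_masked_frac * n_subj or complete.sum() < 3:
            tracks.excluded.append(int(t))
            tracks.in_scope[t] = False
            continue
        Yc = Y[complete]
        rng = _rng_at(seed, int(t))
        obs = rm_anova_3way(Yc)

        cond_flips = condition_swaps(Yc.shape[0], n_perm, rng)
        Y_cswap = _swap_axis(Yc, cond_flips, axis=2)
        null_cond = rm_anova_3way(Y_cswap)
        base_flips = condition_swaps(Yc.shape[0], n_perm, rng)
        Y_bswap = _swap_axis(Yc, base_flips, axis=1)
        null_base = rm_anova_3way(Y_bswap)
        # Trial-label shuffle within subject x baseline x condition.
        keys = rng.random((n_perm,) + Yc.shape)
        idx = np.argsort(keys, axis=-1)
        Y_tshuf = np.take_along_axis(
            np.broadcast_to(Yc, (n_perm,) + Yc.shape), idx, axis=-1
        )
        null_trial = rm_anova_3way(Y_tshuf)

        for eff in effects:
            if "condition" in eff:
                null = null_cond[eff].F
            elif "baseline" in eff:
                null = null_base[eff].F
            else:
                null = null_trial[eff].F
            p = float(np.mean(np.asarray(null) >= obs[eff].F))
            tracks.anova[eff][t] = p < alpha
            rows.append(
                dict(
                    t=int(t),
                    effect=eff,
                    statistic=float(obs[eff].F),
                    df1=obs[eff].df1,
                    df2=obs[eff].df2,
                    eta_p_sq=float(obs[eff].eta_p_sq),
                    p_null=p,
                    flagged=p < alpha,
                )
            )
    return tracks, pd.DataFrame(rows)
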