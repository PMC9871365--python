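"""Scalar entry points: pain ratings, pupil immersion average, EEG band
panels and the cortisol mixed design."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..core import CONDITIONS, MeasurePanel
from ..protocol import ProtocolDefinition, make_default_protocol
from .anova import mixed_anova_2w1b
from .framework import CONTRASTS
from .permutation import (
    PermutationTestResult,
    paired_t_perm,
    rm_anova_2way_perm,
)

__all__ = [
    "pain_analysis",
    "pupil_immersion_analysis",
    "eeg_band_analysis",
    "cortisol_anova",
    "cortisol_mixed_anova",
]


def _gated_pairwise(
    Y: np.ndarray,
    conditions: tuple[str, ...],
    n_perm: int,
    seed,
    skip_zero_variance: bool = True,
) -> dict[tuple[str, str], PermutationTestResult]:
    """Within-condition trial contrasts on a (n, 2, k) table."""
    rng = np.random.default_rng(seed)
    out = {}
    for ci, cond in enumerate(conditions):
        if skip_zero_variance and np.allclose(np.var(Y[:, ci, :], axis=0), 0.0):
            continue  # e.g. control pain ratings: all-zero, no contrast computed
        for contrast, (i, j) in CONTRASTS.items():
            d = Y[:, ci, i] - Y[:, ci, j]
            out[(cond, contrast)] = paired_t_perm(d, n_perm=n_perm, seed=rng)
    return out


def pain_analysis(
    pain: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Condition x trial permutation ANOVA on per-trial pain ratings.

    ``pain`` is (n_subjects, 2, 5). Pairwise contrasts are gated on the
    interaction and skipped for conditions with ~zero variance (the
    control session, when everyone reports no pain).
    """
    pain = np.asarray(pain, dtype=float)
    rng = np.random.default_rng(seed)
    anova = rm_anova_2way_perm(pain, n_perm=n_perm, seed=rng)
    pairwise = {}
    if anova["interaction"].p_null < alpha:
        pairwise = _gated_pairwise(pain, CONDITIONS, n_perm, rng)
    return {"anova": anova, "pairwise": pairwise}


def pupil_immersion_analysis(
    panel: MeasurePanel,
    protocol: ProtocolDefinition | None = None,
    window: tuple[int, int] = (66, 155),
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> dict:
    """Average the pupil panel across the immersion window, then test.

    The window is inclusive seconds (defaults to 66-155); subjects with an
    incomplete averaged table are dropped listwise.
    """
    protocol = protocol or make_default_protocol()
    lo, hi = window
    Y = np.nanmean(panel.values[..., lo : hi + 1], axis=-1)  # (n, 2, 5)
    complete = np.isfinite(Y).all(axis=(1, 2))
    Y = Y[complete]
    rng = np.random.default_rng(seed)
    anova = rm_anova_2way_perm(Y, n_perm=n_perm, seed=rng)
    pairwise = {}
    if anova["interaction"].p_null < alpha:
        pairwise = _gated_pairwise(Y, CONDITIONS, n_perm, rng, skip_zero_variance=False)
    return {"anova": anova, "pairwise": pairwise, "n": int(Y.shape[0])}


def eeg_band_analysis(
    band_panel: pd.DataFrame,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Electrode-wise 2x5 permutation ANOVA per band x period.

    ``band_panel`` is tidy: subject, condition, trial, channel, band,
    period, value. Returns the per-electrode results frame and, for each
    band x period with at least one significant interaction electrode, the
    gated pairwise contrasts computed on the average of the contributing
    electrodes.
    """
    rng = np.random.default_rng(seed)
    subjects = sorted(band_panel["subject"].unique())
    s_idx = {s: i for i, s in enumerate(subjects)}
    c_idx = {c: i for i, c in enumerate(CONDITIONS)}
    rows = []
    followups: dict[tuple[str, str], dict] = {}
    for (band, period), grp in band_panel.groupby(["band", "period"]):
        channels = sorted(grp["channel"].unique())
        cubes = {}
        for ch, sub in grp.groupby("channel"):
            Y = np.full((len(subjects), 2, 5), np.nan)
            Y[
                sub["subject"].map(s_idx),
                sub["condition"].map(c_idx),
                sub["trial"].to_numpy(dtype=int) - 1,
            ] = sub["value"].to_numpy(dtype=float)
            cubes[ch] = Y
        interacting = []
        for ch in channels:
            Y = cubes[ch]
            ok = np.isfinite(Y).all(axis=(1, 2))
            res = rm_anova_2way_perm(Y[ok], n_perm=n_perm, seed=rng)
            for eff, r in res.items():
                rows.append(
                    dict(
                        band=band, period=period, channel=ch, effect=eff,
                        F=r.statistic, df1=r.df1, df2=r.df2,
                        eta_p_sq=r.eta_p_sq, p_null=r.p_null,
                        flagged=r.p_null < alpha,
                    )
                )
            if res["interaction"].p_null < alpha:
                interacting.append(ch)
        if interacting:
            Y = np.nanmean([cubes[ch] for ch in interacting], axis=0)
            ok = np.isfinite(Y).all(axis=(1, 2))
            followups[(band, period)] = {
                "channels": interacting,
                "pairwise": _gated_pairwise(
                    Y[ok], CONDITIONS, n_perm, rng, skip_zero_variance=False
                ),
            }
    return pd.DataFrame(rows), followups


def cortisol_anova(
    cortisol: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict[str, PermutationTestResult]:
    """Within-subject condition(2) x sample(3) permutation ANOVA.

    ``cortisol`` is (n_subjects, 2, 3) in ug/dL, samples ordered
    pre-T1, pre-T3, post-T5. Effect keys: condition, trial (the sample
    factor), interaction.
    """
    Y = np.asarray(cortisol, dtype=float)
    res = rm_anova_2way_perm(Y, n_perm=n_perm, seed=seed)
    res["sample"] = res.pop("trial")
    res["sample"].effect = "sample"
    return res


def cortisol_mixed_anova(
    cortisol: np.ndarray,
    start_times: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict[str, PermutationTestResult]:
    """Mixed ANOVA: start time (AM/PM) between, condition x sample within.

    Permutation nulls shuffle group labels across subjects for
    between-involving effects and within-subject factor labels otherwise.
    """
    Y = np.asarray(cortisol, dtype=float)
    groups = np.asarray(start_times)
    rng = np.random.default_rng(seed)
    obs = mixed_anova_2w1b(Y, groups)
    n = Y.shape[0]

    null_stats: dict[str, list[float]] = {k: [] for k in obs}
    for _ in range(n_perm):
        g_perm = rng.permutation(groups)
        flips_c = rng.random(n) < 0.5
        Yc = np.where(flips_c[:, None, None], Y[:, ::-1, :], Y)
        keys = rng.random(Y.shape)
        Ys = np.take_along_axis(Y, np.argsort(keys, axis=-1), axis=-1)
        res_g = mixed_anova_2w1b(Y, g_perm)
        res_c = mixed_anova_2w1b(Yc, groups)
        res_s = mixed_anova_2w1b(Ys, groups)
        for eff in obs:
            if "group" in eff:
                null_stats[eff].append(res_g[eff].F)
            elif "condition" in eff:
                null_stats[eff].append(res_c[eff].F)
            else:
                null_stats[eff].append(res_s[eff].F)

    out = {}
    for eff, r in obs.items():
        p = float(np.mean(np.asarray(null_stats[eff]) >= r.F))
        out[eff] = PermutationTestResult(
            effect=eff, statistic=float(r.F), df1=r.df1, df2=r.df2,
            p_null=p, eta_p_sq=float(r.eta_p_sq), n_perm=n_perm,
        )
    return out
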