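"""Permutation null distributions for within-subject F and t statistics.

Null draws shuffle labels within participants: condition-type effects swap
each subject's condition labels with probability 1/2 (carrying the full
trial set along), trial effects permute trial labels within subject x
condition, and paired contrasts flip difference signs per subject.
``p_null`` is the fraction of null statistics >= the observed one (strict
count, observed draw not added to the null set).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .anova import paired_t, rm_anova_2way

__all__ = [
    "PermutationTestResult",
    "permutation_p",
    "rm_anova_2way_perm",
    "paired_t_perm",
    "null_f_condition_swap",
    "null_f_trial_shuffle",
]

_F_EFFECTS = ("condition", "trial", "interaction")


@dataclass
class PermutationTestResult:
    effect: str
    statistic: float
    df1: int
    df2: int
    p_null: float
    eta_p_sq: float | None
    n_perm: int
    seed: int | None = None


def _p_from_null(null: np.ndarray, observed, axis: int = 0) -> np.ndarray:
    return np.mean(null >= observed, axis=axis)


def condition_swaps(n_subjects: int, n_perm: int, rng: np.random.Generator):
    """Boolean (n_perm, n_subjects) array: True = swap that subject's labels."""
    return rng.random((n_perm, n_subjects)) < 0.5


def _apply_condition_swap(Y: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """Y (..., n, 2, b), flips (P, n) -> (P, ..., n, 2, b)."""
    extra = Y.ndim - 3
    f = flips.reshape(flips.shape[0], *([1] * extra), flips.shape[1], 1, 1)
    return np.where(f, Y[..., ::-1, :], Y)


def null_f_condition_swap(
    Y: np.ndarray, n_perm: int, rng: np.random.Generator, effects=_F_EFFECTS
) -> dict[str, np.ndarray]:
    """Null F distributions from per-subject condition-label swaps.

    ``Y`` is ``(n, 2, b)``; returns arrays of length ``n_perm`` per effect.
    """
    n = Y.shape[0]
    flips = condition_swaps(n, n_perm, rng)
    Yp = _apply_condition_swap(Y, flips)
    res = rm_anova_2way(Yp, effects=tuple(effects))
    return {e: np.asarray(res[e].F) for e in effects}


def null_f_trial_shuffle(
    Y: np.ndarray, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null F(trial) from permuting trial labels within subject x condition."""
    n, a, b = Y.shape
    keys = rng.random((n_perm, n, a, b))
    idx = np.argsort(keys, axis=-1)
    Yp = np.take_along_axis(np.broadcast_to(Y, (n_perm, n, a, b)), idx, axis=-1)
    return np.asarray(rm_anova_2way(Yp, effects=("trial",))["trial"].F)


def paired_t_perm(
    d: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = True,
    exhaustive: bool | None = None,
) -> PermutationTestResult:
    """Sign-flip permutation test on paired difference scores ``d``.

    With ``exhaustive=True`` (or ``None`` and ``n <= 12``... explicit only)
    all 2**n sign patterns are enumerated instead of sampled.
    """
    d = np.asarray(d, dtype=float)
    n = d.size
    t_obs, df = paired_t(d)
    if exhaustive:
        signs = np.array(list(product((1.0, -1.0), repeat=n)))
        n_draws = signs.shape[0]
    else:
        rng = np.random.default_rng(seed)
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        n_draws = n_perm
    null_t, _ = paired_t(signs * d, axis=-1)
    if two_sided:
        p = float(_p_from_null(np.abs(null_t), abs(t_obs)))
    else:
        p = float(_p_from_null(null_t, t_obs))
    return PermutationTestResult(
        effect="paired_t",
        statistic=float(t_obs),
        df1=1,
        df2=df,
        p_null=p,
        eta_p_sq=None,
        n_perm=n_draws,
    )


def rm_anova_2way_perm(
    Y: np.ndarray,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    effects=_F_EFFECTS,
) -> dict[str, PermutationTestResult]:
    """Observed two-way RM ANOVA plus permutation p per effect.

    Condition and interaction nulls use condition-label swaps; the trial
    null permutes trial labels within subject x condition.
    """
    Y = np.asarray(Y, dtype=float)
    rng = np.random.default_rng(seed)
    obs = rm_anova_2way(Y)
    out: dict[str, PermutationTestResult] = {}
    swap_effects = [e for e in effects if e in ("condition", "interaction")]
    if swap_effects:
        nulls = null_f_condition_swap(Y, n_perm, rng, effects=swap_effects)
        for e in swap_effects:
            out[e] = PermutationTestResult(
                effect=e,
                statistic=float(obs[e].F),
                df1=obs[e].df1,
                df2=obs[e].df2,
                p_null=float(_p_from_null(nulls[e], obs[e].F)),
                eta_p_sq=float(obs[e].eta_p_sq),
                n_perm=n_perm,
            )
    if "trial" in effects:
        null = null_f_trial_shuffle(Y, n_perm, rng)
        e = "trial"
        out[e] = PermutationTestResult(
            effect=e,
            statistic=float(obs[e].F),
            df1=obs[e].df1,
            df2=obs[e].df2,
            p_null=float(_p_from_null(null, obs[e].F)),
            eta_p_sq=float(obs[e].eta_p_sq),
            n_perm=n_perm,
        )
    return out


def permutation_p(
    observed: float,
    data: np.ndarray,
    effect: str,
    n_perm: int = 1000,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = True,
) -> float:
    """Permutation p-value for one effect on a (n, 2, b) table or paired diffs.

    ``effect`` is one of ``condition``, ``trial``, ``interaction`` (F tests
    on a cell-mean table) or ``paired_t`` (sign-flip test on a difference
    vector).
    """
    import warnings

    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is small; p_null resolution is coarse")
    rng = np.random.default_rng(seed)
    if effect == "paired_t":
        d = np.asarray(data, dtype=float)
        n = d.size
        signs = rng.choice((1.0, -1.0), size=(n_perm, n))
        null_t, _ = paired_t(signs * d, axis=-1)
        null = np.abs(null_t) if two_sided else null_t
        obs = abs(observed) if two_sided else observed
        return float(_p_from_null(null, obs))
    if effect in ("condition", "interaction"):
        null = null_f_condition_swap(data, n_perm, rng, effects=(effect,))[effect]
    elif effect == "trial":
        null = null_f_trial_shuffle(data, n_perm, rng)
    else:
        raise ValueError(f"unknown effect {effect!r}")
    return float(_p_from_null(null, observed))
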