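"""Repeated-measures and mixed ANOVA sums-of-squares decompositions.

All routines operate on balanced cell-mean arrays laid out as
``(..., n_subjects, levels_1, levels_2, ...)`` and are vectorised over any
leading axes (timepoints, permutations). Each within-subject effect is
tested against its own subject-by-effect error term.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

import numpy as np

__all__ = [
    "EffectResult",
    "rm_anova",
    "rm_anova_2way",
    "rm_anova_3way",
    "mixed_anova_2w1b",
    "paired_t",
]


@dataclass
class EffectResult:
    """One ANOVA effect: F statistic, its df pair and partial eta squared."""

    effect: str
    F: np.ndarray | float
    df1: int
    df2: int
    eta_p_sq: np.ndarray | float


def _subsets(items: tuple[int, ...]):
    return chain.from_iterable(combinations(items, r) for r in range(len(items) + 1))


def _marginal_means(
    Y: np.ndarray,
    n_factors: int,
    needed: set[tuple[int, ...]] | None = None,
) -> dict[tuple[int, ...], np.ndarray]:
    """Mean arrays keeping each subset of {subject, factor...} axes.

    Keys are sorted tuples of *kept* trailing-axis offsets, where 0 is the
    subject axis and 1..n_factors are the factor axes; arrays keep dims so
    they broadcast against ``Y``. ``needed`` restricts which subsets are
    computed.
    """
    nd = Y.ndim
    trailing = tuple(range(nd - n_factors - 1, nd))  # subject + factors
    means: dict[tuple[int, ...], np.ndarray] = {}
    for kept in _subsets(tuple(range(n_factors + 1))):
        if needed is not None and kept not in needed:
            continue
        drop = tuple(trailing[i] for i in range(n_factors + 1) if i not in kept)
        means[kept] = Y.mean(axis=drop, keepdims=True) if drop else Y
    return means


def _effect_ss(
    means: dict[tuple[int, ...], np.ndarray],
    effect: tuple[int, ...],
    trailing_axes: tuple[int, ...],
    full_shape: tuple[int, ...],
) -> np.ndarray:
    """Sum over all cells of the squared inclusion-exclusion effect array."""
    e = None
    for sub in _subsets(effect):
        sign = (-1) ** (len(effect) - len(sub))
        term = sign * means[tuple(sorted(sub))]
        e = term if e is None else e + term
    # Each squared value is replicated over the collapsed (singleton) axes,
    # so scale by their sizes instead of materialising the full grid.
    mult = 1
    for ax in trailing_axes:
        if e.shape[ax] == 1:
            mult *= full_shape[ax]
    return mult * np.sum(np.square(e), axis=trailing_axes)


def _f_ratio(ss_eff, df1, ss_err, df2):
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_eff / df1) / (ss_err / df2)
        denom = ss_eff + ss_err
        eta = np.where(denom > 0, ss_eff / np.where(denom > 0, denom, 1.0), 0.0)
    F = np.where(ss_err > 0, F, np.where(ss_eff > 0, np.inf, 0.0))
    return F, eta


def rm_anova(
    Y: np.ndarray,
    factor_names: tuple[str, ...],
    effects: tuple[str, ...] | None = None,
) -> dict[str, EffectResult]:
    """Fully within-subject ANOVA on ``(..., n, l_1, ..., l_k)`` data.

    Returns one :class:`EffectResult` per non-empty subset of factors, keyed
    by ``"name"`` or ``"name1:name2"`` for interactions. ``effects``
    restricts computation to the named subset (a speed knob for permutation
    loops).
    """
    Y = np.asarray(Y, dtype=float)
    k = len(factor_names)
    if Y.ndim < k + 1:
        raise ValueError("data has fewer axes than subject + factors")
    n = Y.shape[-(k + 1)]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if np.isnan(Y).any():
        raise ValueError("rm_anova requires complete (NaN-free) cells")
    levels = Y.shape[-k:]
    trailing = tuple(range(Y.ndim - k - 1, Y.ndim))
    full_shape = Y.shape

    wanted = []
    for eff in _subsets(tuple(range(1, k + 1))):
        if not eff:
            continue
        name = ":".join(factor_names[i - 1] for i in eff)
        if effects is None or name in effects:
            wanted.append((name, eff))
    needed: set[tuple[int, ...]] = set()
    for _, eff in wanted:
        for sub in _subsets(tuple(sorted((0,) + eff))):
            needed.add(tuple(sorted(sub)))
    means = _marginal_means(Y, k, needed)

    out: dict[str, EffectResult] = {}
    for name, eff in wanted:
        df1 = int(np.prod([levels[i - 1] - 1 for i in eff]))
        df2 = df1 * (n - 1)
        ss_eff = _effect_ss(means, eff, trailing, full_shape)
        ss_err = _effect_ss(means, tuple(sorted((0,) + eff)), trailing, full_shape)
        F, eta = _f_ratio(ss_eff, df1, ss_err, df2)
        out[name] = EffectResult(name, F, df1, df2, eta)
    return out


_2WAY_ALIASES = {"condition": "condition", "trial": "trial",
                 "interaction": "condition:trial"}


def rm_anova_2way(
    Y: np.ndarray, effects: tuple[str, ...] | None = None
) -> dict[str, EffectResult]:
    """Two-way within-subject ANOVA on ``(..., n, a, b)`` cell means.

    Keys: ``condition`` (axis of length a), ``trial`` (axis of length b),
    ``interaction``. dfs are ``(a-1, (a-1)(n-1))`` etc.
    """
    internal = None
    if effects is not None:
        internal = tuple(_2WAY_ALIASES[e] for e in effects)
    res = rm_anova(Y, ("condition", "trial"), internal)
    if "condition:trial" in res:
        res["interaction"] = res.pop("condition:trial")
        res["interaction"].effect = "interaction"
    return res


def rm_anova_3way(Y: np.ndarray) -> dict[str, EffectResult]:
    """Three-way within-subject ANOVA on ``(..., n, 2, 2, 5)`` cell means.

    Factor order: baseline, condition, trial.
    """
    return rm_anova(Y, ("baseline", "condition", "trial"))


def paired_t(d: np.ndarray, axis: int = -1) -> tuple[np.ndarray, int]:
    """Paired-samples t on difference scores along ``axis``; returns (t, df)."""
    d = np.asarray(d, dtype=float)
    n = d.shape[axis]
    if n < 2:
        raise ValueError("need at least 2 pairs")
    m = d.mean(axis=axis)
    sd = d.std(axis=axis, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = m / (sd / np.sqrt(n))
        t = np.where(sd > 0, t, np.where(m != 0, np.sign(m) * np.inf, 0.0))
    return t, n - 1


def mixed_anova_2w1b(
    Y: np.ndarray, groups: np.ndarray
) -> dict[str, EffectResult]:
    """Mixed ANOVA: two within factors, one between-subjects factor.

    Parameters
    ----------
    Y
        ``(n, a, b)`` cell means: subject x within-A x within-B.
    groups
        Length-``n`` group labels; groups must be balanced.

    Returns effects ``group``, ``condition``, ``sample``,
    ``group:condition``, ``group:sample``, ``condition:sample``,
    ``group:condition:sample``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 3:
        raise ValueError("Y must be (n_subjects, a, b)")
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(set(counts)) != 1:
        raise ValueError("mixed ANOVA requires balanced groups")
    g, n_per = len(labels), int(counts[0])
    n, a, b = Y.shape
    # Reshape to (group, subject-within-group, a, b)
    order = np.argsort(groups, kind="stable")
    Z = Y[order].reshape(g, n_per, a, b)

    M = Z.mean()
    m_g = Z.mean(axis=(1, 2, 3))                      # (g,)
    m_s = Z.mean(axis=(2, 3))                         # (g, n_per)
    m_a = Z.mean(axis=(0, 1, 3))                      # (a,)
    m_b = Z.mean(axis=(0, 1, 2))                      # (b,)
    m_ga = Z.mean(axis=(1, 3))                        # (g, a)
    m_gb = Z.mean(axis=(1, 2))                        # (g, b)
    m_ab = Z.mean(axis=(0, 1))                        # (a, b)
    m_gab = Z.mean(axis=1)                            # (g, a, b)
    m_sa = Z.mean(axis=3)                             # (g, n_per, a)
    m_sb = Z.mean(axis=2)                             # (g, n_per, b)

    out: dict[str, EffectResult] = {}

    ss_G = a * b * n_per * np.sum((m_g - M) ** 2)
    ss_SwG = a * b * np.sum((m_s - m_g[:, None]) ** 2)
    F, eta = _f_ratio(ss_G, g - 1, ss_SwG, g * (n_per - 1))
    out["group"] = EffectResult("group", float(F), g - 1, g * (n_per - 1), float(eta))

    ss_A = b * n * np.sum((m_a - M) ** 2)
    ss_GA = b * n_per * np.sum(
        (m_ga - m_g[:, None] - m_a[None, :] + M) ** 2
    )
    ss_AS = b * np.sum(
        (m_sa - m_s[..., None] - m_ga[:, None, :] + m_g[:, None, None]) ** 2
    )
    df_AS = g * (n_per - 1) * (a - 1)
    F, eta = _f_ratio(ss_A, a - 1, ss_AS, df_AS)
    out["condition"] = EffectResult("condition", float(F), a - 1, df_AS, float(eta))
    F, eta = _f_ratio(ss_GA, (g - 1) * (a - 1), ss_AS, df_AS)
    out["group:condition"] = EffectResult(
        "group:condition", float(F), (g - 1) * (a - 1), df_AS, float(eta)
    )

    ss_B = a * n * np.sum((m_b - M) ** 2)
    ss_GB = a * n_per * np.sum(
        (m_gb - m_g[:, None] - m_b[None, :] + M) ** 2
    )
    ss_BS = a * np.sum(
        (m_sb - m_s[..., None] - m_gb[:, None, :] + m_g[:, None, None]) ** 2
    )
    df_BS = g * (n_per - 1) * (b - 1)
    F, eta = _f_ratio(ss_B, b - 1, ss_BS, df_BS)
    out["sample"] = EffectResult("sample", float(F), b - 1, df_BS, float(eta))
    F, eta = _f_ratio(ss_GB, (g - 1) * (b - 1), ss_BS, df_BS)
    out["group:sample"] = EffectResult(
        "group:sample", float(F), (g - 1) * (b - 1), df_BS, float(eta)
    )

    ss_AB = n * np.sum(
        (m_ab - m_a[:, None] - m_b[None, :] + M) ** 2
    )
    ss_GAB = n_per * np.sum(
        (
            m_gab
            - m_ga[:, :, None]
            - m_gb[:, None, :]
            + m_g[:, None, None]
            - m_ab[None, :, :]
            + m_a[None, :, None]
            + m_b[None, None, :]
            - M
        )
        ** 2
    )
    resid = (
        Z
        - m_sa[..., None]
        - m_sb[..., None, :]
        + m_s[..., None, None]
        - m_gab[:, None, :, :]
        + m_ga[:, None, :, None]
        + m_gb[:, None, None, :]
        - m_g[:, None, None, None]
    )
    ss_ABS = np.sum(resid**2)
    df_ABS = g * (n_per - 1) * (a - 1) * (b - 1)
    F, eta = _f_ratio(ss_AB, (a - 1) * (b - 1), ss_ABS, df_ABS)
    out["condition:sample"] = EffectResult(
        "condition:sample", float(F), (a - 1) * (b - 1), df_ABS, float(eta)
    )
    F, eta = _f_ratio(ss_GAB, (g - 1) * (a - 1) * (b - 1), ss_ABS, df_ABS)
    out["group:condition:sample"] = EffectResult(
        "group:condition:sample",
        float(F),
        (g - 1) * (a - 1) * (b - 1),
        df_ABS,
        float(eta),
    )
    return out
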