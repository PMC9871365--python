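"""Independent brute-force oracles, coded from definitions with plain loops.

These deliberately avoid the package's vectorised implementations so that
agreement is meaningful.
"""

from itertools import product

import numpy as np


def brute_rm_anova_2way(Y):
    """Two-way within-subject ANOVA by explicit sums of squares.

    Y is (n, a, b). Returns dict effect -> (F, df1, df2, eta_p_sq).
    """
    n, a, b = Y.shape
    gm = Y.mean()
    m_s = Y.mean(axis=(1, 2))
    m_a = Y.mean(axis=(0, 2))
    m_b = Y.mean(axis=(0, 1))
    m_sa = Y.mean(axis=2)
    m_sb = Y.mean(axis=1)
    m_ab = Y.mean(axis=0)

    ss_a = n * b * sum((m_a[i] - gm) ** 2 for i in range(a))
    ss_as = b * sum(
        (m_sa[s, i] - m_s[s] - m_a[i] + gm) ** 2
        for s in range(n)
        for i in range(a)
    )
    ss_b = n * a * sum((m_b[j] - gm) ** 2 for j in range(b))
    ss_bs = a * sum(
        (m_sb[s, j] - m_s[s] - m_b[j] + gm) ** 2
        for s in range(n)
        for j in range(b)
    )
    ss_ab = n * sum(
        (m_ab[i, j] - m_a[i] - m_b[j] + gm) ** 2
        for i in range(a)
        for j in range(b)
    )
    ss_abs = sum(
        (
            Y[s, i, j]
            - m_sa[s, i]
            - m_sb[s, j]
            - m_ab[i, j]
            + m_s[s]
            + m_a[i]
            + m_b[j]
            - gm
        )
        ** 2
        for s in range(n)
        for i in range(a)
        for j in range(b)
    )

    def pack(ss_eff, df1, ss_err, df2):
        F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else np.inf
        eta = ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0
        return F, df1, df2, eta

    return {
        "condition": pack(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "trial": pack(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "interaction": pack(
            ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - 1)
        ),
    }


def brute_paired_t(d):
    d = np.asarray(d, float)
    n = len(d)
    return d.mean() / (d.std(ddof=1) / np.sqrt(n))


def exhaustive_signflip_p(d, two_sided=True):
    """Exact sign-flip permutation p for a paired t (strict >= count)."""
    d = np.asarray(d, float)
    t_obs = brute_paired_t(d)
    if two_sided:
        t_obs = abs(t_obs)
    count, total = 0, 0
    for signs in product((1.0, -1.0), repeat=len(d)):
        t = brute_paired_t(np.array(signs) * d)
        if two_sided:
            t = abs(t)
        if t >= t_obs:
            count += 1
        total += 1
    return count / total


def moving_average(times, values, t_grid, window_s):
    """Centered sliding-window mean oracle."""
    out = np.full(len(t_grid), np.nan)
    half = window_s / 2.0
    for i, t in enumerate(t_grid):
        sel = (times >= t - half) & (times < t + half)
        if sel.sum() >= 2:
            out[i] = np.mean(values[sel])
    return out


def even_resample_periodogram_band(times, rr_ms, band, fs_resample=4.0):
    """Band power oracle: even resampling + classic periodogram."""
    from scipy.signal import periodogram

    t_even = np.arange(times[0], times[-1], 1.0 / fs_resample)
    y = np.interp(t_even, times, rr_ms - np.mean(rr_ms))
    f, p = periodogram(y, fs=fs_resample)
    sel = (f >= band[0]) & (f <= band[1])
    return np.trapezoid(p[sel], f[sel])
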