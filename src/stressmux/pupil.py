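"""Pupil preprocessing: binocular averaging, rejection, 1-Hz reduction.

Per-sample mean of the available eyes, short blink gaps linearly
interpolated, 1-s bin means onto the trial grid (bins more than half
missing are masked), per-subject 0-1 min-max normalization across both
sessions jointly, and an optional 5-s moving average for visualization
only — never on the statistics path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContinuousMeasure, MeasurePanel
from .protocol import ProtocolDefinition, make_default_protocol

__all__ = [
    "PupilTrace",
    "preprocess_pupil",
    "missing_fraction",
    "reject_pupil_subjects",
    "normalize_01",
    "smooth_for_display",
]


@dataclass
class PupilTrace:
    """Binocular samples; NaN marks missing."""

    left: np.ndarray
    right: np.ndarray
    fs: float = 500.0

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.left.shape != self.right.shape:
            raise ValueError("eyes must have equal length")


def _interp_short_gaps(y: np.ndarray, fs: float, max_gap_s: float) -> np.ndarray:
    """Linearly bridge NaN runs no longer than ``max_gap_s``."""
    y = y.copy()
    isnan = np.isnan(y)
    if not isnan.any() or isnan.all():
        return y
    max_len = int(max_gap_s * fs)
    idx = np.arange(y.size)
    # Find NaN runs.
    edges = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start <= max_len and start > 0 and stop < y.size:
            y[start:stop] = np.interp(
                idx[start:stop], [start - 1, stop], [y[start - 1], y[stop]]
            )
    return y


def missing_fraction(trace: PupilTrace) -> float:
    """Fraction of samples where both eyes are missing."""
    return float(np.mean(np.isnan(trace.left) & np.isnan(trace.right)))


def preprocess_pupil(
    trace: PupilTrace,
    protocol: ProtocolDefinition | None = None,
    smooth: bool = False,
    max_gap_s: float = 1.0,
    max_missing_per_bin: float = 0.5,
) -> ContinuousMeasure:
    """Binocular mean reduced to 1-s bin means on the trial grid.

    Bins with more than ``max_missing_per_bin`` of their samples missing
    are masked. With ``smooth=True`` a centered 5-s moving average is
    applied (visualization only).
    """
    protocol = protocol or make_default_protocol()
    fs = trace.fs
    left = _interp_short_gaps(trace.left, fs, max_gap_s)
    right = _interp_short_gaps(trace.right, fs, max_gap_s)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        both = np.nanmean(np.stack([left, right]), axis=0)
    n_sec = protocol.n_seconds
    per_bin = int(round(fs))
    vals = np.full(n_sec, np.nan)
    mask = np.zeros(n_sec, dtype=bool)
    for t in range(n_sec):
        seg = both[t * per_bin : (t + 1) * per_bin]
        if seg.size == 0:
            continue
        frac_missing = np.mean(np.isnan(seg))
        if frac_missing <= max_missing_per_bin:
            vals[t] = np.nanmean(seg)
            mask[t] = True
    out = ContinuousMeasure("PUPIL", vals, mask, units="a.u.")
    if smooth:
        out = smooth_for_display(out)
    return out


def smooth_for_display(
    measure: ContinuousMeasure, window_s: int = 5
) -> ContinuousMeasure:
    """Centered moving average over defined points; for plots only."""
    n = len(measure)
    half = window_s // 2
    vals = np.full(n, np.nan)
    for t in range(n):
        lo, hi = max(t - half, 0), min(t + half + 1, n)
        seg = measure.values[lo:hi]
        if np.isfinite(seg).any():
            vals[t] = np.nanmean(seg)
    return ContinuousMeasure(measure.name, vals, np.isfinite(vals), measure.units)


def reject_pupil_subjects(
    trial_missing: pd.DataFrame, threshold: float = 1.0
) -> tuple[list[str], pd.DataFrame]:
    """Exclude subjects with any failed-detection trial in either condition.

    ``trial_missing`` is a tidy frame (subject, condition, trial,
    missing_frac); a subject is dropped when any trial reaches
    ``threshold`` missing fraction (default 1.0 = fully failed).

    Returns (retained subjects, per-subject report).
    """
    worst = trial_missing.groupby("subject")["missing_frac"].max()
    report = worst.reset_index().rename(columns={"missing_frac": "worst_trial_missing"})
    report["excluded"] = report["worst_trial_missing"] >= threshold
    retained = sorted(report.loc[~report["excluded"], "subject"])
    return retained, report


def normalize_01(panel: MeasurePanel) -> MeasurePanel:
    """Min-max scale each subject across all trials and conditions jointly.

    The subject's minimum maps to 0 and maximum to 1, preserving ordering
    and condition differences. Constant subjects become all 0.5 with a
    warning.
    """
    out = panel.copy()
    for s in range(out.n_subjects):
        vals = out.values[s]
        finite = np.isfinite(vals)
        if not finite.any():
            continue
        lo, hi = np.nanmin(vals), np.nanmax(vals)
        if hi - lo < 1e-12:
            warnings.warn(f"constant pupil data for subject {out.subjects[s]}")
            out.values[s] = np.where(finite, 0.5, np.nan)
        else:
            out.values[s] = (vals - lo) / (hi - lo)
    return out
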