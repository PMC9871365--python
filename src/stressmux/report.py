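"""Figures and tables: trial time courses with significance bars.

Each time-course figure shows one panel per condition with the five trial
means (ROYGB) +/- SEM, ANOVA effect bars between the panels, gated
pairwise bars at each panel's base, and out-of-scope epochs shaded. Every
drawn bar interval is also emitted as CSV so figures are auditable.
"""

from __future__ import annotations

import pathlib

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core import CONDITIONS, MeasurePanel
from .protocol import ProtocolDefinition, make_default_protocol
from .stats.framework import SignificanceTracks

__all__ = ["TRIAL_COLORS", "EFFECT_COLORS", "track_runs", "timecourse_figure",
           "summary_tables"]

TRIAL_COLORS = ("red", "orange", "gold", "green", "blue")  # T1..T5
EFFECT_COLORS = {
    "condition": "#4b0082",     # dark purple
    "trial": "#b19cd9",         # light purple
    "interaction": "#404040",   # dark gray
}
PAIRWISE_COLORS = {
    "T1vT5": ("red", "blue"),
    "T1vT3": ("red", "gold"),
    "T3vT5": ("gold", "blue"),
}


def track_runs(track: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where a boolean track is True."""
    flags = np.asarray(track, dtype=bool).view(np.int8)
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flags, [0]])))
    return [(int(a), int(b)) for a, b in zip(edges[::2], edges[1::2])]


def _bars_frame(tracks: SignificanceTracks) -> pd.DataFrame:
    rows = []
    for eff, track in tracks.anova.items():
        for a, b in track_runs(track):
            rows.append(dict(layer="anova", effect=eff, condition="", start=a, stop=b))
    for (cond, contrast), track in tracks.pairwise.items():
        for a, b in track_runs(track):
            rows.append(
                dict(layer="pairwise", effect=contrast, condition=cond,
                     start=a, stop=b)
            )
    return pd.DataFrame(rows, columns=["layer", "effect", "condition", "start", "stop"])


def timecourse_figure(
    panel: MeasurePanel,
    tracks: SignificanceTracks,
    out_path: str | pathlib.Path,
    protocol: ProtocolDefinition | None = None,
    title: str | None = None,
) -> pd.DataFrame:
    """Render the two-condition trial time-course figure.

    Writes the image to ``out_path`` plus two CSV companions
    (``*_traces.csv`` with mean/SEM series, ``*_bars.csv`` with bar
    intervals) and returns the bars frame.
    """
    protocol = protocol or make_default_protocol()
    if panel.n_time != tracks.n_time:
        raise ValueError("panel and tracks cover different grids")
    out_path = pathlib.Path(out_path)
    t = np.arange(panel.n_time)

    fig, axes = plt.subplots(
        2, 1, figsize=(10, 6), sharex=True, constrained_layout=True
    )
    trace_rows = []
    for ci, (ax, cond) in enumerate(zip(axes, CONDITIONS)):
        for k in range(panel.n_trials):
            v = panel.values[:, ci, k, :]
            mean = np.nanmean(v, axis=0)
            n_ok = np.sum(np.isfinite(v), axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                sem = np.nanstd(v, axis=0, ddof=1) / np.sqrt(np.maximum(n_ok, 1))
            ax.plot(t, mean, color=TRIAL_COLORS[k], lw=1.0, label=f"T{k + 1}")
            ax.fill_between(
                t, mean - sem, mean + sem, color=TRIAL_COLORS[k], alpha=0.15, lw=0
            )
            trace_rows.append(
                pd.DataFrame(
                    dict(condition=cond, trial=k + 1, t=t, mean=mean, sem=sem)
                )
            )
        # Shade out-of-scope epochs.
        if tracks.in_scope is not None:
            for a, b in track_runs(~tracks.in_scope):
                ax.axvspan(a, b, color="0.85", zorder=0)
        # Pairwise bars at the panel base.
        y0, y1 = ax.get_ylim()
        dy = (y1 - y0) * 0.04
        for li, (contrast, colors) in enumerate(PAIRWISE_COLORS.items()):
            track = tracks.pairwise.get((cond, contrast))
            if track is None:
                continue
            y = y0 + li * dy
            for a, b in track_runs(track):
                ax.hlines(y, a, b, color=colors[0], lw=3)
                ax.hlines(y - dy * 0.35, a, b, color=colors[1], lw=3)
        ax.set_ylabel(f"{panel.measure} ({cond})")
        if ci == 0:
            ax.legend(ncols=5, fontsize=8, loc="upper right")
    # ANOVA bars in a thin strip on the lower axes' top edge.
    ax = axes[1]
    y0, y1 = ax.get_ylim()
    dy = (y1 - y0) * 0.04
    for li, (eff, color) in enumerate(EFFECT_COLORS.items()):
        track = tracks.anova.get(eff)
        if track is None:
            continue
        for a, b in track_runs(track):
            ax.hlines(y1 - (li + 1) * dy, a, b, color=color, lw=3)
    axes[1].set_xlabel("time (s)")
    if title:
        fig.suptitle(title)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)

    traces = pd.concat(trace_rows, ignore_index=True)
    traces.to_csv(out_path.with_name(out_path.stem + "_traces.csv"), index=False)
    bars = _bars_frame(tracks)
    bars.to_csv(out_path.with_name(out_path.stem + "_bars.csv"), index=False)
    return bars


def summary_tables(
    panels: dict[str, MeasurePanel],
    protocol: ProtocolDefinition | None = None,
    window_s: float = 15.0,
) -> pd.DataFrame:
    """Resting-baseline table: mean (SD) per measure.

    Values come from each subject's mean over the final ``window_s``
    seconds of the baseline epoch in trial 1 of the control condition.
    """
    protocol = protocol or make_default_protocol()
    b0, b1 = protocol.epoch_interval("baseline")
    lo, hi = int(round(b1 - window_s)), int(round(b1))
    ci = CONDITIONS.index("control")
    rows = []
    for name, panel in panels.items():
        per_subject = np.nanmean(panel.values[:, ci, 0, lo:hi], axis=-1)
        rows.append(
            dict(
                measure=name,
                mean=float(np.nanmean(per_subject)),
                sd=float(np.nanstd(per_subject, ddof=1)) if len(per_subject) > 1 else 0.0,
                n=int(np.sum(np.isfinite(per_subject))),
                units=panel.units,
            )
        )
    return pd.DataFrame(rows)
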