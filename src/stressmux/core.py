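"""Shared containers: 1-Hz continuous measures and subject panels."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONDITIONS = ("treatment", "control")
N_TRIALS = 5


@dataclass
class ContinuousMeasure:
    """One measure on the 1-Hz trial grid with a validity mask.

    ``values`` has one sample per integer second of the protocol; ``mask``
    is True where the value is defined.
    """

    name: str
    values: np.ndarray
    mask: np.ndarray
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        self.values = np.where(self.mask, self.values, np.nan)

    def __len__(self) -> int:
        return self.values.size


@dataclass
class MeasurePanel:
    """Values indexed subject x condition(2) x trial(5) x time.

    ``values[s, c, k, t]`` holds subject ``subjects[s]`` in condition
    ``CONDITIONS[c]``, trial ``k+1``, second ``t``. NaN marks masked cells;
    ``mask`` mirrors validity.
    """

    measure: str
    values: np.ndarray
    mask: np.ndarray | None = None
    subjects: list[str] = field(default_factory=list)
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4 or self.values.shape[1] != 2:
            raise ValueError("values must be (n_subjects, 2, n_trials, n_time)")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.subjects:
            self.subjects = [f"s{i:03d}" for i in range(self.values.shape[0])]
        self.values = np.where(self.mask, self.values, np.nan)

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[2]

    @property
    def n_time(self) -> int:
        return self.values.shape[3]

    def copy(self) -> "MeasurePanel":
        return MeasurePanel(
            measure=self.measure,
            values=self.values.copy(),
            mask=self.mask.copy(),
            subjects=list(self.subjects),
            units=self.units,
        )

    def to_tidy(self) -> pd.DataFrame:
        """Long-format frame: subject, condition, trial, measure, t, value, mask."""
        n_s, n_c, n_k, n_t = self.values.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, CONDITIONS[:n_c], range(1, n_k + 1), range(n_t)],
            names=["subject", "condition", "trial", "t"],
        )
        df = pd.DataFrame(
            {"value": self.values.ravel(), "mask": self.mask.ravel()}, index=idx
        ).reset_index()
        df.insert(3, "measure", self.measure)
        return df

    @classmethod
    def from_tidy(cls, df: pd.DataFrame, measure: str | None = None) -> "MeasurePanel":
        if measure is None:
            measures = df["measure"].unique()
            if len(measures) != 1:
                raise ValueError("frame holds multiple measures; pass measure=")
            measure = measures[0]
        df = df[df["measure"] == measure]
        subjects = sorted(df["subject"].unique())
        trials = sorted(df["trial"].unique())
        n_t = int(df["t"].max()) + 1
        values = np.full((len(subjects), 2, len(trials), n_t), np.nan)
        s_idx = {s: i for i, s in enumerate(subjects)}
        c_idx = {c: i for i, c in enumerate(CONDITIONS)}
        k_idx = {k: i for i, k in enumerate(trials)}
        si = df["subject"].map(s_idx).to_numpy()
        ci = df["condition"].map(c_idx).to_numpy()
        ki = df["trial"].map(k_idx).to_numpy()
        ti = df["t"].to_numpy(dtype=int)
        vals = df["value"].to_numpy(dtype=float)
        if "mask" in df:
            vals = np.where(df["mask"].to_numpy(dtype=bool), vals, np.nan)
        values[si, ci, ki, ti] = vals
        return cls(measure=measure, values=values, subjects=subjects)
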