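"""File formats and the in-memory series container.

All files are plain CSV.  Time series use the header
``time_min,permittivity_pF_cm`` with one row per sample on a strict uniform
grid (60 s period by default).  Annotations use ``start_min,end_min,label``;
anomaly matrices use ``start_min,end_min``.  Floats are written with a fixed
``%.6g`` format so repeated runs produce byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InputError

SERIES_VALUE_COLUMN = "permittivity_pF_cm"
FLOAT_FORMAT = "%.6g"


@dataclass(frozen=True)
class PermittivitySeries:
    """Uniformly sampled univariate permittivity signal (pF/cm vs minutes)."""

    values: np.ndarray
    sample_period_s: float = 60.0
    t0_min: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise InputError("a series must be one-dimensional")
        object.__setattr__(self, "values", v)
        if not self.sample_period_s > 0:
            raise InputError("sample_period_s must be > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def period_min(self) -> float:
        return self.sample_period_s / 60.0

    @property
    def time_min(self) -> np.ndarray:
        return self.t0_min + np.arange(len(self)) * self.period_min

    def replace_values(self, values) -> "PermittivitySeries":
        return replace(self, values=np.asarray(values, dtype=float))

    # -- CSV ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, gap_fill: bool = False) -> "PermittivitySeries":
        """Read a two-column series CSV, enforcing a uniform time grid.

        Missing rows on the grid are an error unless ``gap_fill`` is set, in
        which case the previous value is held.
        """
        df = pd.read_csv(path)
        for col in ("time_min", SERIES_VALUE_COLUMN):
            if col not in df.columns:
                raise InputError(f"series CSV {path} lacks column {col!r}")
        t = df["time_min"].to_numpy(dtype=float)
        y = df[SERIES_VALUE_COLUMN].to_numpy(dtype=float)
        if t.size < 2:
            return cls(values=y, t0_min=float(t[0]) if t.size else 0.0)
        steps = np.diff(t)
        period = float(np.min(steps))
        if period <= 0:
            raise InputError("time_min must be strictly increasing")
        on_grid = np.allclose(steps / period, np.round(steps / period),
                              rtol=0, atol=1e-6)
        uniform = np.allclose(steps, period, rtol=0, atol=1e-6 * period)
        if not uniform:
            if not (gap_fill and on_grid):
                raise InputError(
                    f"series {path} is not uniformly sampled "
                    "(pass gap_fill=True to hold the last value over gaps)")
            n = int(round((t[-1] - t[0]) / period)) + 1
            full = np.full(n, np.nan)
            idx = np.round((t - t[0]) / period).astype(int)
            full[idx] = y
            y = pd.Series(full).ffill().to_numpy()
        return cls(values=y, sample_period_s=period * 60.0, t0_min=float(t[0]))

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "time_min": self.time_min,
            SERIES_VALUE_COLUMN: self.values,
        }).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_annotations_csv(path, intervals, period_min: float = 1.0) -> None:
    """Write (start_index, end_index, label) intervals as minutes."""
    rows = [(s * period_min, e * period_min, lab) for s, e, lab in intervals]
    pd.DataFrame(rows, columns=["start_min", "end_min", "label"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def read_annotations_csv(path, period_min: float = 1.0):
    """Read an annotation CSV back into (start_index, end_index, label)."""
    df = pd.read_csv(path)
    for col in ("start_min", "end_min"):
        if col not in df.columns:
            raise InputError(f"annotation CSV {path} lacks column {col!r}")
    labels = df["label"] if "label" in df.columns else ["any"] * len(df)
    out = []
    for s, e, lab in zip(df["start_min"], df["end_min"], labels):
        out.append((int(round(s / period_min)), int(round(e / period_min)),
                    str(lab)))
    return out


def write_matrix_csv(path, matrix, period_min: float = 1.0) -> None:
    """Write an anomaly matrix as start/end minutes."""
    rows = [(s * period_min, e * period_min) for s, e in matrix]
    pd.DataFrame(rows, columns=["start_min", "end_min"]).to_csv(
        path, index=False, float_format=FLOAT_FORMAT)


def write_run_csv(path, frame: pd.DataFrame) -> None:
    """Write the per-sample pipeline output with fixed float formatting."""
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)
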