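"""Evaluation machinery: NRMSE, point-wise confusion metrics, delay
estimation by cross-correlation, and parameter grid search.

Detection quality is scored per *sample* (not per event): every annotated
anomalous sample that is flagged counts as a true positive, every flagged
clean sample as a false positive, every missed anomalous sample as a false
negative.  Smoothing quality is scored as the root-mean-square error against
a noiseless reference, normalized by the reference range and expressed in
percent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .correction import run_pipeline
from .errors import InputError, ParameterError

ANNOTATION_LABELS = ("spike", "shift", "any")


@dataclass(frozen=True)
class AnnotationSet:
    """Ground-truth anomaly intervals as (start, end, label) sample indices
    (both ends inclusive)."""

    intervals: tuple = ()

    def __post_init__(self) -> None:
        ivs = []
        for start, end, label in self.intervals:
            if end < start:
                raise InputError(f"annotation end {end} precedes start {start}")
            if label not in ANNOTATION_LABELS:
                raise InputError(f"unknown annotation label {label!r}")
            ivs.append((int(start), int(end), str(label)))
        object.__setattr__(self, "intervals", tuple(ivs))

    def __len__(self) -> int:
        return len(self.intervals)

    def mask(self, n: int) -> np.ndarray:
        """Per-sample boolean mask of length *n*."""
        out = np.zeros(n, dtype=bool)
        for start, end, _ in self.intervals:
            if start < 0 or end >= n:
                raise InputError(
                    f"annotation ({start}, {end}) outside series of length {n}")
            out[start : end + 1] = True
        return out


@dataclass
class EvaluationReport:
    """Point-wise detection counts and derived quality metrics."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    nrmse: float | None = None
    delay: float | None = None


def nrmse(reference, candidate) -> float:
    """Root-mean-square error normalized by the reference range, in percent.

    ``100 × sqrt(mean((y − y*)²)) / (y_max − y_min)`` with y the reference.
    """
    y = np.asarray(reference, dtype=float)
    ystar = np.asarray(candidate, dtype=float)
    if y.shape != ystar.shape or y.ndim != 1 or y.size < 2:
        raise InputError("nrmse needs two equal-length series of length >= 2")
    span = float(y.max() - y.min())
    if span <= 0:
        raise InputError("nrmse is undefined for a constant reference")
    rmse = float(np.sqrt(np.mean((y - ystar) ** 2)))
    return 100.0 * rmse / span


def confusion(detected_mask, annotated_mask) -> EvaluationReport:
    """Point-wise TP/FP/FN counts and precision/recall/F1 (0/0 → 0)."""
    det = np.asarray(detected_mask, dtype=bool)
    ann = np.asarray(annotated_mask, dtype=bool)
    if det.shape != ann.shape:
        raise InputError("detection and annotation masks differ in length")
    tp = int(np.sum(det & ann))
    fp = int(np.sum(det & ~ann))
    fn = int(np.sum(~det & ann))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return EvaluationReport(tp=tp, fp=fp, fn=fn, precision=precision,
                            recall=recall, f1=f1)


def estimate_delay(x, y, max_lag: int) -> int:
    """Lag (in samples) at which *y* best correlates with *x*.

    Positive result: *y* lags *x* by that many samples.  Signals are
    mean-removed and the correlation is evaluated over the overlapping
    support at each lag; ties break toward the smallest ``|lag|``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise InputError("estimate_delay needs two equal-length 1-D series")
    n = xa.size
    if not 0 <= max_lag < n - 1:
        raise ParameterError(f"max_lag must lie in [0, {n - 2}]")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise InputError("correlation undefined for zero-variance input")

    best_lag, best_corr = 0, -np.inf
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        if lag >= 0:
            xs, ys = xa[: n - lag], ya[lag:]
        else:
            xs, ys = xa[-lag:], ya[: n + lag]
        xs = xs - xs.mean()
        ys = ys - ys.mean()
        denom = np.sqrt(np.sum(xs**2) * np.sum(ys**2))
        if denom == 0:
            continue
        corr = float(np.sum(xs * ys) / denom)
        if corr > best_corr:  # visiting order already prefers small |lag|
            best_corr, best_lag = corr, lag
    return best_lag


# ---------------------------------------------------------------------------
# Grid search

def _apply_params(config: PipelineConfig, params: dict) -> PipelineConfig:
    """Return *config* with dotted-path parameters replaced
    (e.g. ``{"threshold.static_value": 1.06, "dra.w2": 15}``)."""
    groups: dict[str, dict] = {}
    top: dict = {}
    for key, value in params.items():
        if "." in key:
            section, name = key.split(".", 1)
            groups.setdefault(section, {})[name] = value
        else:
            top[key] = value
    kwargs = dict(top)
    for section, fields in groups.items():
        if section not in ("smoother", "dra", "threshold"):
            raise ParameterError(f"unknown config section {section!r}")
        kwargs[section] = replace(getattr(config, section), **fields)
    return replace(config, **kwargs)


def grid_search(datasets, grid: dict, config_base: PipelineConfig | None = None,
                ) -> pd.DataFrame:
    """Sweep pipeline parameters, scoring each grid point by mean F1.

    Parameters
    ----------
    datasets:
        List of ``(series, annotations)`` pairs; *annotations* is an
        :class:`AnnotationSet` (may be empty).  Datasets without annotated
        anomalies are excluded from the F1 average but their false positives
        are reported in a diagnostic column.
    grid:
        Mapping from dotted config paths (``"threshold.static_value"``,
        ``"dra.w2"``, ...) to iterables of values.
    config_base:
        Configuration supplying every parameter not in the grid.

    Returns a DataFrame with one row per grid point, sorted by mean F1
    descending (ties: smaller ``dra.w2``, then smaller static threshold).
    """
    if not datasets or not grid:
        raise ParameterError("grid_search needs nonempty datasets and grid")
    config_base = config_base or PipelineConfig()
    prepared = []
    any_annotated = False
    for series, ann in datasets:
        values = np.asarray(getattr(series, "values", series), dtype=float)
        mask = ann.mask(values.size)
        annotated = bool(mask.any())
        any_annotated = any_annotated or annotated
        prepared.append((series, mask, annotated))
    if not any_annotated:
        raise ParameterError("no dataset has annotated anomalies; F1 undefined")

    names = list(grid)
    rows = []
    for combo in itertools.product(*(list(grid[name]) for name in names)):
        params = dict(zip(names, combo))
        config = _apply_params(config_base, params)
        f1s, precisions, recalls = [], [], []
        fp_unannotated = 0
        for series, mask, annotated in prepared:
            frame, _, _ = run_pipeline(series, config)
            rep = confusion(frame["anomaly_flag"].to_numpy(), mask)
            if annotated:
                f1s.append(rep.f1)
                precisions.append(rep.precision)
                recalls.append(rep.recall)
            else:
                fp_unannotated += rep.fp
        row = dict(params)
        row["mean_precision"] = float(np.mean(precisions))
        row["mean_recall"] = float(np.mean(recalls))
        row["mean_f1"] = float(np.mean(f1s))
        row["fp_unannotated"] = fp_unannotated
        rows.append(row)

    table = pd.DataFrame(rows)

    def _tiebreak(column, default=0.0):
        return table[column] if column in table.columns else default

    order = pd.DataFrame({
        "neg_f1": -table["mean_f1"],
        "w2": _tiebreak("dra.w2"),
        "thr": _tiebreak("threshold.static_value"),
    }).sort_values(["neg_f1", "w2", "thr"], kind="mergesort").index
    return table.loc[order].reset_index(drop=True)
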