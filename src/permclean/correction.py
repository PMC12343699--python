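"""Streaming anomaly logging, value replacement and shift compensation.

This module implements the per-minute correction loop.  Each incoming raw
sample passes through, in order:

1. causal smoothing over the raw history;
2. subtraction of the cumulative correction factor ``fc_total`` — giving the
   *candidate* corrected value;
3. the DRA transform over the candidate history (Perm_d);
4. threshold detection on Perm_d;
5. bookkeeping:

   * **flagged** — the sample joins the open anomaly; the emitted corrected
     value is the mean of the last 15 corrected values (replacement), so a
     downstream feed-rate controller never sees the excursion;
   * **first clean sample after an anomaly** — the interval is registered in
     the anomaly matrix and a validation countdown of ``validation_len``
     samples starts, during which replacement values continue to be emitted
     while the incoming candidate level is observed;
   * **new anomaly during validation** — the intervals merge (the matrix row
     extends, the countdown restarts), guaranteeing at least
     ``validation_len`` clean samples after the last flank.  Spikes (up-flank
     then down-flank) therefore collapse into a single registered anomaly;
   * **countdown reaches zero** — the correction factor
     ``Fc = mean(candidate over validation) − mean(corrected before onset)``
     is folded into ``fc_total`` and pass-through resumes.  For a spike the
     signal returns to its old level and Fc ≈ 0; for a persistent shift Fc
     recovers the step height and all subsequent samples are compensated.

Non-finite raw samples (sensor dropout) are treated as anomalous and logged
distinctly.  When Fc is folded in, the stored DRA history is re-based by
−Fc so the compensation step itself is invisible to the detector.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .detection import dynamic_decide, static_decide
from .dra import dra_value
from .errors import StateError
from .smoothing import smooth_causal

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StepRecord:
    """Everything the loop knows about one processed sample."""

    index: int
    raw: float
    smoothed: float
    corrected: float
    perm_d: float
    anomaly_flag: bool
    fc_total: float
    dropout: bool = False


@dataclass
class AnomalyMatrix:
    """Registered anomalies as chronologically ordered (start, end) sample
    index intervals (both inclusive)."""

    rows: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def mask(self, n: int) -> np.ndarray:
        """Per-sample boolean mask of length *n*."""
        out = np.zeros(n, dtype=bool)
        for start, end in self.rows:
            out[start : end + 1] = True
        return out


def replacement_value(history, n: int = 15) -> float:
    """Mean of the ``min(n, available)`` most recent corrected values."""
    x = np.asarray(history, dtype=float)
    if x.size == 0:
        raise StateError("cannot compute a replacement value from empty history")
    return float(x[-n:].mean())


def compute_fc(pre_mean: float, post_mean: float) -> float:
    """Correction factor: post-anomaly level minus pre-anomaly level."""
    return post_mean - pre_mean


class Detector:
    """Stateful implementation of the streaming correction loop.

    Feed samples one at a time through :meth:`step`; finish with
    :meth:`close_run`, which returns the :class:`AnomalyMatrix`.
    """

    def __init__(self, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        cfg = self.config
        self._raw_buf: deque[float] = deque(maxlen=cfg.smoother.w)
        self._dra_buf: deque[float] = deque(maxlen=cfg.dra.min_buffer)
        self._band_buf: deque[float] = (
            deque(maxlen=cfg.threshold.w3)
            if cfg.threshold.kind != "static"
            else deque(maxlen=1)
        )
        hist_len = max(cfg.replacement_window, cfg.validation_len)
        self._corr_hist: deque[float] = deque(maxlen=hist_len)

        self.n_seen = 0
        self.fc_total = 0.0
        self.in_anomaly = False
        self.validation_countdown = 0
        self.pre_anomaly_mean: float | None = None
        self.open_start: int | None = None
        self.open_end: int | None = None
        self._post_vals: list[float] = []
        self._row_pending = False  # last matrix row still amendable (merging)
        self.matrix = AnomalyMatrix()
        self.fc_events: list[float] = []  # one entry per registered anomaly

        w3 = cfg.threshold.w3 if cfg.threshold.kind != "static" else 0
        #: samples with no detection until every configured window has filled
        self.warmup = max(cfg.smoother.w, cfg.dra.min_buffer, w3 or 0,
                          cfg.replacement_window)

    # -- helpers -----------------------------------------------------------

    def _decide(self, perm_d: float) -> bool:
        thr = self.config.threshold
        if thr.kind == "static":
            return static_decide(perm_d, thr)
        return dynamic_decide(perm_d, np.asarray(self._band_buf), thr)

    def _register_or_extend(self) -> None:
        assert self.open_start is not None and self.open_end is not None
        if self._row_pending and self.matrix.rows:
            self.matrix.rows[-1] = (self.matrix.rows[-1][0], self.open_end)
        else:
            self.matrix.rows.append((self.open_start, self.open_end))
            self._row_pending = True

    def _fold_fc(self, truncated: bool = False) -> None:
        post = self._post_vals
        if post:
            fc = compute_fc(self.pre_anomaly_mean, float(np.mean(post)))
        else:
            fc = 0.0
        if truncated:
            logger.warning(
                "run ended during validation: Fc=%.4g estimated from %d of %d "
                "post-anomaly samples", fc, len(post), self.config.validation_len,
            )
        self.fc_total += fc
        self.fc_events.append(fc)
        # re-base the DRA history so the fold is not itself seen as a step
        self._dra_buf = deque((v - fc for v in self._dra_buf),
                              maxlen=self._dra_buf.maxlen)
        start, end = self.matrix.rows[-1]
        logger.info("anomaly %d-%d validated: Fc=%.4g, cumulative Fc=%.4g",
                    start, end, fc, self.fc_total)
        self._post_vals = []
        self.pre_anomaly_mean = None
        self.open_start = None
        self.open_end = None
        self._row_pending = False

    # -- the per-sample loop ----------------------------------------------

    def step(self, raw: float) -> StepRecord:
        cfg = self.config
        idx = self.n_seen
        raw = float(raw)
        dropout = not np.isfinite(raw)
        if dropout:
            # hold the smoother's input at its last value; log distinctly
            held = self._raw_buf[-1] if self._raw_buf else 0.0
            logger.warning("non-finite raw sample at index %d treated as "
                           "sensor dropout", idx)
            self._raw_buf.append(held)
        else:
            self._raw_buf.append(raw)

        smoothed = smooth_causal(np.asarray(self._raw_buf), cfg.smoother)
        candidate = smoothed - self.fc_total
        self._dra_buf.append(candidate)
        perm_d = dra_value(np.asarray(self._dra_buf), cfg.dra)

        if idx < self.warmup:
            flag = False
        elif dropout:
            flag = True
        else:
            flag = self._decide(perm_d)

        if flag:
            if self.in_anomaly:
                self.open_end = idx
            elif self.validation_countdown > 0:
                # merge: reopen the pending interval, restart validation later
                self.in_anomaly = True
                self.validation_countdown = 0
                self._post_vals = []
                self.open_end = idx
            else:
                self.in_anomaly = True
                self.open_start = idx
                self.open_end = idx
                self.pre_anomaly_mean = replacement_value(
                    np.asarray(self._corr_hist), cfg.validation_len)
            corrected = (replacement_value(np.asarray(self._corr_hist),
                                           cfg.replacement_window)
                         if self._corr_hist else candidate)
        else:
            if self.in_anomaly:
                # anomaly has passed: register it, start validating
                self.in_anomaly = False
                self.validation_countdown = cfg.validation_len
                self._register_or_extend()
            if self.validation_countdown > 0:
                self._post_vals.append(candidate)
                self.validation_countdown -= 1
                corrected = replacement_value(np.asarray(self._corr_hist),
                                              cfg.replacement_window)
                if self.validation_countdown == 0:
                    self._fold_fc()
            else:
                corrected = candidate

        # band windows receive only unflagged Perm_d values, so an anomaly
        # cannot inflate the very band that should catch it
        if not flag:
            self._band_buf.append(perm_d)

        self._corr_hist.append(corrected)
        self.n_seen += 1
        return StepRecord(index=idx, raw=raw, smoothed=smoothed,
                          corrected=corrected, perm_d=perm_d,
                          anomaly_flag=flag, fc_total=self.fc_total,
                          dropout=dropout)

    def close_run(self) -> AnomalyMatrix:
        """Finalize the stream: close any open anomaly / pending validation."""
        if self.in_anomaly:
            logger.warning("run ended inside an anomaly; closing at index %d",
                           self.n_seen - 1)
            self.in_anomaly = False
            self._register_or_extend()
            self._fold_fc(truncated=True)
        elif self.validation_countdown > 0:
            self.validation_countdown = 0
            self._fold_fc(truncated=True)
        return self.matrix


def run_pipeline(series, config: PipelineConfig | None = None):
    """Replay a full series sample-by-sample through a :class:`Detector`.

    *series* may be a plain array or a :class:`~permclean.io.PermittivitySeries`.
    Returns ``(frame, matrix, detector)`` where *frame* is a pandas DataFrame
    with columns ``time_min, raw, smoothed, corrected, perm_d, anomaly_flag,
    fc_total``.
    """
    import pandas as pd

    config = config or PipelineConfig()
    values = np.asarray(getattr(series, "values", series), dtype=float)
    period_min = getattr(series, "period_min", config.period_min)
    t0 = getattr(series, "t0_min", 0.0)

    det = Detector(config)
    records = [det.step(v) for v in values]
    matrix = det.close_run()
    frame = pd.DataFrame({
        "time_min": t0 + np.arange(values.size) * period_min,
        "raw": [r.raw for r in records],
        "smoothed": [r.smoothed for r in records],
        "corrected": [r.corrected for r in records],
        "perm_d": [r.perm_d for r in records],
        "anomaly_flag": [r.anomaly_flag for r in records],
        "fc_total": [r.fc_total for r in records],
    })
    logger.info("run complete: %d samples, %d anomalies, cumulative Fc=%.4g",
                values.size, len(matrix), det.fc_total)
    return frame, matrix, det
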