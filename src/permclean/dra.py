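"""Double rolling aggregate (DRA) transform.

Bioprocess signals are non-stationary: the mean rises with biomass.  The DRA
transform removes that context by sliding two co-moving windows along the
series, aggregating each (mean), and emitting the difference

    Perm_d = agg(short window) - agg(long window)

In the default *overlapping* mode both windows end at the current sample; in
*adjacent* mode the second window immediately precedes the first.  A sudden
upward jump enters the short window first, so Perm_d swings positive (and
negative on a drop), while slow trends and constant offsets cancel: the
transform is invariant under adding a constant and linear in the signal.

Warm-up samples (buffer shorter than the longest window) emit the neutral
value 0 so that nothing can be flagged before the windows fill.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

DRA_MODES = ("overlapping", "adjacent")
DRA_AGGREGATES = ("mean",)


@dataclass(frozen=True)
class DraSpec:
    """Window configuration of the double rolling aggregate transform."""

    w1: int = 1
    w2: int = 15
    mode: str = "overlapping"
    aggregate: str = "mean"

    def __post_init__(self) -> None:
        if int(self.w1) < 1 or int(self.w2) < 1:
            raise ParameterError(f"w1 and w2 must be >= 1 (got {self.w1}, {self.w2})")
        if self.mode not in DRA_MODES:
            raise ParameterError(f"unknown DRA mode {self.mode!r}")
        if self.aggregate not in DRA_AGGREGATES:
            raise ParameterError(f"unsupported aggregate {self.aggregate!r}")

    @property
    def min_buffer(self) -> int:
        """Samples required before the transform leaves warm-up."""
        if self.mode == "overlapping":
            return max(self.w1, self.w2)
        return self.w1 + self.w2


def dra_value(buffer, spec: DraSpec) -> float:
    """Transformed value for the newest sample of *buffer* (oldest→newest).

    Returns 0.0 while the buffer is still in warm-up.
    """
    x = np.asarray(buffer, dtype=float)
    if x.size < spec.min_buffer:
        return 0.0
    a1 = float(x[-spec.w1 :].mean())
    if spec.mode == "overlapping":
        a2 = float(x[-spec.w2 :].mean())
    else:
        a2 = float(x[-(spec.w1 + spec.w2) : -spec.w1].mean())
    return a1 - a2


def dra_series(values, spec: DraSpec) -> np.ndarray:
    """Element-wise DRA over a sliding causal buffer (same length as input).

    Each output sample is computed exactly as :func:`dra_value` would compute
    it on the growing buffer, so streaming and batch results agree bit for
    bit.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    out = np.zeros(n)
    start = spec.min_buffer - 1
    if spec.mode == "overlapping":
        for t in range(start, n):
            a1 = float(x[t + 1 - spec.w1 : t + 1].mean())
            a2 = float(x[t + 1 - spec.w2 : t + 1].mean())
            out[t] = a1 - a2
    else:
        for t in range(start, n):
            a1 = float(x[t + 1 - spec.w1 : t + 1].mean())
            a2 = float(x[t + 1 - spec.w1 - spec.w2 : t + 1 - spec.w1].mean())
            out[t] = a1 - a2
    return out
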