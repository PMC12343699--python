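"""Threshold-based anomaly detection on the DRA-transformed signal.

A sample is flagged when its transformed value Perm_d falls strictly outside a
threshold band

    band = location estimator ± threshold factor × scale estimator

Four band kinds are supported:

``static``
    A fixed, manually chosen cut-off (default 1.06 pF/cm); two-sided by
    default so both the up- and the down-flank of a spike are caught.
``three_sigma``
    mean ± 3 × sample standard deviation over a rolling window of the last
    ``w3`` transformed values.
``hampel``
    median ± 3 × b × MAD with the normal-consistency constant b = 1.4826 —
    the Hampel identifier, robust against masking by the outlier itself.
``iqr``
    median ± 2 × (Q3 − Q1); for normal data this corresponds to roughly
    ±2.7 σ since IQR/1.35 is an unbiased estimate of σ.

Dynamic bands are computed from the ``w3`` values strictly *before* the
current sample, so a jump cannot inflate its own band.  A window of constant
values collapses the band to a point; the strict inequality then flags only
genuinely non-zero deviations.  Note that within a window of size ``w``, no
point can ever exceed ``(w - 1)/sqrt(w)`` standard deviations from the mean
(:func:`max_threshold_factor`), so a 3-sigma rule needs windows larger than
10 samples to be able to fire at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ParameterError

THRESHOLD_KINDS = ("static", "three_sigma", "hampel", "iqr")

#: MAD → σ consistency constant for the normal distribution, 1/Φ⁻¹(3/4)
DEFAULT_B = 1.4826


@dataclass(frozen=True)
class ThresholdBand:
    """Lower/upper detection limits around a location estimate (pF/cm)."""

    center: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.center <= self.upper):
            raise ParameterError(
                f"band must satisfy lower <= center <= upper, got "
                f"({self.lower}, {self.center}, {self.upper})"
            )

    def outside(self, value: float, two_sided: bool = True) -> bool:
        """Strictly outside the band (upper side only if one-sided)."""
        if two_sided and value < self.lower:
            return True
        return value > self.upper


@dataclass(frozen=True)
class ThresholdSpec:
    """Detection configuration.

    ``threshold_factor`` of ``None`` resolves to the conventional default for
    the kind: 3 for ``three_sigma`` and ``hampel``, 2 for ``iqr``.
    ``min_scale`` imposes a floor on the scale estimate so a dead-flat window
    does not collapse the band entirely.
    """

    kind: str = "static"
    static_value: float = 1.06
    threshold_factor: float | None = None
    b_constant: float = DEFAULT_B
    w3: int | None = None
    two_sided: bool = True
    min_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in THRESHOLD_KINDS:
            raise ParameterError(f"unknown threshold kind {self.kind!r}")
        if self.kind == "static":
            if not self.static_value > 0:
                raise ParameterError("static_value must be > 0")
        else:
            min_w3 = 4 if self.kind == "iqr" else 2
            if self.w3 is None or int(self.w3) < min_w3:
                raise ParameterError(
                    f"{self.kind} threshold needs w3 >= {min_w3}, got {self.w3}"
                )
        if self.threshold_factor is not None and not self.threshold_factor > 0:
            raise ParameterError("threshold_factor must be > 0")
        if self.min_scale < 0:
            raise ParameterError("min_scale must be >= 0")

    @property
    def factor(self) -> float:
        if self.threshold_factor is not None:
            return float(self.threshold_factor)
        return 2.0 if self.kind == "iqr" else 3.0


def static_decide(perm_d: float, spec: ThresholdSpec) -> bool:
    """Flag a transformed value against the fixed threshold."""
    if spec.kind != "static":
        raise ParameterError("static_decide requires a static ThresholdSpec")
    if spec.two_sided:
        return abs(perm_d) > spec.static_value
    return perm_d > spec.static_value


def _band(center: float, scale: float, factor: float, min_scale: float) -> ThresholdBand:
    scale = max(scale, min_scale)
    return ThresholdBand(center=center, lower=center - factor * scale,
                         upper=center + factor * scale)


def band_three_sigma(window, factor: float = 3.0,
                     min_scale: float = 0.0) -> ThresholdBand:
    """mean ± factor × sample standard deviation (n−1 denominator)."""
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ParameterError("three-sigma band needs a window of >= 2 values")
    return _band(float(x.mean()), float(x.std(ddof=1)), factor, min_scale)


def band_hampel(window, factor: float = 3.0, b: float = DEFAULT_B,
                min_scale: float = 0.0) -> ThresholdBand:
    """median ± factor × b × MAD (the Hampel identifier)."""
    x = np.asarray(window, dtype=float)
    if x.size < 2:
        raise ParameterError("Hampel band needs a window of >= 2 values")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return _band(med, b * mad, factor, min_scale)


def band_iqr(window, factor: float = 2.0, min_scale: float = 0.0) -> ThresholdBand:
    """median ± factor × (Q3 − Q1), linear-interpolation quantiles."""
    x = np.asarray(window, dtype=float)
    if x.size < 4:
        raise ParameterError("IQR band needs a window of >= 4 values")
    q1, q3 = np.quantile(x, [0.25, 0.75])
    return _band(float(np.median(x)), float(q3 - q1), factor, min_scale)


def band_for(window, spec: ThresholdSpec) -> ThresholdBand:
    """Dispatch to the band constructor named by ``spec.kind``."""
    if spec.kind == "three_sigma":
        return band_three_sigma(window, spec.factor, spec.min_scale)
    if spec.kind == "hampel":
        return band_hampel(window, spec.factor, spec.b_constant, spec.min_scale)
    if spec.kind == "iqr":
        return band_iqr(window, spec.factor, spec.min_scale)
    raise ParameterError(f"no rolling band for threshold kind {spec.kind!r}")


def dynamic_decide(perm_d: float, window, spec: ThresholdSpec) -> bool:
    """Flag *perm_d* against the band of the previous ``w3`` values.

    *window* must exclude the current sample.  Fewer than ``w3`` past values
    means warm-up: nothing is flagged.
    """
    x = np.asarray(window, dtype=float)
    if spec.w3 is None or x.size < spec.w3:
        return False
    return band_for(x[-spec.w3 :], spec).outside(perm_d, spec.two_sided)


def decide_series(perm_d_values, spec: ThresholdSpec) -> np.ndarray:
    """Batch detection over a full transformed series (boolean mask)."""
    pd_ = np.asarray(perm_d_values, dtype=float)
    if spec.kind == "static":
        if spec.two_sided:
            return np.abs(pd_) > spec.static_value
        return pd_ > spec.static_value
    flags = np.zeros(pd_.size, dtype=bool)
    for t in range(pd_.size):
        flags[t] = dynamic_decide(pd_[t], pd_[:t], spec)
    return flags


def max_threshold_factor(w: int) -> float:
    """Largest z-score any point can attain within a sample of size ``w``.

    Equals ``(w - 1) / sqrt(w)``; a rolling 3-sigma rule can therefore only
    ever fire when its window holds more than 10 samples.
    """
    if int(w) < 2:
        raise ParameterError(f"window length must be >= 2, got {w}")
    return (w - 1) / np.sqrt(w)


# ---------------------------------------------------------------------------
# Normal-theory constants behind the robust-scale conventions, recomputed
# from first principles (standard normal quantiles / CDF).

def mad_normal_constant() -> float:
    """Consistency constant b = 1/Φ⁻¹(3/4) making b × MAD estimate σ (≈1.4826)."""
    return 1.0 / float(stats.norm.ppf(0.75))


def three_sigma_coverage_percent() -> float:
    """Percentage of a normal population within ±3σ (≈99.73 %)."""
    return 100.0 * (2.0 * float(stats.norm.cdf(3.0)) - 1.0)


def iqr_normal_width() -> float:
    """IQR of the standard normal, Φ⁻¹(3/4) − Φ⁻¹(1/4) (≈1.349)."""
    return float(stats.norm.ppf(0.75) - stats.norm.ppf(0.25))


def iqr_sigma_multiple(factor: float = 2.0) -> float:
    """σ-multiple of an IQR band: factor × normal IQR (≈2.7 for factor 2)."""
    return factor * iqr_normal_width()


def min_window_for_threshold_factor(factor: float = 3.0) -> int:
    """Smallest window size whose maximum attainable z-score exceeds *factor*."""
    w = 2
    while max_threshold_factor(w) <= factor:
        w += 1
    return w
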