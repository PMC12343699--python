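"""Causal and offline smoothing of in-line permittivity signals.

Permittivity probes report viable-biomass-correlated capacitance (pF/cm) once
per minute; the raw trace carries substantial measurement noise that must be
reduced before any change-detection transform is applied.  Two regimes are
covered here:

* **offline** — :func:`smooth_offline`, a local polynomial (loess-style)
  regression over the *whole* record.  It may look into the future and is used
  to build a "noiseless" reference trace against which real-time smoothers are
  scored.
* **causal** — :func:`smooth_causal`, a streaming smoother that sees only the
  ``w`` most recent samples (right-aligned window ending at the current
  sample).  Every causal window smoother of length ``w`` lags the input by
  roughly ``(w - 1) / 2`` samples; :func:`theoretical_delay` returns that
  figure.

During warm-up (fewer than ``w`` samples seen) the causal smoothers operate on
all available samples instead of emitting nothing, so the output trace is
always full length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError, StateError

SMOOTHING_METHODS = (
    "moving_mean",
    "moving_median",
    "gaussian",
    "savitzky_golay",
    "lowess",
    "loess",
)

#: implied local-regression degree for the named loess variants
_LOCAL_DEGREE = {"lowess": 1, "loess": 2}


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube weight kernel ``(1 - |u|^3)^3`` for ``|u| < 1``, else 0."""
    u = np.clip(np.abs(np.asarray(u, dtype=float)), 0.0, 1.0)
    return (1.0 - u**3) ** 3


@dataclass(frozen=True)
class SmootherSpec:
    """Configuration of a causal smoother.

    Parameters
    ----------
    method:
        One of :data:`SMOOTHING_METHODS`.
    w:
        Window length in samples (>= 1).  The causal window is the ``w`` most
        recent samples, ending at the current one.
    gaussian_sigma:
        Standard deviation of the Gaussian kernel in samples.  ``None`` means
        the conventional ``w / 5``.
    poly_degree:
        Polynomial degree for the Savitzky-Golay fit (default 2).
    robust_iterations:
        Number of bisquare reweighting passes for the loess variants
        (0 = plain weighted least squares).
    """

    method: str = "gaussian"
    w: int = 70
    gaussian_sigma: float | None = None
    poly_degree: int = 2
    robust_iterations: int = 0

    def __post_init__(self) -> None:
        if self.method not in SMOOTHING_METHODS:
            raise ParameterError(f"unknown smoothing method {self.method!r}")
        if int(self.w) < 1:
            raise ParameterError(f"window length w must be >= 1, got {self.w}")
        if self.method == "savitzky_golay" and self.w < self.poly_degree + 1:
            raise ParameterError(
                f"Savitzky-Golay needs w >= poly_degree + 1 "
                f"(w={self.w}, degree={self.poly_degree})"
            )
        if self.gaussian_sigma is not None and not self.gaussian_sigma > 0:
            raise ParameterError("gaussian_sigma must be > 0")
        if self.robust_iterations < 0:
            raise ParameterError("robust_iterations must be >= 0")

    @property
    def sigma(self) -> float:
        """Effective Gaussian standard deviation (defaults to ``w / 5``)."""
        if self.gaussian_sigma is not None:
            return float(self.gaussian_sigma)
        return self.w / 5.0


def smooth_causal(buffer, spec: SmootherSpec) -> float:
    """Smooth the newest sample of *buffer* using only past and present data.

    *buffer* is ordered oldest to newest; at most the last ``spec.w`` samples
    are used.  Returns the smoothed value for the newest time point.
    """
    x = np.asarray(buffer, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise StateError("smoothing buffer is empty")
    x = x[-spec.w :]
    m = x.size
    method = spec.method

    if method == "moving_mean":
        return float(x.mean())
    if method == "moving_median":
        return float(np.median(x))
    if method == "gaussian":
        # distances from the newest sample; kernel centred on "now"
        d = np.arange(m - 1, -1, -1, dtype=float)
        wts = np.exp(-0.5 * (d / spec.sigma) ** 2)
        wts /= wts.sum()
        return float(wts @ x)

    # polynomial fits, evaluated at the newest time point (t = 0)
    if m == 1:
        return float(x[-1])
    t = np.arange(m, dtype=float) - (m - 1)
    if method == "savitzky_golay":
        deg = min(spec.poly_degree, m - 1)
        wts = np.ones(m)
    else:
        deg = min(_LOCAL_DEGREE[method], m - 1)
        # span reaches one sample beyond the oldest point so every weight
        # stays positive and the design matrix keeps full rank
        wts = tricube(np.abs(t) / m)
    coef = np.polynomial.polynomial.polyfit(t, x, deg, w=np.sqrt(wts))
    return float(coef[0])


def smooth_series_causal(values, spec: SmootherSpec) -> np.ndarray:
    """Apply :func:`smooth_causal` sample by sample over a full series."""
    x = np.asarray(values, dtype=float)
    out = np.empty_like(x)
    w = spec.w
    for i in range(x.size):
        out[i] = smooth_causal(x[max(0, i - w + 1) : i + 1], spec)
    return out


def _loess_pass(y: np.ndarray, k: int, degree: int, robust_w: np.ndarray) -> np.ndarray:
    n = y.size
    fit = np.empty(n)
    t_all = np.arange(n, dtype=float)
    for i in range(n):
        lo = min(max(i - (k - 1) // 2, 0), n - k)
        idx = slice(lo, lo + k)
        t = t_all[idx] - i
        d = np.abs(t).max()
        wts = tricube(np.abs(t) / d) * robust_w[idx]
        deg = degree
        nz = int(np.count_nonzero(wts))
        if nz <= deg:  # robust pass may have zeroed too many points
            deg = max(nz - 1, 0)
        if deg == 0:
            s = wts.sum()
            fit[i] = float((wts @ y[idx]) / s) if s > 0 else float(y[i])
            continue
        coef = np.polynomial.polynomial.polyfit(t, y[idx], deg, w=np.sqrt(wts))
        fit[i] = float(coef[0])
    return fit


def smooth_offline(series, span_fraction: float = 0.03, degree: int = 2,
                   robust_iterations: int = 0):
    """Offline loess smoothing over the complete (uniformly sampled) record.

    Each point is replaced by a weighted local polynomial fit of the given
    *degree* over its ``ceil(span_fraction * n)`` nearest neighbours, with
    tricube distance weights.  ``robust_iterations > 0`` applies iterated
    reweighting with bisquare weights on scaled residuals, down-weighting
    outliers.

    Accepts either a plain 1-D array or an object with a ``values`` attribute
    (e.g. :class:`~permclean.io.PermittivitySeries`) and returns the same kind.
    """
    values = getattr(series, "values", series)
    y = np.asarray(values, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ParameterError("offline smoothing needs a 1-D series of length >= 3")
    if not 0.0 < span_fraction <= 1.0:
        raise ParameterError("span_fraction must lie in (0, 1]")
    if degree not in (1, 2):
        raise ParameterError("degree must be 1 or 2")
    n = y.size
    k = int(np.ceil(span_fraction * n))
    if k < degree + 1:
        raise ParameterError(
            f"span window of {k} samples is too small for degree {degree}"
        )
    k = min(k, n)

    robust_w = np.ones(n)
    fit = _loess_pass(y, k, degree, robust_w)
    for _ in range(robust_iterations):
        r = y - fit
        s = 6.0 * float(np.median(np.abs(r)))
        if s == 0.0:
            break
        robust_w = np.clip(1.0 - (r / s) ** 2, 0.0, None) ** 2
        fit = _loess_pass(y, k, degree, robust_w)

    if hasattr(series, "values") and hasattr(series, "replace_values"):
        return series.replace_values(fit)
    return fit


def theoretical_delay(w: int) -> float:
    """Expected lag ``(w - 1) / 2`` (in samples) of a causal window smoother."""
    if int(w) < 1:
        raise ParameterError(f"window length w must be >= 1, got {w}")
    return (w - 1) / 2.0
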