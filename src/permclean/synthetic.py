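"""Synthetic fed-batch permittivity traces with ground-truth anomalies.

The generator emulates the qualitative shape of an in-line permittivity
signal from a *Pichia pastoris* fed-batch cultivation: exponential growth
during the glycerol batch phase, a smooth non-anomalous dip at the
glycerol→methanol substrate switch (the culture adapts for roughly 1-2 h with
little growth), slower exponential growth during methanol induction, and a
stationary plateau once the signal saturates.  Gaussian measurement noise and
injected *spike* (transient, zero-returning) and *shift* (persistent step)
anomalies are added on top, with exact ground-truth annotations.

The substrate-switch dip is deliberately **not** annotated: it is a genuine
process feature, and a well-behaved detector must ignore it because it is
gradual, not because it is small.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .evaluation import AnnotationSet
from .io import PermittivitySeries


@dataclass(frozen=True)
class Injection:
    """One injected anomaly: a transient spike or a persistent shift."""

    kind: str
    onset_index: int
    magnitude: float
    width: int = 1  # spikes only

    def __post_init__(self) -> None:
        if self.kind not in ("spike", "shift"):
            raise ParameterError(f"unknown injection kind {self.kind!r}")
        if self.magnitude == 0:
            raise ParameterError("injection magnitude must be nonzero")
        if self.kind == "spike" and int(self.width) < 1:
            raise ParameterError("spike width must be >= 1 sample")
        if self.onset_index < 0:
            raise ParameterError("onset_index must be >= 0")

    def span(self) -> tuple[int, int]:
        """Samples the injection directly alters (inclusive indices)."""
        if self.kind == "spike":
            return self.onset_index, self.onset_index + self.width - 1
        return self.onset_index, self.onset_index


@dataclass(frozen=True)
class ScenarioSpec:
    """Everything that defines one synthetic cultivation trace.

    Growth rates default to the plausible range for methanol-grown
    *P. pastoris* (0.02-0.15 1/h); the batch phase on glycerol is the faster
    one.  ``noise_sigma`` is absolute (pF/cm); with ``noise_proportional``
    the local standard deviation scales with the clean signal level.
    """

    duration_h: float = 40.0
    sample_period_s: float = 60.0
    baseline: float = 2.0          # pF/cm at inoculation
    mu_batch: float = 0.12         # 1/h, glycerol batch phase
    mu_fedbatch: float = 0.04      # 1/h, methanol fed-batch phase
    switch_time_h: float = 24.0    # glycerol -> methanol
    dip_depth_frac: float = 0.05   # fractional trough depth at the switch
    dip_duration_h: float = 1.5    # adaptation period, ~1-2 h
    plateau_cap: float = 30.0      # stationary-phase ceiling, pF/cm
    noise_sigma: float = 1.8       # pF/cm
    noise_proportional: bool = False
    anomalies: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.duration_h > 0:
            raise ParameterError("duration_h must be > 0")
        if not self.sample_period_s > 0:
            raise ParameterError("sample_period_s must be > 0")
        for mu in (self.mu_batch, self.mu_fedbatch):
            if mu < 0:
                raise ParameterError("growth rates must be >= 0")
        if not 0 <= self.dip_depth_frac < 1:
            raise ParameterError("dip_depth_frac must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        object.__setattr__(self, "anomalies", tuple(self.anomalies))
        n = self.n_samples
        spans = []
        for inj in self.anomalies:
            start, end = inj.span()
            if end >= n:
                raise ParameterError(
                    f"injection at {start} extends past the trace ({n} samples)")
            spans.append((start, end))
        spans.sort()
        for (s0, e0), (s1, _) in zip(spans, spans[1:]):
            if s1 <= e0:
                raise ParameterError("injections overlap")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_h * 3600.0 / self.sample_period_s))


def inject(values, injection: Injection) -> np.ndarray:
    """Return a copy of *values* with one anomaly added.

    A spike adds ``magnitude`` over ``[onset, onset + width)`` and returns to
    baseline; a shift adds ``magnitude`` from onset to the end of the series.
    """
    x = np.asarray(values, dtype=float).copy()
    start, end = injection.span()
    if end >= x.size:
        raise ParameterError(
            f"injection ({start}, {end}) outside series of length {x.size}")
    if injection.kind == "spike":
        x[start : end + 1] += injection.magnitude
    else:
        x[start:] += injection.magnitude
    return x


def _clean_trace(spec: ScenarioSpec) -> np.ndarray:
    dt_h = spec.sample_period_s / 3600.0
    t = np.arange(spec.n_samples) * dt_h
    ts = spec.switch_time_h
    level_at_switch = spec.baseline * np.exp(spec.mu_batch * ts)
    growth = np.where(
        t < ts,
        spec.baseline * np.exp(spec.mu_batch * t),
        level_at_switch * np.exp(spec.mu_fedbatch * (t - ts)),
    )
    growth = np.minimum(growth, spec.plateau_cap)
    if spec.dip_depth_frac > 0 and spec.dip_duration_h > 0:
        in_dip = (t >= ts) & (t < ts + spec.dip_duration_h)
        phase = (t[in_dip] - ts) / spec.dip_duration_h
        trough = 1.0 - spec.dip_depth_frac * 0.5 * (1.0 - np.cos(2 * np.pi * phase))
        growth[in_dip] *= trough
    return growth


def _annotation_for(injection: Injection) -> tuple[int, int, str]:
    start, end = injection.span()
    if injection.kind == "spike":
        # the first post-spike sample carries the down-flank of the excursion
        return start, end + 1, "spike"
    return start, end, "shift"


def generate(spec: ScenarioSpec):
    """Generate one scenario.

    Returns ``(clean, noisy, annotations)``: the noiseless trace, the noisy
    trace with anomalies injected, and the ground-truth
    :class:`~permclean.evaluation.AnnotationSet`.  Identical specs (same
    seed) reproduce bit-identical output.
    """
    clean = _clean_trace(spec)
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma
        if spec.noise_proportional:
            sigma = sigma * clean / clean.max()
        noisy = clean + rng.normal(0.0, 1.0, clean.size) * sigma
    else:
        noisy = clean.copy()
    intervals = []
    n = clean.size
    for injection in spec.anomalies:
        noisy = inject(noisy, injection)
        start, end, label = _annotation_for(injection)
        intervals.append((start, min(end, n - 1), label))
    period = spec.sample_period_s
    return (
        PermittivitySeries(clean, sample_period_s=period),
        PermittivitySeries(noisy, sample_period_s=period),
        AnnotationSet(tuple(intervals)),
    )


# ---------------------------------------------------------------------------
# Canonical study conditions for anomaly-recovery experiments.
#
# Injections sit on the stationary plateau of a short trace: the correction
# factor is a difference of two 15-sample means taken ~30 samples apart, so
# any growth slope enters Fc as bias by construction.  Measuring recovery on
# the plateau isolates the injected quantity.  The matching pipeline
# configuration uses a light Gaussian smoother (w = 5), sized for this
# scenario's modest sensor noise (sigma = 0.2 pF/cm).

RECOVERY_NOISE_SIGMA = 0.2
RECOVERY_ONSET = 510  # sample index, well inside the plateau


def _recovery_base(seed: int, anomalies: tuple) -> ScenarioSpec:
    return ScenarioSpec(
        duration_h=10.0, baseline=5.0, mu_batch=0.12, mu_fedbatch=0.0,
        switch_time_h=11.0, dip_depth_frac=0.0, plateau_cap=12.0,
        noise_sigma=RECOVERY_NOISE_SIGMA, anomalies=anomalies, seed=seed,
    )


def shift_recovery_scenario(height: float, seed: int) -> ScenarioSpec:
    """Plateau trace with one persistent shift of *height* pF/cm."""
    return _recovery_base(seed, (Injection("shift", RECOVERY_ONSET, height),))


def spike_merging_scenario(magnitude: float, width: int, seed: int) -> ScenarioSpec:
    """Plateau trace with one symmetric spike (up then back down)."""
    return _recovery_base(
        seed, (Injection("spike", RECOVERY_ONSET, magnitude, width),))


def recovery_config():
    """Pipeline configuration matched to the recovery scenarios."""
    from .config import PipelineConfig
    from .smoothing import SmootherSpec

    return PipelineConfig(smoother=SmootherSpec("gaussian", w=5))
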