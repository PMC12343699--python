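# Methods

This note documents the model behind `permclean`, the choices made where the
design was genuinely open, and what the synthetic test suite does and does
not demonstrate.

## Signal model and pipeline

The input is a uniformly sampled (default 60 s) univariate permittivity
trace in pF/cm.  We model it as

    raw(t) = biomass_signal(t) + noise(t) + artefacts(t)

where `biomass_signal` is smooth and slowly varying (growth kinetics),
`noise` is approximately Gaussian measurement noise, and `artefacts` are
transient spikes (up-flank followed by a down-flank of similar magnitude)
and persistent baseline shifts.  The streaming loop processes one sample per
iteration:

1. `smoothed = causal_smooth(raw history, w)`
2. `candidate = smoothed − fc_total` (cumulative shift compensation)
3. `perm_d = DRA(candidate history; w1, w2)`
4. threshold decision on `perm_d`
5. replacement / validation / merging / Fc bookkeeping

### Causal smoothing

All causal smoothers operate on the `w` most recent samples,
**right-aligned** at the current sample.  The classical centred window of a
moving mean, Gaussian kernel or Savitzky-Golay filter is non-causal; the
causal right-aligned form is the streaming equivalent and exhibits the
expected group delay of about `(w − 1)/2` samples, which the evaluation
module can verify empirically by cross-correlation.  During warm-up the
smoother uses every available sample instead of emitting nothing, so the
output trace is full length.

For the Gaussian kernel the weights follow a Gaussian centred on the newest
sample (σ defaults to `w/5`) and are normalized to sum to one.  Causal
Savitzky-Golay and lowess/loess fit a weighted polynomial over the buffer
and evaluate it at the newest time point; the loess variants use tricube
distance weights scaled so the oldest point keeps a small positive weight
(full-rank design matrix on tiny warm-up buffers).

The offline reference smoother is a standard loess: for each point, a
degree-1 or degree-2 weighted polynomial over the `ceil(span × n)` nearest
neighbours with tricube weights, optionally iterated with bisquare
robustness weights on residuals scaled by six times their median absolute
value.  It reproduces polynomials up to its degree exactly and matches
`statsmodels.nonparametric.lowess` to machine precision on the degree-1
path (used as an independent oracle in the tests); degree 2 is needed for
the reference trace and is not available in statsmodels, which is why the
smoother is implemented here.

### DRA transform

`perm_d(t) = mean(last w1 candidates) − mean(last w2 candidates)`, both
windows ending at t (overlapping mode, the default) or the second window
immediately preceding the first (adjacent mode).  The transform removes
constant offsets exactly and converts a slope `s` into the constant
`s·(w2 − 1)/2` (for `w1 = 1`), so slow growth contributes only a small
positive floor while sudden jumps appear at nearly full height
(`14/15 × h` for a step of `h` with `w1 = 1, w2 = 15`).  Warm-up samples
emit 0: nothing can be flagged before the windows fill.  The short-window
mean is the minuend, so upward jumps give positive `perm_d`.

### Detection

Static threshold: `|perm_d| > 1.06 pF/cm` by default.  Detection is
two-sided because every spike has a down-flank of similar magnitude that
must be caught; a one-sided mode is available in the configuration.

Dynamic thresholds compute `location ± factor × scale` over the `w3`
transformed values strictly **before** the current sample, so a jump cannot
inflate its own band; the delayed response of dynamic bands to volatility
changes is an inherent property of this construction.  Conventions fixed
here because they change band edges on small windows: sample standard
deviation with `n − 1` denominator; linear-interpolation quantiles for
Q1/Q3; MAD scaled by `b = 1.4826 = 1/Φ⁻¹(3/4)`.  A zero-scale (collapsed)
band flags only strictly non-zero deviations; `min_scale` imposes an
optional scale floor.  Within a window of size `w` no point can lie more
than `(w − 1)/√w` standard deviations from the window mean, so a factor-3
band needs `w3 > 10` to be able to fire at all.

While a sample is flagged, its `perm_d` is *not* pushed into the dynamic
band window — the anomaly would otherwise poison the very statistic meant
to catch it.

### Validation, merging and Fc

The emitted corrected value while flagged (and during validation) is the
mean of the 15 most recent corrected values.  The DRA, however, consumes
the *candidate* stream (smoothed − fc_total, before replacement): if the
DRA history were held at the replacement baseline, a persistent shift would
keep `perm_d ≈ h` forever and the anomaly could never close, making Fc
uncomputable.  With the candidate stream, `perm_d` decays as the long
window catches up and the interval closes after roughly `w2` samples.

`Fc = mean(candidate over the 15-sample validation window) −
mean(15 corrected values before the first flagged sample)`.  The pre-mean
is frozen at anomaly onset, so the Fc of a merged group always references
the level before the *first* flank.  Any anomaly re-firing during
validation extends the registered interval and restarts the countdown,
guaranteeing at least 15 clean samples after the last flank and at least 15
non-anomalous samples between registered rows.  When Fc is folded into
`fc_total`, the stored DRA history is re-based by −Fc; without this the
compensation step itself appears as a −Fc jump in the candidate stream and
would be re-detected.  Correction is forward-only (streaming consumers
cannot revise the past); a retroactive rewrite of history is possible
offline from the output CSV (`corrected` plus the logged per-anomaly Fc)
but is not part of the streaming loop.

Non-finite raw samples are treated as sensor dropout: flagged and logged
distinctly, the smoother's input held at its last value.  A run ending
inside an anomaly closes it at the final index; a run ending mid-validation
finalizes Fc from the truncated post window with a warning.

Known limitation: Fc is a difference of two 15-sample means taken ~30
samples apart, so any genuine growth over that span enters Fc as bias.  At
realistic growth rates (2–15 %/h) this is a few tenths of a pF/cm per
event; it is inherent to the before/after-mean construction.  Heavy
smoothing adds a second bias: with `w = 70` the smoothed step transition is
not complete when validation ends, so Fc underestimates large shifts by a
few percent.  The recovery studies therefore use light smoothing (below).

## Synthetic data

The generator emulates a fed-batch cultivation trace: piecewise exponential
growth (`X0·e^{μt}` per phase, batch μ faster than fed-batch μ, both inside
the plausible 0.02–0.15 h⁻¹ band for methanol-grown yeast), a smooth
multiplicative cosine trough at the substrate switch (the 1–2 h adaptation
dip, deliberately **not** annotated: it is a process feature, and it must
go undetected because it is gradual, not because it is small), a stationary
plateau cap, additive Gaussian noise, and injected spike/shift anomalies
with exact annotations.  Spike annotations span `[onset, onset + width]`
(the first return sample carries the down-flank); shifts are annotated at
their onset sample.  The default noise level (σ = 1.8 pF/cm against a
~28 pF/cm range) puts the raw trace near 6–7 % NRMSE of the clean trace,
a realistic magnitude for an uncleaned permittivity signal.

What the generator does *not* emulate: conductivity-dependent noise
structure, autocorrelated disturbances (gas hold-up fluctuations),
irregular sampling, multi-probe effects.  Passing tests demonstrate correct
mechanics and parameter recovery under the stated model, not performance on
any particular plant's data.

### Study conditions for the recovery experiments

`shift_recovery_scenario` / `spike_merging_scenario` place a single
injection on the stationary plateau of a 10 h trace (baseline 5 pF/cm,
plateau 12 pF/cm, σ = 0.2 pF/cm) and pair it with a Gaussian `w = 5`
smoother (`recovery_config`).  The plateau isolates the injected quantity
from the growth-trend bias discussed above, and the light smoother is the
appropriate choice at this noise level (its DRA step response retains 83 %
of a step, so even h = 2 pF/cm shifts clear the 1.06 threshold).  Observed
over 100 seeded replicates each: shifts of 2/5/10 pF/cm are registered as
exactly one anomaly in every run with |Fc − h| ≤ 4σ/√15 in ≈98 % of runs;
spikes of width 3–10 merge into a single row in every run with
|Fc| ≤ 2σ throughout.  These rates are recomputed by
`scripts/acceptance.py` and asserted (≥ 95 %) in `tests/test_acceptance.py`.

## Numerical and interface choices

- Streaming and batch DRA produce bit-identical results: the batch form
  evaluates the same `mean` over the same window contents per sample.
- Cross-correlation delay estimation mean-removes both signals and
  normalizes per overlapping support; ties break toward the smallest |lag|.
  On trend-dominated signals (random walks) it recovers filter delays near
  `(w − 1)/2`; on noise-dominated signals the correlation peaks near lag 0
  because the causal kernel's weight concentrates on the newest sample —
  which is why measured delays are typically smaller than the theoretical
  figure.
- Point-wise (per-sample) confusion counting; datasets without annotated
  anomalies are excluded from F1 averaging but contribute a false-positive
  diagnostic column in grid searches.  Grid results sort by mean F1
  descending, ties broken by smaller `w2`, then smaller static threshold.
- Output CSVs use a fixed `%.6g` float format; repeated runs are
  byte-identical.
- Warm-up: no detection until the longest configured window (smoother,
  DRA, band, replacement) has filled.
- Problem sizes in tests and the acceptance script (600–2400-sample traces,
  100 replicates per study) were chosen to give stable ≥95 % pass/fail
  margins at interactive runtimes.
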