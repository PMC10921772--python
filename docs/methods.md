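# Methods

This note documents the models, conventions and numerical choices behind
`csfdyn`, and what the synthetic test bed does and does not establish
about real data.

## Signal model

A real-time phase-contrast acquisition of CSF yields a continuous
flow-rate signal Q(t) (ml/min, positive = caudocranial) sampled every
78–96 ms for 30–50 s. The package models it as

Q(t) = N(t) + A(t) · w(ψ(t)),

where w is a zero-mean, unit peak-to-peak cardiac waveform with its
minimum at the cycle boundary (cycles are cut minimum-to-minimum), ψ the
within-cycle phase, A the peak-to-peak flow amplitude and N the net
(offset) flow. Respiration modulates the cycle period Tc, A and N at the
breathing period Tb (~3.4 s at rest); heart rate modulation is the
respiratory sinus arrhythmia.

Two waveform templates are provided: `sinusoid` (−cos(2πψ)/2), whose
closed forms anchor the oracle tests, and `csf_like`, a two-harmonic
template sin 2πψ + 0.35 sin(4πψ + π/3) rescaled to zero mean and unit
peak-to-peak and rolled so its minimum sits at ψ = 0 — an asymmetric
systolic trough resembling measured aqueduct and spinal CSF curves. The
template is a plausible stand-in, not a fit to any particular subject.

## Synthetic generator

`SimulationConfig` defaults describe a spinal (C2-C3) free-breathing
acquisition: 45 s at 96 ms/frame, T0 = 0.832 s, A0 = 338 ml/min,
N0 = 9.4 ml/min, Tb = 3.4 s. Each cycle's period is drawn from the
breathing phase of its own midpoint (resolved by fixed-point iteration,
since the midpoint depends on the period); the amplitude and net offset
follow *continuous* breathing-locked envelopes evaluated along the record.
The continuous choice matters: stepping A or N per beat would place
artificial discontinuities exactly at the minima the analysis segments
on, and the resulting step rectification measurably biases the recovered
modulation phases. Per-cycle ground truth records the envelope values at
each midpoint.

Depth calibration. The configured depths are the insp/exp contrasts the
analysis should measure. A sinusoidal modulation p = p0(1 + m sin(2πφ + Φ))
has half-cycle mean contrast p0·m·4/π (the mean of sin over a half cycle
is 2/π), so the generator sets m = Δp%·π/400. Two refinements:

- Qnet modulation is additive and scaled by A0 (CSF net flow is near zero
  and its percent contrast is normalized by the amplitude), and its
  envelope coefficient is divided by sinc(T0/Tb) ≈ 0.90 because a cycle's
  measured net flow is the beat-mean of the envelope, which attenuates a
  Tb-periodic sinusoid by exactly that factor.
- With the analysis' shift-sign convention (a cycle joins the phase
  containing midpoint + Φ), a lag injected as +Φ° is recovered as
  Φp° = +Φ°; the sweep curve is Δp(Φs) ∝ cos(2πΦs/Tb − Φ).

The belt is a raised cosine with troughs at multiples of Tb; its
ascending half (breathing phase in [0, 0.5)) is inspiration. Noise is
additive white Gaussian on the flow samples, seeded; no 1/f or
ultra-slow (<0.1 Hz) physiological component is modelled.

What the generator does *not* emulate: k-space/MR physics, partial-volume
area bias, vessel-area change with breathing, thoracic-vs-abdominal belt
differences, heart-rate drift unrelated to breathing. Passing tests
demonstrate that the *analysis operators* are correct and well
conditioned at realistic signal scales — not that any physiological
claim holds in vivo.

## Image chain

Rendering uses a uniform plug profile: every lumen pixel carries
v = Q·(1000/60)/(area·10) cm/s; the eddy-current-like offset applies to
all pixels (a phase offset is spatially global); aliasing wraps stored
velocities into [−VENC, VENC).

Segmentation uses the fraction of mean-removed spectral power each pixel
carries in the cardiac band (default 0.8–2.0 Hz = 48–120 BPM), computed
over the whole record with the DC bin excluded, so the statistic is
invariant to constant offsets. The threshold defaults to 0.5: white noise
puts about bandwidth/Nyquist ≈ 0.23 of its power in the band at a 96 ms
frame interval, while plug-flow CSF pixels sit near 0.9, so 0.5 separates
the populations by a wide margin in both directions. The mask is the
4-connected component containing the seed; the record must cover ≥ 5
cardiac periods for the band to be resolvable.

The stationary region is the ring of pixels at taxicab distance
[2, 2 + width) from the mask (width 3 by default), excluding pixels that
are themselves pulsatile; its spatiotemporal mean velocity becomes the new
zero. De-aliasing unwraps each pixel's time course by multiples of
2·VENC, anchored at the frame with the smallest stored |v| — the one
least likely to be aliased — and propagating outward; this is robust to
records that *begin* at the aliased systolic trough, where an
assume-the-first-frame anchor fails. Temporal unwrapping presumes the
true frame-to-frame velocity change stays below VENC; pixels whose
unwrapped course leaves the single-wrap range (|v| ≥ 3·VENC) are reported
and left untouched rather than silently corrected.

## Cycle reconstruction

The flow record is first upsampled ×8 by polyphase-FIR interpolation: the
cardiac content lies far below the frame-rate Nyquist, and working on the
dense grid removes a sampling-alignment artifact in which the accuracy of
each beat's measured extremes depends on where the ~10 frames per beat
fall — an alignment that drifts with the respiration-modulated cycle
length and would otherwise imprint a spurious breathing-locked component
on the per-cycle amplitudes.

Minima detection: a 5 Hz low-pass (clipped below Nyquist) suppresses
noise; a second low-pass at half the cardiac frequency estimates the
breathing-band baseline, which is subtracted before any timing decision —
otherwise baseline wander drags the trough positions and aliases
respiratory structure into the measured periods. Coarse minima come from
peak-finding with a half-period spacing constraint, are refined to the
sample minimum of the detrended signal within ±¼ median period, and are
placed at sub-sample precision by a three-point parabolic fit.

Cycles outside [0.6, 1.4] × the median duration are discarded and logged
(guards against missed or spurious minima). Each retained cycle is
resampled to 32 equispaced phases by shape-preserving piecewise-cubic
(PCHIP) interpolation — exact at the knots, no overshoot — keeping one
sample of margin beyond each boundary so evaluation never extrapolates.
Averaging is an unweighted pointwise mean; Tc is the mean duration.

Parameters: Qnet = mean, Amplitude = max − min; stroke volumes integrate
the positive and negative parts by the trapezoid rule on the periodically
closed 32-point grid (dt = Tc/32), converted ml/min·s → mm³ by 1000/60;
SV = (SV⁺ + SV⁻)/2. On this grid the SV of a pure sinusoid agrees with
the closed form A·Tc·1000/(60π) to 0.3 %. Velocities divide the peak
flows by the segment area (cm/s = ml/min · (1000/60)/(area·10)) and are
reported as magnitudes; a direction with no flow yields 0.

## Breathing-effect quantification

Inspiration = belt trough → peak on a smoothed copy; only complete
trough-to-trough cycles with exactly one interior peak are kept; records
with fewer than two complete cycles or trough-interval variability above
50 % (irregular breathing) are rejected. The extrema search admits
boundary samples (records often start at end-expiration) and uses a
spacing constraint capped at 2 s so that short breaths are detected — and
the irregularity check can fire — even when the spectral peak sits
elsewhere.

Assignment uses half-open intervals (a midpoint exactly on a boundary
joins the interval starting there). The sweep grid is −3.0 … +3.0 s
inclusive in 0.1 s steps (61 points). At each shift both phase averages
are rebuilt from the precomputed 32-vectors; shifts where either set is
empty are missing — isolated gaps are filled by linear interpolation,
and more than 20 % missing aborts. Intensity = half peak-to-peak of
Δp(Φ), which reproduces the worked identity ((144 − (−137))/2 = 140.5)
and is robust to curves not symmetric about zero. The reported Φp is the
grid shift of whichever extreme (max or min), after wrapping into the
principal breathing interval (Φp% ∈ (−50, 50]), lies closer to zero —
ties break toward the maximum. Wrapping both enforces the (−50, 50]
convention and prevents the replica lobe touching the ±3 s grid edge from
being selected under noise. Normalization means are computed once from
all cycles retained at Φ = 0.

Besides the intensity, `PhaseSweepResult` carries the signed Δp at Φ = 0
(`delta_at_zero`): the intensity is non-negative by construction, so the
zero-shift value is the quantity with zero expectation under the null and
is what the type-I tests assert on.

## Agreement statistics

BPM mismatch uses |BPM_a − BPM_b| relative to the pair mean (symmetric in
the methods; default threshold 10 %). Percentage Bland–Altman uses the
pair mean as denominator, d = 100(a − b)/mean(a, b), bias = mean(d),
limits = bias ± 1.96·SD(d); zero-mean pairs are dropped with a warning.
Correlation is Pearson when both samples pass Shapiro–Wilk at α = 0.05,
Spearman otherwise.

## Problem sizes and determinism

Recovery and null checks use 45 s records (≈54 beats, 13 breathing
cycles) and average 20 independent seeds; a single record is honest about
its own scatter (phase sd ≈ 10–30° depending on the parameter), the
20-seed mean recovers injected depths within a few percent and phases
within ~7°. Property tests of the sweep's breathing-periodicity and
belt-shift coupling use 180 s records, where edge-window subset changes
(which scale as the inverse record length) drop below the 5 %-of-intensity
tolerance. All randomness flows through explicit integer seeds; repeated
runs are bit-identical.

## Known limitations

- With zero noise and a single modulated parameter, the deterministic
  alignment between the frame grid and the (then nearly constant) beat
  length aliases the per-cycle interpolation error into the breathing
  band, which can bias the recovered amplitude phase by a few grid steps.
  Joint modulation (as in real RSA-bearing data) or sample noise
  decorrelates the alignment and removes the bias; the zero-noise
  single-parameter corner is physiologically unreachable.
- The measured ΔAmplitude% carries a mild (~10–15 %) attenuation relative
  to the injected depth: a min-to-min window reads the amplitude envelope
  partly at the beat edges (±Tc/2 from the midpoint), where a Tb-periodic
  envelope is attenuated by cos(πT0/Tb). This is a property of windowed
  peak-to-peak measurement of a continuously modulated signal, left
  uncompensated and within the recovery tolerance.
- Temporal de-aliasing cannot distinguish a genuine slew faster than VENC
  per frame from a wrap; such data violate its stated precondition.
- The segmentation reimplements the frequency-domain idea with an
  explicit statistic (band energy fraction) and threshold; it is not the
  original authors' algorithm, and the threshold may need retuning for
  other frame rates or bands.
- Cohort-level biases of real acquisitions (partial-volume area
  overestimation, SNR-dependent velocity underestimation) are out of
  scope of the plug-flow renderer.
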