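# Methods

This note documents the models, numerical choices and known limits of
`sepkit`, module by module. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Filter design and zero-phase application

Two filter classes are implemented, reflecting the two design traditions in
evoked-potential work.

**Kaiser-windowed sinc FIR.** The designer is driven by a ripple/attenuation
specification δ (default 0.001, i.e. A = 60 dB) and either an even order N or
a transition bandwidth Δf in Hz, related by the standard Kaiser formulas

    β = 0.1102 (A − 8.7)                       for A > 50 dB,
    N ≈ (A − 7.95) / (2.285 · 2π Δf / fs),     rounded up to even.

At δ = 0.001 the window parameter is β = 5.653. Orders are rounded *up to
the next even integer* so the group delay N/2 is an integer and single-pass
zero-phase application is an exact sample shift. The published orders
4948/7420 for Δf = 1.5/1 Hz at fs = 2048 Hz differ from this formula's
round-up by a few taps (4950/7426); where a pipeline stage reproduces the
published configuration it uses the published orders verbatim. Low-pass
kernels are windowed sincs scaled to unit DC gain; high-pass kernels are the
spectral inversion δ[n − N/2] − lowpass, which nulls DC *exactly* rather
than within ripple. Band-pass filters are the convolution of a high-pass
and a low-pass stage of the stated order each (total order 2N); this keeps
the transition semantics per edge and allows different sharpness per edge
in principle.

**Butterworth IIR.** "2nd order" is interpreted as 2nd order per band edge;
band-pass is a 2nd-order high-pass cascaded with a 2nd-order low-pass
(2 + 2 poles), not a single 4-pole band-pass section. Designs come from the
bilinear transform with frequency pre-warping, are kept as second-order
sections, and are verified stable (all poles strictly inside the unit
circle).

**Zero phase.** FIR filters are applied in a single central convolution
(the symmetric odd-length kernel makes "same"-mode convolution the
delay-compensated pass). IIR filters are applied forward, reversed,
filtered again and reversed back, which cancels the phase and squares the
magnitude (the half-power point of one pass becomes a 0.5 gain point).
The two-pass is written literally over reflect-padded data (pad length
3 × the summed section orders per end, configurable); tests pin it against
a per-sample direct-form recursion. Edge samples within roughly one
impulse-response length of the recording boundaries are transient-
contaminated, which is why recordings carry ≥ 30 s of padding around the
stimulus train. All filtering is in double precision.

**Transition-bandwidth measurement.** The realized transition width around
a cutoff is measured on a dense grid (2 mHz) as the span between the last
frequency whose attenuation is at least A and the first frequency whose
magnitude is within δ of unity. For a high-pass edge whose transition
reaches below DC (for example a 0.5 Hz edge designed with a 1 Hz
transition), the stopband edge is truncated and the stored measurement is
NaN.

## Standardization ("prep")

This stage replaces a full EEG standardization pipeline with deterministic,
documented minima; the scientific payload of the package is downstream.

* **Truncation** keeps 30 s before the first stimulus to 30 s after the
  last, clamped to the recording, with events re-based.
* **Bad channels** are flagged by a one-sided robust z-score of per-channel
  standard deviations ((sd − median)/1.4826·MAD > 5) plus any exactly
  constant channel. No RANSAC, no interpolation. Flagged channels stay in
  the data matrix but are excluded from referencing and dropped before ICA.
* **Line noise** is removed by least-squares sine/cosine regression at the
  mains frequency and harmonics in non-overlapping 4 s windows. A harmonic
  is only subtracted from a channel when its captured energy exceeds 10×
  the local noise level, estimated from identical probe fits at ±1.5 and
  ±3 Hz around the harmonic. The gate matters: an ungated least-squares fit
  removes ~√(2k/n) of the RMS from a perfectly clean window (≈ 2.7% for
  three harmonic pairs in a 4 s window at 2048 Hz), while the gated version
  is a near-identity on clean data and still attenuates genuine mains lines
  by far more than 20 dB. Notch filters are deliberately not offered.
* **Average reference** subtracts the instantaneous mean over good channels
  (idempotent, reduces rank by one).

## Epoching and artifact rules

Epochs span −100 to +150 ms, half-open in samples (512 samples at 2048 Hz),
with the stimulus at sample offset 0 and baseline correction over
[−100, 0) ms. Events whose window does not fit are dropped with a warning.

Five rules mark (never delete) epochs; any tested channel violating any
rule flags the epoch:

| rule  | statistic                            | threshold | window/step |
|-------|--------------------------------------|-----------|-------------|
| abs   | max absolute voltage                 | 100 μV    | —           |
| p2p   | windowed max − min                   | 150 μV    | 200/100 ms  |
| step  | half-window mean difference          | 100 μV    | 200/50 ms   |
| diff  | adjacent-sample difference           | 50 μV     | —           |
| flat  | run of samples with abs value < 2 μV | > 125 ms  | —           |

Windows anchor at the epoch start, advance on the stated grid, and one
final window is placed flush with the epoch end so the tail is always
covered. Samples in −2…2 ms (inclusive) are masked from every rule: window
statistics use only unmasked samples, the adjacent-difference rule skips
pairs touching the mask, and a masked gap breaks a flatline run (strict
inequality on the run duration). A practical consequence of the sliding
grid: a step-like transient only produces its full swing as a step
statistic when the transition aligns with a half-window boundary of the
grid; otherwise the best window mixes the two levels. Tests therefore pin
every rule against a literal nested-loop oracle rather than against
idealized closed-form values.

Manual overrides (`mark`/`unmark` with a reason, e.g. the convention of
keeping frontal step-like epochs that are eye blinks for later ICA repair)
are append-only; automatic flags survive in provenance.

## ICA cleanup

The decomposition algorithm is out of scope by design: the module consumes
an unmixing matrix plus one label per component ({brain, muscle, eye,
channel_noise, line_noise}) and back-projects the retained components,
`mixing[:, keep] · unmixing[keep] · data`, on the modelled channel subset
only. `mixing` defaults to the Moore–Penrose pseudo-inverse, so models
with fewer components than channels (for example channels − 1 after average
referencing) are accepted. Data are prepared for decomposition by
anti-alias filtering (Kaiser FIR low-pass at 0.8× the target Nyquist),
integer-factor decimation to 512 Hz, epoch extraction, and dropping of
flagged epochs and bad channels.

## N30 quantification

Good epochs are averaged pointwise; the amplitude is
|max in 15–25 ms − min in 25–35 ms| on the averaged F3 trace, peaks taken
as extremal samples (no interpolation), both windows inclusive of their
endpoints (a 25 ms extremum may be selected by both), ties broken to the
earlier latency. The measure is invariant to constant offsets and scales
linearly. Expert overrides re-read the amplitudes at supplied latencies and
set a `manual_adjusted` flag. Note the read-out is a biased statistic:
extrema over windows ride on residual noise, so anything that adds variance
to the average (fewer epochs, retained artifact components) inflates it —
which is precisely why the preprocessing comparison is interesting.

## Synthetic data generator

The generator emulates one stimulation session — 62 channels at 2048 Hz,
1000 stimuli at 2.3 Hz, 31 s edge padding — as `mixing · sources` with a
known square mixing matrix:

* **Evoked source**: Gaussian lobes at 20 ms (+2.0 μV, 5 ms FWHM) and 30 ms
  (−2.5 μV, 8 ms FWHM), topography peaked at F3. The widths are unequal on
  purpose: the complex then has non-zero net area and substantial spectral
  energy below 30 Hz, so a 30 Hz high-pass attenuates the measured
  peak-to-peak — the regime the passband comparison probes.
* **Stimulus-locked reflex EMG** (1.5 μV, biphasic lobes near 22/32 ms) on
  the muscle source: stimulation at motor threshold twitches the thumb, and
  the trial-consistent part of that EMG survives averaging. It gives the
  ICA comparison a deterministic direction: the measured N30 is inflated
  until the muscle component is removed.
* **Artifacts**: eye blinks (Tukey-windowed pulses, 150 μV, 4/min, frontal
  topography), muscle bursts (20–300 Hz band-limited noise under a Hann
  envelope, 30 μV, 3/min, spatially broad with a posterior maximum), a
  50 Hz mains line (5 μV, per-channel pick-up weights), a ±1 ms biphasic
  stimulus artifact (50 μV, injected after mixing with a flat topography),
  optional flat channels (zeroed after mixing).
* **Background**: one 1/f source per remaining channel (exponent 1, 8 μV
  RMS), each loading mainly on its home channel with small random
  cross-talk.
* **Timing**: stimulus times carry ±2 ms uniform jitter. Real stimulators
  are not sample-exact, and exactly periodic events would beat coherently
  against the mains period, producing a stimulus-locked 50 Hz residual in
  the average whose phase is an artifact of the sample grid.
* **Identifiability**: the mixing columns are redrawn (line weights and
  background cross-talk) until the condition number is below 150; a
  near-degenerate mixing would amplify any unmodelled content (stimulus
  artifact, regression residue) into the unmixed components.

Everything is driven by per-source RNG streams split from one master seed,
so output is bit-reproducible and adding one artifact type does not perturb
the others. The ground truth records sources, mixing, per-epoch artifact
labels, flat channels, the stimulus-artifact template and the true N30 of
the template; the true ICA model is the inverse of the (non-flat, matching
source subset) mixing.

The condition grid processes one recording through
{FIR, IIR} × {0.5–1000, 3–1000, 30–1000 Hz} × {no ICA, ICA}: gated line
removal, artifact detection on 1 Hz high-pass data of the matching class
(FIR order 4948), band filtering (FIR order 7420 per stage), epoching and
baseline correction, ground-truth component removal for the ICA arm, and
N30 measurement at F3. Average referencing is exercised in its own module
tests but is not part of the grid: it would make the referenced data
rank-deficient and the exact ground-truth unmixing would no longer apply,
muddying the component-removal comparisons the grid exists for.

**What the generator does not emulate** — volume conduction from a head
model, realistic electrode geometry, non-stationary background spectra,
subject covariance beyond a scalar random intercept, habituation of the
evoked response. Passing tests therefore show the pipeline's operations are
correct and the directional effects are reproduced under controlled
conditions; they do not certify effect sizes on human data.

**Scales used in tests.** Test and direction-of-effect runs use 8 channels,
40–120 stimuli and 3–5 s edge padding; these sizes keep the suite fast
while leaving every mechanism (flagging rates, averaging noise, filter
transients) in a realistic regime. The generator defaults remain the
full-session values.

## Statistics

**Paired t-test** on artifact counts: t = mean(d)/(sd(d)/√n), df = n − 1,
two-sided p, effect size r = √(t²/(t²+df)), 95% CI from the t quantile.
A zero-variance difference with non-zero mean reports an infinite t.

**Gamma random-intercept model.** Amplitudes are strictly positive and
right-skewed; the model is y_ij ~ Gamma(shape k, mean μ_ij) with
g(μ_ij) = x_ijᵀβ + z_i, z_i ~ N(0, σ²), where x is the treatment-coded
2 × 3 × 2 factorial with all interactions (reference cell FIR / 0.5–1000 /
no ICA; 12 coefficients) and g is log (default) or identity. The marginal
likelihood integrates z by adaptive Gauss–Hermite quadrature: per subject,
a Newton search finds the integrand's mode and curvature and the 21
standard nodes (configurable) are recentred and rescaled there, which keeps
the rule accurate at small node counts; the log-sum-exp is accumulated in
log space. (β, log σ, log k) are maximized jointly with L-BFGS-B from a
gamma GLM start (log σ bounded in [log 1e−6, log 10], so the σ → 0
boundary reduces smoothly to the GLM). The identity link guards μ ≤ 0 at
any node by penalized rejection. Fixed-effect covariance is the inverse
observed information from a central-difference Hessian. AICc is
AIC + 2p(p+1)/(n−p−1) with p = 14 (12 fixed effects, σ, k).

**Marginal means and contrasts.** Cell means are exp(x_cellᵀβ) with
delta-method standard errors and exponentiated linear-scale intervals.
Contrast families (filter within ICA × band; pairwise bands within
filter × ICA; ICA within filter × band) are linear functions of β reported
as ratios with asymptotic z statistics (no small-sample df correction —
a deliberate simplification). Multiplicity is controlled per family by a
single-step max-|z| adjustment: the adjusted p of a contrast is the
probability, under the contrasts' estimated null multivariate normal
(Monte-Carlo, 10⁵ draws, seeded), that the family maximum of |Z| exceeds
the observed |z|. This is the operating characteristic a Tukey-style
single-step procedure targets; Holm is available as a conservative
fallback. Confidence intervals are reported unadjusted.

**Recovery behaviour** is established by seeded simulation from the model
itself (the simulator draws complete 12-cell grids per subject and
session); the acceptance suite runs 500 replicates at 17 subjects × 2
sessions and checks the fixed effects for material bias.

## Interfaces

Continuous recordings travel as plain text: a TSV sample matrix (header =
channel labels), a two-column events TSV and a JSON sidecar. ICA models are
a TSV weight matrix plus a label-per-line file. The `sepkit` CLI is a thin
wrapper over these files and the library calls; the library API is the
primary interface.

## Known limitations

* The artifact `step` statistic's sensitivity depends on where a transient
  falls relative to the sliding-window grid (see above); per-subject
  adaptive thresholds are not implemented.
* The two-pass IIR padding (reflective, 3× filter memory) controls but does
  not eliminate edge transients for very low cutoffs; generous recording
  padding is the intended mitigation.
* `fit_gamma_lmm` estimates a single scalar random intercept; crossed or
  nested random effects and Kenward–Roger/Satterthwaite degrees of freedom
  are out of scope.
* The generator's topographies are schematic index-based weightings, not
  electrode-geometry fields.
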