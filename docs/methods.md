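# Methods

This note documents the models, parameters and numerical choices behind
`vocalsniff`, and what the synthetic-data tests do and do not establish
about real recordings.

## Detection model

USVs are detected as low-entropy epochs of a multitaper sonogram. Each
2 ms window (0.25 ms step) is tapered with 3 DPSS tapers at
time-bandwidth product `window × bandwidth = 2` (consistent with the
2TW−1 rule for 3 tapers at 1 kHz bandwidth), zero-padded to 0.5 kHz bin
spacing, and reduced to the 18–100 kHz power vector. The entropy
`H = −Σ pₙ log₂ pₙ` of the normalized vector is ~log₂(n_bins) ≈ 7.3 bits
for broadband noise and typically < 3 bits for a whistle; the detection
threshold is 6.5 bits. Frame times are window centers; frame count for a
trace of length L is `floor((L − window)/step) + 1`.

Below-threshold runs separated by ≤ 20 ms merge into one segment (so
segments are bounded by silences > 20 ms, and sub-syllable gaps shorter
than 20 ms stay inside one segment); merged segments shorter than 3 ms
are discarded. Segments whose median sonic-to-ultrasonic power ratio
exceeds 1 are rejected as broadband noise — an automatic stand-in for
manual curation of ambiguous events.

Caller assignment compares temporally overlapping segments across the
two microphones. The entropy statistic is the mean frame entropy over
the overlap. The dual-caller test (frequency tracks > 1 kHz apart for
> 3 ms) only counts frames where *both* channels are below the entropy
threshold; frames inside sub-syllable gaps have noise-driven peak
frequencies and would otherwise produce spurious divergence. The
frequency track itself is the per-frame argmax of ultrasonic power.

When audio is sampled below 200 kHz (the generator's 192 kHz fast mode),
the nominal 100 kHz band edge is unattainable and the default band top is
clamped to Nyquist − 1 kHz; every downstream statistic is insensitive to
this because rat calls stay below 90 kHz.

## Respiration model

The tubing transfer function is the ratio of distorted to reference
spectra (Fourier deconvolution); reference bins below 10⁻³ of the peak
magnitude inherit the nearest well-conditioned estimate. Inversion floors
`|TF|` at 10⁻³ of its maximum (phase preserved) to bound noise
amplification.

Drift removal is a zero-phase 0.1 Hz high-pass. A nominal 400 Hz
low-pass is retained as an anti-noise smoother, though at 1 kHz sampling
it is nearly inert; a low-pass cannot remove slow drift, so the high-pass
carries that job. Traces are z-scored and sign-flipped to
inhalation-positive (raw sensors read inhalation as a pressure drop).

Sniff landmarks are threshold crossings at 0 SD with a ±0.05 SD Schmitt
hysteresis (the threshold value is a free choice; 0 SD is the natural
fixed point of a z-scored trace). Crossing times are linearly
interpolated between samples for sub-millisecond precision. Cycles with
inhalations < 20 ms are rejected as aberrant; the final cycle (no next
onset) is dropped from rate computations. Phase warping is the
three-point piecewise-linear morph: inhalation → [0, f], exhalation →
[f, 1], with f the ratio of population-mean inhalation duration to mean
cycle duration.

## Generator: the study conditions

The generator emulates a social recording session. Defaults (rat preset):

| parameter | default | rationale |
|---|---|---|
| passive / active rate | 2 / 8 Hz (bands 1–4 / 5–10) | resting vs theta sniffing |
| rate jitter | CV 0.13, AR(1) φ = 0.7 per sniff | breathing rate drifts smoothly and populates the theta band; the serial correlation is what lets instant call rates carry information about the ongoing sniff rate |
| regime dwell | exp(10 s) | block-like alternation |
| inhalation fraction | 0.33 active, 0.35 passive | theta sniffs spend ~1/3 of the cycle inhaling; resting rodent inspiratory fraction is ~0.35, which puts the *population* inhalation fraction at ~0.33 for any regime mixture |
| exhalation coupling β | 0.85 (mouse 0.32) | ms exhalation per ms ultrasound |
| exhalation noise SD | 15 ms (mouse 14 ms) | sets the regression R² near 0.35 (mouse ≈ 0.08), the realistic dispersion regime |
| call duration | 40 ± 15 ms (mouse 46 ± 15) | truncated normal, ≥ 5 ms |
| call onset jitter | 5 ± 2 ms after inhalation offset | calls begin shortly after inhalation ends |
| call probability | latent mean 0.1875 in active regime, SD 0.15, fluctuation FWHM 1.5 s | yields ~15% vocal sniffs overall; the 1.5 s timescale is what the bout analysis should recover (~12 sniffs at 8 Hz) |
| mouse bout process | enter 0.2, exit 0.45, P(call\|state) 0.92 | persistent bout states; ~40% single-call bouts with a heavy tail no smooth-rate null reproduces |
| sub-syllable gaps | Poisson(1.4)/call, 3–18 ms | reproduces the bimodal silence histogram (short within-sniff vs long across-sniff silences) |
| SNR | 12 dB over in-band noise | puts the −20 dB crosstalk copy near the detection boundary, so most calls register on one microphone only, as in real arenas |
| crosstalk | −20 dB | far-microphone attenuation |
| audio rate | 250 kHz (192 kHz fast mode) | Nyquist for 100 kHz; the fast mode still covers rat calls |
| tubing | 1st-order low-pass 40 Hz + 4 ms delay | typical ~1 m cannula tubing |

Calls longer than 90% of their available exhalation are truncated and
flagged — the mechanism by which very fast sniffing clips call durations.
Exhalation noise applies to silent sniffs too, so at β = 0 vocal and
silent exhalation-duration distributions coincide.

Vocal-sniff pressure is rendered as: inhalation half-sine, descent to a
low plateau (12% of the exhalation peak — reduced nasal airflow while the
larynx whistles), then the exhalation peak after the call offset and
return to baseline at the cycle end. Silent cycles are half-sine pairs
with inhaled/exhaled areas balanced.

**What the generator does not emulate:** call-type repertoires (trills,
steps), harmonics and echoes, microphone directivity, non-stationary
noise (bedding, movement), 22 kHz alarm calls, inter-animal answer
timing, and sniff-shape idiosyncrasies beyond the plateau motif. Passing
tests therefore validate the *algorithmic chain* — detection geometry,
segmentation, linkage, statistics — under realistic statistical structure,
not detector robustness to every acoustic nuisance in real arenas.

## Analysis conventions

- 3 s sliding windows with 0.25 s stride for vocal ratio, call rate and
  ongoing sniff rate; windows without eligible sniffs are gaps (NaN), not
  zeros. Ongoing sniff rate uses silent sniffs only.
- Sniff-rate bins: 1 Hz over 1–12 Hz; instant call rate uses calls on
  consecutive sniffs only, and pairs with the instant rate of the silent
  sniff immediately preceding the first call.
- Silences are ≥ 2 ms gaps in detected ultrasound. In the
  silence-threshold sweep, a "call" at threshold T is ultrasound merged
  across gaps < T; the two equivalence percentages are computed against
  the sniff landmarks by interval overlap.
- A detected emission crossing an inhalation onset is split there, which
  preserves the ≤ 1-call-per-sniff invariant (such events are rare,
  < 10⁻³ under defaults).
- Autocorrelations subtract the segment mean and normalize by the lag-0
  value, averaged over consecutive 3 s segments; constant segments are
  skipped (a fully constant series reports 1 by convention).
- Surrogate ensembles pool bout counts across all surrogates before
  forming probabilities; unobserved lengths get a 0.5-bout pseudocount so
  log-ratios stay finite. The Gaussian rate kernel is discretized at
  integer sniff offsets, truncated at ±3 SD, renormalized at the edges,
  and the smoothed probability is clipped to [0, 1]. One master seed
  spawns one independent stream per surrogate.

## Problem sizes

The acceptance script simulates five 270 s two-rat sessions (~2000 vocal
sniffs through the full pipeline) and five 600 s mouse sessions (~4000
vocal sniffs); the test suite uses comparable pools (four 220 s rat and
four 600 s mouse sessions) shared across tests via session-scoped
fixtures. Slope recoveries at these sizes carry standard errors of
~0.02–0.03, inside the ±0.05 recovery bands; the mouse regression needs
the larger pool because its R² is by construction low (~0.08).
Monte-Carlo bout checks use 10⁵–10⁶-element vectors with 200-surrogate
ensembles.

## Known limitations

- Caller assignment handles at most two microphones and resolves
  overlapping segments pairwise by largest overlap; three-way ambiguities
  (one segment overlapping two on the far channel) fall back to
  single-mic assignment for the leftover segment.
- Near-coincident calls from both subjects (< 20 ms apart) can merge
  across channels into a single event; at the default SNR/crosstalk this
  is rare, but it bounds recall slightly below 1 in two-subject sessions.
- The entropy detector assumes whistle-like (narrowband) calls; broadband
  or strongly harmonic vocalizations would require a different statistic.
- The deconvolution assumes a linear, time-invariant tubing response and
  shared acquisition clocks.
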