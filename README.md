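# vocalsniff

Coupled analysis of rodent ultrasonic vocalization (USV) and sniffing.

Rats and mice emit whistle-like ultrasonic calls (rats: the "50 kHz"
family, ~30–90 kHz; mice: ~50–100 kHz) while actively sniffing at theta
rates (5–10 Hz). Because ultrasound can only be produced while exhaling,
the respiratory cycle segments vocal output into discrete calls, imposes
its rhythm on call timing, and is itself deformed by calling: the
exhalation hosting a call is prolonged roughly in proportion to the call's
duration. `vocalsniff` implements the full analysis chain needed to study
this coupling from paired recordings of ultrasonic audio and intranasal
pressure, plus a synthetic-data generator that produces such recordings
with exhaustive ground truth.

## What it does

- **USV detection by spectral entropy** (`vocalsniff.detection`). A
  sliding multitaper sonogram (2 ms window, 0.25 ms step, 1 kHz bandwidth,
  3 tapers) yields, per time step, the power vector *P* over 18–100 kHz.
  After normalizing to *Pₙ*, the Shannon entropy *H = −Σ Pₙ log₂ Pₙ* is
  low for whistle-like calls and high for broadband noise. Runs of frames
  with *H* < 6.5 bits, at least 3 ms long and bounded by silences longer
  than 20 ms, become USV segments; segments with high sonic-band
  (5–18 kHz) power are rejected as noise. With two microphones (one above
  each animal), segments are assigned to the emitter: seen on one channel
  only → that animal; seen on both → the lower-entropy channel, unless the
  two frequency tracks diverge by >1 kHz for >3 ms, which means both
  animals called at once.
- **Sniff analysis** (`vocalsniff.respiration`). The tubing connecting
  the nasal cannula to the pressure sensor low-passes and delays the
  signal; its transfer function, measured once by Fourier deconvolution of
  a known broadband stimulus, is inverted to reconstruct the true
  intranasal pressure. The z-scored, inhalation-positive trace is
  segmented at threshold crossings into sniff cycles (inhalation onset →
  inhalation offset → exhalation offset), and each cycle can be warped
  onto a common phase axis in which inhalation spans [0, f] and exhalation
  [f, 1], with f the population-mean inhalation fraction.
- **Coupling statistics** (`vocalsniff.coupling`). Calls are defined
  physiologically: the ultrasound emitted within one sniff cycle. The
  module computes vocal ratio, call rate, onset/offset phase
  distributions, exhalation/inhalation-vs-call-duration regressions,
  silence-threshold segmentation sweeps, instant call rates on consecutive
  sniffs, and autocorrelations.
- **Bout statistics** (`vocalsniff.bouts`). Bouts are maximal runs of
  vocal sniffs. Observed bout-length distributions are compared against
  constant-probability surrogates and against variable-probability
  surrogates whose local call probability is the binary vocal-sniff vector
  smoothed with a Gaussian kernel of FWHM *W* sniffs, via
  log₁₀ likelihood ratios per bout length.
- **Synthetic sessions** (`vocalsniff.synthetic`). Two-state breathing
  regimes (passive ~2 Hz / active ~8 Hz), calls drawn per active sniff
  from a latent smoothly fluctuating probability (rat) or persistent
  bout-state process (mouse), exhalations prolonged by β × call duration
  (rat 0.85, mouse 0.32), FM whistle audio over noise with attenuated
  crosstalk, and tubing-distorted pressure traces — all reproducible from
  one seed.

## Worked example

```python
import pandas as pd
from vocalsniff import synthetic, workflow

cfg = synthetic.rat_config(audio_rate=synthetic.FAST_AUDIO_RATE)
session = synthetic.generate_session(cfg, duration=120.0, seed=11)
results = workflow.analyze_session(session)   # detect -> sniff -> link

res = results[0]                              # first of the two rats
print(f"sniffs: {len(res.sniffs)}, vocal: {res.sniffs.is_vocal.sum()}")
print(f"exhalation slope: {res.regression['exh_slope']:.2f}")
print(f"inhalation slope: {res.regression['inh_slope']:.2f}")
events = pd.concat([r.call_events for r in results])
rep = workflow.evaluate_against_truth(events, session)
print(f"recall {rep['recall']:.2f}, precision {rep['precision']:.2f}")
```

prints (seed 11):

```
sniffs: 614, vocal: 88
exhalation slope: 0.86
inhalation slope: -0.02
recall 1.00, precision 1.00
```

88 of 614 sniffs carry a call (≈14%, near the ~15% population figure the
generator is calibrated to). The exhalation-duration regression recovers
the generator's 0.85 ms-per-ms coupling within sampling error at this
small n (SE ≈ 0.12), while the inhalation slope stays near zero —
vocalization stretches exhalations, not inhalations. Detection against
ground truth is essentially perfect at the default 12 dB SNR.

A command-line interface mirrors the library:
`vocalsniff simulate | detect | sniff | couple | bouts | run | evaluate`.

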