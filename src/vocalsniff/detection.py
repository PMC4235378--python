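"""Ultrasonic-vocalization detection by multitaper spectral entropy.

Rodent ultrasonic vocalizations (USVs) are whistle-like, nearly pure tones:
at any instant their power is concentrated in one narrow frequency band, so
the Shannon entropy of the normalized ultrasonic power spectrum is low,
while broadband mechanical noise has high entropy.  Detection therefore
slides a short multitaper spectral estimate over the recording (2 ms
window, 0.25 ms step, 1 kHz bandwidth, 3 tapers), computes the entropy of
the normalized 18-100 kHz power vector at every step, and marks runs of
frames below a fixed entropy threshold (6.5 bits).  Runs separated by
silences of at most 20 ms are merged, runs shorter than 3 ms are dropped,
and candidate segments with high relative power in the sonic band
(5-18 kHz) are rejected as noise.

With two microphones (one over each animal), each detected USV is assigned
to its emitter: detected on one channel only -> that animal; detected on
both -> the channel with lowest entropy, unless the two frequency tracks
diverge by more than 1 kHz for more than 3 ms, in which case both animals
vocalized simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import rfft
from scipy.signal.windows import dpss

FREQ_BIN_SPACING_HZ = 500.0  # zero-padded FFT resolution of the sonogram


@dataclass
class SpectrogramParams:
    """Multitaper sonogram parameters.

    ``window * bandwidth`` is the time-bandwidth product (2 at defaults,
    consistent with 2TW-1 = 3 tapers).  Entropy is computed over
    [freq_lo, freq_hi]; power in [sonic_lo, sonic_hi] flags sonic noise.
    """

    window: float = 0.002        # s
    step: float = 0.00025        # s
    bandwidth: float = 1000.0    # Hz
    n_tapers: int = 3
    freq_lo: float = 18_000.0    # Hz
    freq_hi: float = 100_000.0   # Hz
    sonic_lo: float = 5_000.0    # Hz
    sonic_hi: float = 18_000.0   # Hz

    def __post_init__(self) -> None:
        if self.step > self.window:
            raise ValueError("step must not exceed window")
        if self.freq_lo >= self.freq_hi:
            raise ValueError("freq_lo must be below freq_hi")
        if self.n_tapers < 1:
            raise ValueError("need at least one taper")


def default_params_for(sampling_rate: float) -> SpectrogramParams:
    """Default sonogram parameters, with the analysis band top clamped
    below Nyquist (needed for the generator's 192 kHz fast-audio mode,
    where the nominal 100 kHz band edge is unattainable)."""
    p = SpectrogramParams()
    top = 0.5 * sampling_rate - 1000.0
    if p.freq_hi > top:
        p.freq_hi = top
    return p


@dataclass
class Spectrogram:
    """Per-frame summaries of the ultrasonic sonogram.

    ``power`` (frames x ultrasonic bins) is retained only when requested;
    the per-frame reductions (entropy, band powers, peak frequency) are what
    detection needs and are always present.
    """

    times: np.ndarray            # s, frame centers
    entropy: np.ndarray          # bits
    ultrasonic_power: np.ndarray  # summed power in [freq_lo, freq_hi]
    sonic_power: np.ndarray       # summed power in [sonic_lo, sonic_hi]
    peak_freq: np.ndarray         # kHz, argmax of ultrasonic power
    params: SpectrogramParams
    freqs: np.ndarray | None = None   # Hz, ultrasonic bin centers
    power: np.ndarray | None = None   # optional full ultrasonic power matrix

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def n_bins(self) -> int:
        return self.freqs.size if self.freqs is not None else 0


def spectral_entropy(power: np.ndarray, axis: int = -1) -> np.ndarray:
    """Shannon entropy (bits) of power vector(s) normalized by their sum.

    ``H = -sum(p_n * log2(p_n))`` with the convention ``0*log(0) = 0``.
    Raises on vectors that are all zero (entropy undefined) or negative.
    """
    power = np.asarray(power, dtype=float)
    if np.any(power < 0):
        raise ValueError("power must be non-negative")
    total = power.sum(axis=axis, keepdims=True)
    if np.any(total == 0):
        raise ValueError("entropy undefined for an all-zero power vector")
    p = power / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    h = -plogp.sum(axis=axis)
    return float(h) if np.ndim(h) == 0 else h


def compute_spectrogram(samples: np.ndarray, sampling_rate: float,
                        params: SpectrogramParams | None = None,
                        keep_power: bool = False,
                        chunk_frames: int = 32768) -> Spectrogram:
    """Sliding multitaper spectral estimate of one audio channel.

    One frame per ``params.step``; frame count is
    ``floor((L - window)/step) + 1`` for trace duration L.  Each window is
    tapered with ``n_tapers`` DPSS tapers (time-bandwidth product
    ``window * bandwidth``), zero-padded to 500 Hz bin spacing, and the
    taper-averaged power restricted to the ultrasonic and sonic bands.
    """
    params = params or SpectrogramParams()
    samples = np.asarray(samples)
    if sampling_rate < 2 * params.freq_hi:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz below Nyquist for "
            f"freq_hi={params.freq_hi} Hz")
    win = int(round(params.window * sampling_rate))
    if samples.size < win:
        raise ValueError("audio shorter than one analysis window")
    step = params.step * sampling_rate  # samples, possibly fractional
    n_frames = int(np.floor((samples.size - win) / step + 1e-9)) + 1
    starts = np.round(np.arange(n_frames) * step).astype(np.int64)
    starts = np.minimum(starts, samples.size - win)
    times = (starts + (win - 1) / 2) / sampling_rate

    nw = params.window * params.bandwidth
    tapers = dpss(win, NW=nw, Kmax=params.n_tapers).astype(np.float32)
    nfft = max(win, int(round(sampling_rate / FREQ_BIN_SPACING_HZ)))
    freqs = np.fft.rfftfreq(nfft, 1.0 / sampling_rate)
    band = (freqs >= params.freq_lo) & (freqs <= params.freq_hi)
    sonic = (freqs >= params.sonic_lo) & (freqs <= params.sonic_hi)
    band_freqs = freqs[band]

    x = samples.astype(np.float32, copy=False)
    offs = np.arange(win)
    entropy = np.empty(n_frames)
    upow = np.empty(n_frames)
    spow = np.empty(n_frames)
    peak = np.empty(n_frames)
    full_power = np.empty((n_frames, band.sum()), dtype=np.float32) \
        if keep_power else None
    log2 = np.log2
    for lo in range(0, n_frames, chunk_frames):
        hi = min(lo + chunk_frames, n_frames)
        frames = x[starts[lo:hi, None] + offs]          # (m, win)
        pw_band = None
        pw_sonic = None
        for k in range(params.n_tapers):
            spec = rfft(frames * tapers[k], n=nfft, axis=1)
            mag2 = spec.real ** 2 + spec.imag ** 2
            if pw_band is None:
                pw_band = mag2[:, band]
                pw_sonic = mag2[:, sonic].sum(axis=1)
            else:
                pw_band += mag2[:, band]
                pw_sonic += mag2[:, sonic].sum(axis=1)
        pw_band /= params.n_tapers
        pw_sonic /= params.n_tapers
        tot = pw_band.sum(axis=1)
        p = pw_band / tot[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -(np.where(p > 0, p * log2(np.where(p > 0, p, 1.0)),
                             0.0)).sum(axis=1)
        entropy[lo:hi] = ent
        upow[lo:hi] = tot
        spow[lo:hi] = pw_sonic
        peak[lo:hi] = band_freqs[np.argmax(pw_band, axis=1)] / 1000.0
        if keep_power:
            full_power[lo:hi] = pw_band
    return Spectrogram(times=times, entropy=entropy, ultrasonic_power=upow,
                       sonic_power=spow, peak_freq=peak, params=params,
                       freqs=band_freqs, power=full_power)


SEGMENT_COLUMNS = ["onset", "offset", "first_frame", "last_frame",
                   "mean_entropy", "sonic_ratio"]


def _runs(mask: np.ndarray) -> np.ndarray:
    """(start, stop) index pairs of maximal True runs; stop is inclusive."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=int)
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    stops = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.concatenate([[0], starts])
    if mask[-1]:
        stops = np.concatenate([stops, [mask.size - 1]])
    return np.column_stack([starts, stops])


def detect_usv_segments(spec: Spectrogram, entropy_threshold: float = 6.5,
                        min_dur: float = 0.003,
                        bounding_silence: float = 0.020) -> pd.DataFrame:
    """Candidate USV segments from below-threshold entropy runs.

    Maximal runs of frames with entropy below ``entropy_threshold`` whose
    separating gaps are at most ``bounding_silence`` are merged into one
    segment (so each segment is bounded by silences longer than that);
    merged segments whose extent (first to last below-threshold frame time)
    is shorter than ``min_dur`` are discarded.

    Returns a DataFrame with onset/offset times, the frame-index extent
    (``first_frame``..``last_frame``, inclusive), mean frame entropy and
    median sonic/ultrasonic power ratio over the extent, plus an
    ``emissions`` column holding the (onset, offset) pairs of the
    constituent below-threshold runs -- the raw ultrasound-on intervals used
    by silence analyses.
    """
    below = spec.entropy < entropy_threshold
    runs = _runs(below)
    cols = SEGMENT_COLUMNS + ["emissions"]
    if runs.size == 0:
        return pd.DataFrame(columns=cols)
    t = spec.times
    starts, stops = runs[:, 0], runs[:, 1]
    gaps = t[starts[1:]] - t[stops[:-1]]
    new_group = np.concatenate([[True], gaps > bounding_silence])
    group = np.cumsum(new_group) - 1
    rows = []
    for g in range(group[-1] + 1):
        sel = group == g
        first = starts[sel][0]
        last = stops[sel][-1]
        onset, offset = t[first], t[last]
        if offset - onset < min_dur:
            continue
        ent = spec.entropy[first:last + 1]
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = spec.sonic_power[first:last + 1] / \
                spec.ultrasonic_power[first:last + 1]
        emissions = [(t[a], t[b]) for a, b in zip(starts[sel], stops[sel])]
        rows.append((onset, offset, first, last, float(ent.mean()),
                     float(np.median(ratio)), emissions))
    return pd.DataFrame(rows, columns=cols)


def reject_sonic_noise(segments: pd.DataFrame,
                       sonic_ratio_max: float = 1.0) -> pd.DataFrame:
    """Drop segments whose median sonic/ultrasonic power ratio is high.

    Broadband noise (footsteps, bedding) has comparable power below and
    above 18 kHz; whistle-like USVs concentrate power in the ultrasonic
    band, so their ratio is far below 1.
    """
    keep = segments["sonic_ratio"] <= sonic_ratio_max
    return segments[keep].reset_index(drop=True)


CALL_COLUMNS = ["subject", "onset", "offset", "assignment_mode",
                "mean_entropy", "emissions"]


def _track_divergence_frames(spec_a: Spectrogram, spec_b: Spectrogram,
                             lo: int, hi: int, freq_divergence: float,
                             entropy_threshold: float) -> int:
    """Longest consecutive run of frames (lo..hi) where the two channels'
    peak-frequency tracks differ by more than ``freq_divergence`` kHz.

    Only frames with a defined track on *both* channels (entropy below
    threshold, i.e. tonal ultrasound present) are compared; frames inside
    sub-syllable gaps have noise-driven peak frequencies and are ignored.
    """
    da = spec_a.peak_freq[lo:hi + 1]
    db = spec_b.peak_freq[lo:hi + 1]
    tonal = ((spec_a.entropy[lo:hi + 1] < entropy_threshold) &
             (spec_b.entropy[lo:hi + 1] < entropy_threshold))
    diff = (np.abs(da - db) > freq_divergence) & tonal
    runs = _runs(diff)
    if runs.size == 0:
        return 0
    return int((runs[:, 1] - runs[:, 0] + 1).max())


def assign_caller(segments: list[pd.DataFrame], specs: list[Spectrogram],
                  subjects: list[str] | None = None,
                  freq_divergence: float = 1.0,
                  divergence_dur: float = 0.003,
                  entropy_threshold: float = 6.5) -> pd.DataFrame:
    """Assign detected segments to the emitting subject.

    ``segments``/``specs`` hold one entry per microphone channel (at most
    two); microphone *i* sits over subject *i*.  A segment with no temporal
    overlap on the far channel is assigned to its own subject
    (``single_mic``).  Overlapping segment pairs are one call heard on both
    microphones -- assigned to the channel with the lower mean frame entropy
    over the overlap (``entropy_compare``) -- unless their peak-frequency
    tracks differ by more than ``freq_divergence`` kHz for longer than
    ``divergence_dur``, in which case both subjects vocalized simultaneously
    and each keeps its own segment (``dual_caller``).

    Returns a CallEvent DataFrame sorted by onset.
    """
    if len(segments) > 2:
        raise ValueError("at most two microphone channels are supported")
    if subjects is None:
        subjects = [str(i) for i in range(len(segments))]
    if len(segments) == 1:
        df = segments[0].copy()
        out = pd.DataFrame({
            "subject": subjects[0],
            "onset": df["onset"], "offset": df["offset"],
            "assignment_mode": "single_mic",
            "mean_entropy": df["mean_entropy"],
            "emissions": df["emissions"],
        })
        return out.sort_values("onset").reset_index(drop=True)

    seg_a, seg_b = segments
    spec_a, spec_b = specs
    step = spec_a.params.step
    div_frames = int(np.ceil(divergence_dur / step))
    used_b: set[int] = set()
    rows: list[tuple] = []

    b_on = seg_b["onset"].to_numpy() if len(seg_b) else np.empty(0)
    b_off = seg_b["offset"].to_numpy() if len(seg_b) else np.empty(0)

    for ia, a in seg_a.iterrows():
        overl = np.flatnonzero((b_on < a["offset"]) & (b_off > a["onset"]))
        overl = [ib for ib in overl if ib not in used_b]
        if not overl:
            rows.append((subjects[0], a["onset"], a["offset"], "single_mic",
                         a["mean_entropy"], a["emissions"]))
            continue
        # pick the partner with the largest overlap
        ov = [min(a["offset"], b_off[ib]) - max(a["onset"], b_on[ib])
              for ib in overl]
        ib = overl[int(np.argmax(ov))]
        used_b.add(ib)
        b = seg_b.iloc[ib]
        lo = max(int(a["first_frame"]), int(b["first_frame"]))
        hi = min(int(a["last_frame"]), int(b["last_frame"]))
        run = _track_divergence_frames(spec_a, spec_b, lo, hi,
                                       freq_divergence, entropy_threshold)
        if run >= div_frames:
            rows.append((subjects[0], a["onset"], a["offset"], "dual_caller",
                         a["mean_entropy"], a["emissions"]))
            rows.append((subjects[1], b["onset"], b["offset"], "dual_caller",
                         b["mean_entropy"], b["emissions"]))
            continue
        ent_a = float(spec_a.entropy[lo:hi + 1].mean())
        ent_b = float(spec_b.entropy[lo:hi + 1].mean())
        if ent_a <= ent_b:
            rows.append((subjects[0], a["onset"], a["offset"],
                         "entropy_compare", ent_a, a["emissions"]))
        else:
            rows.append((subjects[1], b["onset"], b["offset"],
                         "entropy_compare", ent_b, b["emissions"]))
    for ib, b in seg_b.iterrows():
        if ib not in used_b:
            rows.append((subjects[1], b["onset"], b["offset"], "single_mic",
                         b["mean_entropy"], b["emissions"]))
    out = pd.DataFrame(rows, columns=CALL_COLUMNS)
    return out.sort_values("onset", kind="stable").reset_index(drop=True)


def detect_calls(channels: list[np.ndarray], sampling_rate: float,
                 subjects: list[str] | None = None,
                 params: SpectrogramParams | None = None,
                 entropy_threshold: float = 6.5, min_dur: float = 0.003,
                 bounding_silence: float = 0.020,
                 sonic_ratio_max: float = 1.0) -> pd.DataFrame:
    """Full detection chain: sonogram -> entropy segments -> noise rejection
    -> caller assignment.  Convenience wrapper used by the pipeline."""
    if params is None:
        params = default_params_for(sampling_rate)
    specs = [compute_spectrogram(ch, sampling_rate, params) for ch in channels]
    segs = [
        reject_sonic_noise(
            detect_usv_segments(s, entropy_threshold, min_dur,
                                bounding_silence),
            sonic_ratio_max)
        for s in specs
    ]
    return assign_caller(segs, specs, subjects=subjects,
                         entropy_threshold=entropy_threshold)
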