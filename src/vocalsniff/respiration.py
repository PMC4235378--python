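"""Intranasal-pressure processing: tubing deconvolution, sniff segmentation,
phase warping and ongoing-rate estimation.

A *sniff* is one respiratory cycle, running from an inhalation onset to the
onset of the next inhalation (= exhalation offset).  Landmarks are detected
on the normalized pressure trace as threshold crossings: inhalation onset at
the positive-slope crossing of a fixed threshold, inhalation offset at the
following negative-slope crossing.  Internally the sign convention is
inhalation-positive; raw sensor traces (where inhalation lowers measured
pressure) are inverted during preprocessing.

The pressure sensor is coupled to the nasal cannula through ~1 m of tubing
which low-passes and delays the true intranasal pressure.  The tubing is
characterized once by recording the same broadband signal directly and
through the tubing; the ratio of their spectra (Fourier deconvolution) gives
a complex transfer function which is then inverted, with a regularization
floor, to reconstruct the undistorted signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass
class PressureTrace:
    """A preprocessed intranasal-pressure trace.

    ``samples`` are unitless (z-scored), inhalation-positive, at
    ``sampling_rate`` Hz (nominally 1000).
    """

    samples: np.ndarray
    sampling_rate: float = 1000.0

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sampling_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass
class TransferFunction:
    """Complex gain of the cannula tubing per rFFT frequency bin.

    ``gain[i]`` multiplies the clean spectrum at ``freqs[i]`` to produce the
    distorted spectrum.  ``freqs`` spans 0..Nyquist of the trace it was
    estimated from.
    """

    freqs: np.ndarray
    gain: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("transfer function gain must be finite")

    def interpolated(self, freqs: np.ndarray) -> np.ndarray:
        """Gain resampled onto a different rFFT frequency grid."""
        re = np.interp(freqs, self.freqs, self.gain.real)
        im = np.interp(freqs, self.freqs, self.gain.imag)
        return re + 1j * im


SNIFF_COLUMNS = [
    "inh_onset",
    "inh_offset",
    "exh_offset",
    "inh_duration",
    "exh_duration",
    "instant_rate",
    "is_vocal",
]


def estimate_transfer_function(
    reference: np.ndarray,
    distorted: np.ndarray,
    sampling_rate: float = 1000.0,
    floor: float = 1e-3,
) -> TransferFunction:
    """Estimate the tubing transfer function by Fourier deconvolution.

    Parameters
    ----------
    reference, distorted
        The same broadband test signal recorded directly at the source and
        after passing through the tubing.  Must be equal length and
        time-aligned at acquisition.
    floor
        Bins where the reference spectral magnitude falls below
        ``floor * max|reference|`` are replaced by the neighboring estimate,
        bounding noise amplification.
    """
    reference = np.asarray(reference, dtype=float)
    distorted = np.asarray(distorted, dtype=float)
    if reference.shape != distorted.shape:
        raise ValueError("reference and distorted traces must be equal length")
    ref_f = np.fft.rfft(reference)
    dis_f = np.fft.rfft(distorted)
    mag = np.abs(ref_f)
    ok = mag > floor * mag.max()
    if not ok.any():
        raise ValueError("reference spectrum entirely below conditioning floor")
    gain = np.empty_like(ref_f)
    gain[ok] = dis_f[ok] / ref_f[ok]
    # fill ill-conditioned bins from the nearest well-conditioned one
    idx = np.flatnonzero(ok)
    bad = np.flatnonzero(~ok)
    if bad.size:
        nearest = idx[np.searchsorted(idx, bad).clip(0, idx.size - 1)]
        prev = idx[(np.searchsorted(idx, bad) - 1).clip(0, idx.size - 1)]
        pick = np.where(np.abs(nearest - bad) < np.abs(bad - prev), nearest, prev)
        gain[bad] = gain[pick]
    freqs = np.fft.rfftfreq(reference.size, 1.0 / sampling_rate)
    return TransferFunction(freqs=freqs, gain=gain)


def apply_transfer_function(trace: np.ndarray, tf: TransferFunction,
                            sampling_rate: float = 1000.0) -> np.ndarray:
    """Distort ``trace`` with the tubing transfer function (forward model)."""
    trace = np.asarray(trace, dtype=float)
    freqs = np.fft.rfftfreq(trace.size, 1.0 / sampling_rate)
    gain = tf.interpolated(freqs)
    return np.fft.irfft(np.fft.rfft(trace) * gain, n=trace.size)


def correct_tubing_distortion(raw: np.ndarray, tf: TransferFunction,
                              sampling_rate: float = 1000.0,
                              floor: float = 1e-3) -> np.ndarray:
    """Inverse-filter a raw trace to undo the tubing distortion.

    Bins where ``|gain|`` falls below ``floor * max|gain|`` are floored in
    magnitude (keeping phase) so the inverse filter cannot amplify noise
    without bound.
    """
    raw = np.asarray(raw, dtype=float)
    freqs = np.fft.rfftfreq(raw.size, 1.0 / sampling_rate)
    gain = tf.interpolated(freqs)
    mag = np.abs(gain)
    lo = floor * mag.max()
    if mag.max() == 0:
        raise ValueError("transfer function is identically zero")
    small = mag < lo
    safe = gain.copy()
    # floor magnitude, keep phase; zero-magnitude bins get a real floor
    phase = np.where(mag > 0, gain / np.where(mag > 0, mag, 1.0), 1.0)
    safe[small] = lo * phase[small]
    return np.fft.irfft(np.fft.rfft(raw) / safe, n=raw.size)


def preprocess(raw: np.ndarray, sampling_rate: float = 1000.0,
               invert: bool = True, drift_highpass_hz: float = 0.1,
               smooth_lowpass_hz: float | None = 400.0) -> PressureTrace:
    """Normalize a raw pressure trace for sniff segmentation.

    Slow sensor drift is removed with a zero-phase high-pass (default
    0.1 Hz), fast sensor noise optionally smoothed with a zero-phase
    low-pass, then the trace is z-scored.  With ``invert=True`` (default)
    the raw acquisition convention -- inhalation decreases measured
    pressure -- is flipped so inhalations are positive deflections.
    """
    x = np.asarray(raw, dtype=float)
    if x.size < 2 * sampling_rate:
        raise ValueError("need at least 2 s of pressure data")
    if x.std() == 0:
        raise ValueError("pressure trace has zero variance")
    if drift_highpass_hz:
        sos = sps.butter(2, drift_highpass_hz, "highpass", fs=sampling_rate,
                         output="sos")
        x = sps.sosfiltfilt(sos, x)
    if smooth_lowpass_hz and smooth_lowpass_hz < sampling_rate / 2:
        sos = sps.butter(4, smooth_lowpass_hz, "lowpass", fs=sampling_rate,
                         output="sos")
        x = sps.sosfiltfilt(sos, x)
    sd = x.std()
    if sd == 0:
        raise ValueError("pressure trace has zero variance")
    x = (x - x.mean()) / sd
    if invert:
        x = -x
    return PressureTrace(samples=x, sampling_rate=sampling_rate)


def _interp_crossing(x: np.ndarray, i: int, level: float, fs: float) -> float:
    """Sub-sample time where x crosses `level` between samples i and i+1."""
    x0, x1 = x[i], x[i + 1]
    if x1 == x0:
        return i / fs
    return (i + (level - x0) / (x1 - x0)) / fs


def _scan_crossings(x: np.ndarray, threshold: float, hysteresis: float,
                    fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Schmitt-trigger threshold-crossing scan.

    Returns interpolated times of confirmed up-crossings and down-crossings
    of ``threshold``.  An up-crossing is confirmed if the signal reaches
    ``threshold + hysteresis`` before dipping below
    ``threshold - hysteresis`` (symmetrically for down-crossings), which
    suppresses noise-induced double crossings.  Confirmed crossings strictly
    alternate.  With ``hysteresis <= 0`` this reduces to plain crossings.
    """
    up_raw = np.flatnonzero((x[:-1] < threshold) & (x[1:] >= threshold))
    down_raw = np.flatnonzero((x[:-1] >= threshold) & (x[1:] < threshold))
    if hysteresis <= 0:
        ups = np.array([_interp_crossing(x, i, threshold, fs) for i in up_raw])
        downs = np.array([_interp_crossing(x, i, threshold, fs)
                          for i in down_raw])
        return ups, downs
    hi, lo = threshold + hysteresis, threshold - hysteresis
    # precompute, for every sample, the next index reaching above hi / below lo
    above_hi = x >= hi
    below_lo = x <= lo
    n = x.size

    def next_true(mask: np.ndarray) -> np.ndarray:
        idx = np.where(mask, np.arange(n), n)
        return np.minimum.accumulate(idx[::-1])[::-1]

    nxt_hi = next_true(above_hi)
    nxt_lo = next_true(below_lo)
    events = sorted([(int(i), +1) for i in up_raw] +
                    [(int(i), -1) for i in down_raw])
    ups_i: list[int] = []
    downs_i: list[int] = []
    armed = +1 if x[0] < threshold else -1  # crossing type accepted next
    for i, kind in events:
        if kind != armed:
            continue
        # confirmation scans strictly after the crossing sample
        if kind == +1:
            confirmed = nxt_hi[i + 1] < nxt_lo[i + 1]
        else:
            confirmed = nxt_lo[i + 1] < nxt_hi[i + 1]
        if confirmed:
            (ups_i if kind == +1 else downs_i).append(i)
            armed = -kind
    ups = np.array([_interp_crossing(x, i, threshold, fs) for i in ups_i])
    downs = np.array([_interp_crossing(x, i, threshold, fs) for i in downs_i])
    return ups, downs


def segment_sniffs(trace: PressureTrace, threshold: float = 0.0,
                   hysteresis: float = 0.05,
                   min_inhalation: float = 0.020) -> pd.DataFrame:
    """Segment a preprocessed trace into sniff cycles.

    Inhalation onsets are positive-slope crossings of ``threshold`` (in SD
    units of the z-scored trace), inhalation offsets the following
    negative-slope crossings; each cycle ends at the next inhalation onset.
    Crossing times are linearly interpolated between samples.  Cycles with
    inhalation shorter than ``min_inhalation`` (aberrant) are rejected.
    ``instant_rate`` is the reciprocal of the onset-to-next-onset interval;
    the last cycle (no next onset) is dropped.

    Returns a DataFrame with columns ``inh_onset, inh_offset, exh_offset,
    inh_duration, exh_duration, instant_rate, is_vocal`` (is_vocal
    initialized to False; set by call--sniff linkage).
    """
    x = trace.samples
    fs = trace.sampling_rate
    ups, downs = _scan_crossings(x, threshold, hysteresis, fs)
    if ups.size < 2:
        return pd.DataFrame(columns=SNIFF_COLUMNS)
    rows = []
    for k in range(ups.size - 1):
        on, nxt = ups[k], ups[k + 1]
        mid = downs[(downs > on) & (downs < nxt)]
        if mid.size == 0:
            continue
        off = mid[0]
        rows.append((on, off, nxt, off - on, nxt - off, 1.0 / (nxt - on)))
    df = pd.DataFrame(rows, columns=SNIFF_COLUMNS[:-1])
    df = df[df["inh_duration"] >= min_inhalation].reset_index(drop=True)
    df["is_vocal"] = False
    return df


def mean_inhalation_fraction(sniffs: pd.DataFrame) -> float:
    """Population phase of the inhalation-to-exhalation transition.

    Mean inhalation duration over (mean inhalation + mean exhalation
    duration), across all accepted sniffs -- the warped phase assigned to
    every inhalation offset.
    """
    mi = sniffs["inh_duration"].mean()
    me = sniffs["exh_duration"].mean()
    return float(mi / (mi + me))


def sniff_phase(t, inh_onset: float, inh_offset: float, exh_offset: float,
                mean_inh_frac: float):
    """Warped phase (0-1) of time(s) ``t`` within one sniff cycle.

    Piecewise-linear morph: the inhalation maps onto [0, mean_inh_frac] and
    the exhalation onto [mean_inh_frac, 1], so cycles of different durations
    align at the three landmarks (inhalation onset = 0, inhalation offset =
    mean_inh_frac, exhalation offset = 1).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < inh_onset) or np.any(t > exh_offset):
        raise ValueError("time outside the sniff cycle")
    inh = mean_inh_frac * (t - inh_onset) / (inh_offset - inh_onset)
    exh = mean_inh_frac + (1 - mean_inh_frac) * (t - inh_offset) / (
        exh_offset - inh_offset)
    out = np.where(t <= inh_offset, np.minimum(inh, mean_inh_frac), exh)
    return float(out) if out.ndim == 0 else out


def ongoing_sniff_rate(sniffs: pd.DataFrame, window: float = 3.0,
                       stride: float = 0.25, silent_only: bool = True,
                       t_start: float | None = None,
                       t_end: float | None = None) -> pd.DataFrame:
    """Mean instant sniff rate in sliding windows.

    With ``silent_only`` (default) vocal sniffs are excluded so the estimate
    reflects the respiratory rhythm without direct vocalization effects.
    Windows containing no eligible sniff yield NaN (a gap, not zero).

    Returns a DataFrame with columns ``time`` (window center) and ``rate``.
    """
    if t_start is None:
        t_start = float(sniffs["inh_onset"].min()) if len(sniffs) else 0.0
    if t_end is None:
        t_end = float(sniffs["exh_offset"].max()) if len(sniffs) else 0.0
    centers = np.arange(t_start + window / 2, t_end - window / 2 + 1e-9, stride)
    sel = sniffs if not silent_only else sniffs[~sniffs["is_vocal"]]
    onsets = sel["inh_onset"].to_numpy()
    rates = sel["instant_rate"].to_numpy()
    order = np.argsort(onsets)
    onsets, rates = onsets[order], rates[order]
    csum = np.concatenate([[0.0], np.cumsum(rates)])
    lo = np.searchsorted(onsets, centers - window / 2)
    hi = np.searchsorted(onsets, centers + window / 2)
    n = hi - lo
    with np.errstate(invalid="ignore"):
        mean = np.where(n > 0, (csum[hi] - csum[lo]) / np.maximum(n, 1), np.nan)
    return pd.DataFrame({"time": centers, "rate": mean})
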