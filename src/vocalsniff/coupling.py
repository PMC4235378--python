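"""Call--sniff coupling statistics.

A *call* is the ultrasound emitted within a single sniff cycle, spanning
the first to the last ultrasound timepoint inside it; each sniff harbors at
most one call.  This module links detected ultrasound to segmented sniffs
and computes the coupling statistics: vocal ratio, phase locking of call
onsets/offsets to the warped sniff cycle, exhalation-prolongation
regressions, silence-threshold segmentation equivalence, rate-conditioned
call metrics and autocorrelations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .respiration import mean_inhalation_fraction, sniff_phase


def pool_emissions(call_events: pd.DataFrame) -> np.ndarray:
    """(n, 2) array of raw ultrasound-on intervals from detected events.

    Events carry their constituent below-threshold runs in an ``emissions``
    column; events without one contribute their full extent."""
    ivs: list[tuple[float, float]] = []
    for _, ev in call_events.iterrows():
        ems = ev.get("emissions")
        if isinstance(ems, (list, tuple)) and len(ems):
            ivs.extend(ems)
        else:
            ivs.append((ev["onset"], ev["offset"]))
    if not ivs:
        return np.empty((0, 2))
    arr = np.asarray(sorted(ivs))
    return arr


def merge_intervals(intervals: np.ndarray, max_gap: float = 0.0) -> np.ndarray:
    """Merge sorted intervals separated by gaps smaller than ``max_gap``."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2)
    out = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s - out[-1][1] < max_gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out)


CALL_LINK_COLUMNS = ["sniff_index", "onset", "offset", "duration"]


def link_calls_to_sniffs(call_events: pd.DataFrame, sniffs: pd.DataFrame,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool detected ultrasound into at most one call per sniff.

    All ultrasound intervals falling inside a sniff cycle
    (``inh_onset <= t < exh_offset``) form one call spanning the first to
    the last ultrasound timepoint within it; an interval crossing an
    inhalation onset is split at that landmark.  Ultrasound outside any
    sniff is excluded (orphan).  Returns ``(calls, sniffs)`` where sniffs
    has ``is_vocal`` updated.

    The returned calls table holds ``sniff_index`` (positional index into
    ``sniffs``), onset, offset and duration.
    """
    sniffs = sniffs.reset_index(drop=True).copy()
    emissions = pool_emissions(call_events)
    bounds_on = sniffs["inh_onset"].to_numpy()
    bounds_off = sniffs["exh_offset"].to_numpy()
    pieces: dict[int, list[tuple[float, float]]] = {}
    for s, e in emissions:
        # split the interval at every sniff boundary it crosses
        k = int(np.searchsorted(bounds_on, s, side="right") - 1)
        while s < e:
            if k < 0 or k >= len(sniffs):
                break
            if s >= bounds_off[k]:
                # gap between sniffs (rejected cycle): skip forward
                k = int(np.searchsorted(bounds_on, s, side="right") - 1)
                if k < 0 or s >= bounds_off[k]:
                    nxt = np.searchsorted(bounds_on, s, side="right")
                    if nxt >= len(sniffs):
                        break
                    s = bounds_on[nxt]
                    k = int(nxt)
                    continue
            cut = min(e, bounds_off[k])
            if s >= bounds_on[k] and cut > s:
                pieces.setdefault(k, []).append((s, cut))
            s = cut
            k += 1
    rows = []
    for k in sorted(pieces):
        ivs = pieces[k]
        onset = min(s for s, _ in ivs)
        offset = max(e for _, e in ivs)
        rows.append((k, onset, offset, offset - onset))
    calls = pd.DataFrame(rows, columns=CALL_LINK_COLUMNS)
    sniffs["is_vocal"] = False
    if len(calls):
        sniffs.loc[calls["sniff_index"].to_numpy(), "is_vocal"] = True
    return calls, sniffs


def vocal_ratio(call_events: pd.DataFrame, window: float = 3.0,
                stride: float = 0.25, t_start: float = 0.0,
                t_end: float | None = None) -> pd.DataFrame:
    """Fraction of time (0-1) spent producing ultrasound per sliding window.

    Independent of any call segmentation: uses raw ultrasound coverage.
    """
    ivs = merge_intervals(pool_emissions(call_events))
    if t_end is None:
        t_end = float(ivs[:, 1].max()) if len(ivs) else t_start + window
    centers = np.arange(t_start + window / 2, t_end - window / 2 + 1e-9,
                        stride)
    if len(ivs) == 0:
        return pd.DataFrame({"time": centers,
                             "vocal_ratio": np.zeros(centers.size)})
    # cumulative coverage C(t): piecewise linear between interval knots
    knots = ivs.ravel()
    cum = np.concatenate([[0.0],
                          np.cumsum((ivs[:, 1] - ivs[:, 0]))])
    cov_at_knots = np.empty(knots.size)
    cov_at_knots[0::2] = cum[:-1]   # at interval starts
    cov_at_knots[1::2] = cum[1:]    # at interval ends

    def coverage(t):
        return np.interp(t, knots, cov_at_knots,
                         left=0.0, right=cum[-1])

    ratio = (coverage(centers + window / 2) -
             coverage(centers - window / 2)) / window
    return pd.DataFrame({"time": centers, "vocal_ratio": ratio})


def phase_locking(calls: pd.DataFrame, sniffs: pd.DataFrame,
                  mean_inh_frac: float | None = None,
                  trace: np.ndarray | None = None,
                  sampling_rate: float = 1000.0,
                  n_phase: int = 200) -> dict:
    """Call onset/offset phases on the warped sniff axis, and mean warped
    pressure waveforms for vocal vs silent sniffs.

    Each sniff is morphed so its inhalation spans [0, mean_inh_frac] and
    its exhalation [mean_inh_frac, 1]; call onsets/offsets map through the
    same piecewise-linear warp.
    """
    if len(calls) == 0:
        raise ValueError("phase locking needs at least one call")
    if mean_inh_frac is None:
        mean_inh_frac = mean_inhalation_fraction(sniffs)
    onset_phases = []
    offset_phases = []
    for _, c in calls.iterrows():
        s = sniffs.iloc[int(c["sniff_index"])]
        args = (s["inh_onset"], s["inh_offset"], s["exh_offset"],
                mean_inh_frac)
        onset_phases.append(sniff_phase(
            np.clip(c["onset"], s["inh_onset"], s["exh_offset"]), *args))
        offset_phases.append(sniff_phase(
            np.clip(c["offset"], s["inh_onset"], s["exh_offset"]), *args))
    out = {
        "mean_inh_frac": float(mean_inh_frac),
        "onset_phases": np.asarray(onset_phases),
        "offset_phases": np.asarray(offset_phases),
    }
    if trace is not None:
        phase_axis = np.linspace(0.0, 1.0, n_phase)
        n_inh = max(int(round(mean_inh_frac * n_phase)), 2)
        waves = {True: [], False: []}
        t_all = np.arange(trace.size) / sampling_rate
        for _, s in sniffs.iterrows():
            seg_t_inh = np.linspace(s["inh_onset"], s["inh_offset"], n_inh)
            seg_t_exh = np.linspace(s["inh_offset"], s["exh_offset"],
                                    n_phase - n_inh)
            tt = np.concatenate([seg_t_inh, seg_t_exh])
            if tt[-1] > t_all[-1]:
                continue
            waves[bool(s["is_vocal"])].append(np.interp(tt, t_all, trace))
        out["phase_axis"] = phase_axis
        out["mean_vocal_wave"] = (np.mean(waves[True], axis=0)
                                  if waves[True] else None)
        out["mean_silent_wave"] = (np.mean(waves[False], axis=0)
                                   if waves[False] else None)
    return out


def prolongation_regression(calls: pd.DataFrame,
                            sniffs: pd.DataFrame) -> dict:
    """OLS of exhalation (and inhalation) duration on call duration.

    Slopes are dimensionless (ms exhalation per ms ultrasound).  Also
    reports the instantaneous-rate drop on vocal sniffs relative to the
    preceding silent sniff, and the corrected rate obtained after
    subtracting the vocalization duration from the vocal sniff's period.
    """
    if len(calls) < 10:
        raise ValueError("need at least 10 vocal sniffs for regression")
    idx = calls["sniff_index"].to_numpy()
    sub = sniffs.iloc[idx]
    exh = (sub["exh_offset"] - sub["inh_offset"]).to_numpy()
    inh = (sub["inh_offset"] - sub["inh_onset"]).to_numpy()
    dur = calls["duration"].to_numpy()
    if np.std(dur) == 0:
        raise ValueError("degenerate call-duration variance")
    exh_fit = stats.linregress(dur, exh)
    inh_fit = stats.linregress(dur, inh)
    cycle = (sub["exh_offset"] - sub["inh_onset"]).to_numpy()
    vocal_rate = 1.0 / cycle
    corrected_rate = 1.0 / np.maximum(cycle - dur, 1e-3)
    prev_idx = idx - 1
    valid = prev_idx >= 0
    prev = sniffs.iloc[prev_idx[valid]]
    prev_silent = ~prev["is_vocal"].to_numpy()
    preceding_rate = prev["instant_rate"].to_numpy()[prev_silent]
    return {
        "exh_slope": float(exh_fit.slope),
        "exh_intercept": float(exh_fit.intercept),
        "exh_r2": float(exh_fit.rvalue ** 2),
        "inh_slope": float(inh_fit.slope),
        "inh_r2": float(inh_fit.rvalue ** 2),
        "n_vocal": int(len(calls)),
        "mean_vocal_rate": float(vocal_rate.mean()),
        "mean_corrected_rate": float(corrected_rate.mean()),
        "mean_preceding_silent_rate": (float(preceding_rate.mean())
                                       if preceding_rate.size else np.nan),
    }


def silence_durations(call_events: pd.DataFrame,
                      min_silence: float = 0.002) -> np.ndarray:
    """Durations of silences (gaps >= ``min_silence``) between ultrasound
    emissions -- the silence-duration histogram input."""
    ivs = merge_intervals(pool_emissions(call_events), max_gap=min_silence)
    if len(ivs) < 2:
        return np.empty(0)
    gaps = ivs[1:, 0] - ivs[:-1, 1]
    return gaps[gaps >= min_silence]


def _overlapped_sniffs(onset: float, offset: float,
                       bounds_on: np.ndarray,
                       bounds_off: np.ndarray) -> np.ndarray:
    """Indices of sniff cycles a (onset, offset) span overlaps."""
    first = np.searchsorted(bounds_off, onset, side="right")
    last = np.searchsorted(bounds_on, offset, side="left") - 1
    if last < first:
        return np.empty(0, dtype=int)
    return np.arange(first, last + 1)


def silence_segmentation_sweep(call_events: pd.DataFrame,
                               sniffs: pd.DataFrame,
                               thresholds: np.ndarray | list[float],
                               ) -> pd.DataFrame:
    """Segment ultrasound by silence-duration thresholds and compare with
    the sniff-cycle segmentation.

    For each threshold T, ultrasound emissions separated by silences
    shorter than T are merged into one "call".  Reported per threshold:
    the percentage of calls that do not share a sniff cycle with another
    call, and the percentage that do not span more than one sniff cycle.
    Both reach ~100% only when T-segmentation is equivalent to segmenting
    by sniff cycle.
    """
    raw = merge_intervals(pool_emissions(call_events), max_gap=0.002)
    bounds_on = sniffs["inh_onset"].to_numpy()
    bounds_off = sniffs["exh_offset"].to_numpy()
    rows = []
    for thr in thresholds:
        segs = merge_intervals(raw, max_gap=float(thr))
        n = len(segs)
        if n == 0:
            rows.append((thr, np.nan, np.nan, 0))
            continue
        counts: dict[int, int] = {}
        spans = []
        memberships = []
        for s, e in segs:
            ov = _overlapped_sniffs(s, e, bounds_on, bounds_off)
            memberships.append(ov)
            spans.append(ov.size <= 1)
            for k in ov:
                counts[k] = counts.get(k, 0) + 1
        unique = [all(counts[k] == 1 for k in ov) if ov.size else True
                  for ov in memberships]
        rows.append((thr, 100.0 * np.mean(unique), 100.0 * np.mean(spans), n))
    return pd.DataFrame(rows, columns=["threshold", "pct_unique_per_sniff",
                                       "pct_not_spanning", "n_calls"])


def instant_call_rates(calls: pd.DataFrame,
                       sniffs: pd.DataFrame) -> pd.DataFrame:
    """Instant call rate for calls emitted on consecutive sniffs.

    The rate is the reciprocal of the interval between the onsets of the
    two calls; calls separated by a silent sniff are excluded.  Each pair
    is annotated with the instant rate of the silent sniff immediately
    preceding the first call (NaN if that sniff was vocal or absent).
    """
    if len(calls) < 2:
        return pd.DataFrame(columns=["rate", "preceding_silent_rate"])
    idx = calls["sniff_index"].to_numpy()
    onsets = calls["onset"].to_numpy()
    consecutive = idx[1:] == idx[:-1] + 1
    rates = 1.0 / (onsets[1:] - onsets[:-1])
    prev_idx = idx[:-1] - 1
    prev_rate = np.full(prev_idx.size, np.nan)
    ok = prev_idx >= 0
    prev = sniffs.iloc[prev_idx[ok]]
    silent = ~prev["is_vocal"].to_numpy()
    vals = np.where(silent, prev["instant_rate"].to_numpy(), np.nan)
    prev_rate[ok] = vals
    return pd.DataFrame({"rate": rates[consecutive],
                         "preceding_silent_rate": prev_rate[consecutive]})


def histogram_mode(values: np.ndarray, bin_width: float,
                   lo: float = 0.0) -> float:
    """Center of the most populated histogram bin."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("no values to histogram")
    hi = values.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(values, bins=edges)
    k = int(np.argmax(counts))
    return float((edges[k] + edges[k + 1]) / 2)


def rate_conditioned_metrics(calls: pd.DataFrame, sniffs: pd.DataFrame,
                             call_events: pd.DataFrame | None = None,
                             window: float = 3.0, stride: float = 0.25,
                             rate_bins: np.ndarray | None = None) -> dict:
    """Call metrics conditioned on the ongoing (silent-sniff) rate.

    Binned curves (default 1 Hz bins over 1-12 Hz) of call rate and the
    percentage of vocal sniffs against the ongoing sniff rate of the same
    3 s windows, plus per-pair instant call rates with the rate of the
    preceding silent sniff, and call duration against that rate.  Empty
    bins are NaN gaps.
    """
    from .respiration import ongoing_sniff_rate
    if rate_bins is None:
        rate_bins = np.arange(1.0, 13.0, 1.0)
    osr = ongoing_sniff_rate(sniffs, window=window, stride=stride)
    centers = osr["time"].to_numpy()
    call_onsets = calls["onset"].to_numpy()
    n_calls = (np.searchsorted(call_onsets, centers + window / 2) -
               np.searchsorted(call_onsets, centers - window / 2))
    call_rate = n_calls / window
    sniff_onsets = sniffs["inh_onset"].to_numpy()
    vocal = sniffs["is_vocal"].to_numpy().astype(float)
    cum_v = np.concatenate([[0.0], np.cumsum(vocal)])
    lo = np.searchsorted(sniff_onsets, centers - window / 2)
    hi = np.searchsorted(sniff_onsets, centers + window / 2)
    with np.errstate(invalid="ignore"):
        pct_vocal = np.where(hi > lo, 100.0 * (cum_v[hi] - cum_v[lo]) /
                             np.maximum(hi - lo, 1), np.nan)
    which = np.digitize(osr["rate"].to_numpy(), rate_bins) - 1
    n_bins = rate_bins.size - 1
    curve_rate = np.full(n_bins, np.nan)
    curve_pct = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            curve_rate[b] = np.nanmean(call_rate[sel])
            curve_pct[b] = np.nanmean(pct_vocal[sel])
    icr = instant_call_rates(calls, sniffs)
    # call duration vs instant rate of the preceding silent sniff
    idx = calls["sniff_index"].to_numpy()
    prev_idx = idx - 1
    ok = prev_idx >= 0
    prev = sniffs.iloc[prev_idx[ok]]
    silent = ~prev["is_vocal"].to_numpy()
    dur_rate = pd.DataFrame({
        "duration": calls["duration"].to_numpy()[ok][silent],
        "preceding_silent_rate": prev["instant_rate"].to_numpy()[silent],
    })
    return {
        "bin_centers": (rate_bins[:-1] + rate_bins[1:]) / 2,
        "call_rate_curve": curve_rate,
        "pct_vocal_sniffs_curve": curve_pct,
        "windows": pd.DataFrame({"time": centers,
                                 "ongoing_sniff_rate": osr["rate"],
                                 "call_rate": call_rate,
                                 "pct_vocal_sniffs": pct_vocal}),
        "instant_call_rates": icr,
        "call_duration_vs_rate": dur_rate,
    }


def segment_averaged_autocorr(x: np.ndarray, sampling_rate: float,
                              max_lag: float, segment: float = 3.0,
                              ) -> pd.DataFrame:
    """Autocorrelation averaged over consecutive segments.

    Each segment is mean-subtracted, its autocorrelation normalized by the
    zero-lag value, and the per-segment functions averaged.  Constant
    segments (zero variance) are skipped.
    """
    x = np.asarray(x, dtype=float)
    seg_n = int(round(segment * sampling_rate))
    lag_n = int(round(max_lag * sampling_rate))
    if seg_n <= lag_n:
        raise ValueError("segment must exceed max_lag")
    acfs = []
    for start in range(0, x.size - seg_n + 1, seg_n):
        seg = x[start:start + seg_n]
        seg = seg - seg.mean()
        denom = np.dot(seg, seg)
        if denom == 0:
            continue
        full = np.correlate(seg, seg, mode="full")[seg_n - 1:seg_n + lag_n]
        acfs.append(full / denom)
    if not acfs:
        # constant input: autocorrelation is identically 1 by convention
        acf = np.ones(lag_n + 1)
    else:
        acf = np.mean(acfs, axis=0)
    lags = np.arange(lag_n + 1) / sampling_rate
    return pd.DataFrame({"lag": lags, "autocorr": acf})


def presence_series(call_events: pd.DataFrame, duration: float,
                    sampling_rate: float = 1000.0) -> np.ndarray:
    """Binary ultrasound-presence series sampled at ``sampling_rate``."""
    ivs = merge_intervals(pool_emissions(call_events))
    n = int(round(duration * sampling_rate))
    out = np.zeros(n)
    for s, e in ivs:
        i0 = max(int(np.ceil(s * sampling_rate)), 0)
        i1 = min(int(np.ceil(e * sampling_rate)), n)
        out[i0:i1] = 1.0
    return out
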