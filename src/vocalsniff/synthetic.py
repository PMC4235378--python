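"""Synthetic sessions of paired ultrasonic audio and intranasal pressure.

The generator emulates the statistical structure of rodent recordings in a
social setting, with exhaustive ground truth:

* breathing alternates between passive (~2 Hz) and active-sniffing
  (~8 Hz) regimes with exponentially distributed dwell times;
* ultrasonic calls occur only during active sniffing, drawn per sniff from
  a latent call-probability process -- a smoothly fluctuating rate for rats
  (fluctuation FWHM ~1.5 s) or a persistent two-state bout process for
  mice;
* each call starts shortly after the end of the inhalation and the host
  exhalation is prolonged by ``exh_coupling_beta`` times the call duration,
  so calls always fit inside their exhalation;
* calls are whistle-like frequency-modulated tones (30-90 kHz for rats,
  50-100 kHz for mice) over broadband microphone noise, optionally broken
  by sub-syllable gaps shorter than 20 ms, with an attenuated crosstalk
  copy on the far microphone;
* intranasal pressure shows a near-sinusoidal cycle for silent sniffs and a
  near-zero-flow plateau during the call followed by the exhalation peak
  for vocal sniffs; the clean trace is additionally passed through a
  tubing transfer function (low-pass + delay) to produce the raw sensor
  signal.

All randomness flows from a single integer seed; identical configuration
and seed give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .respiration import TransferFunction, apply_transfer_function

# ---------------------------------------------------------------------------
# configuration

@dataclass
class GeneratorConfig:
    """Generator parameters.  Defaults are the rat preset; use
    :func:`mouse_config` for the mouse preset.

    Durations are seconds, rates Hz, frequencies Hz unless noted.
    """

    species: str = "rat"
    # breathing regimes
    passive_rate_mean: float = 2.0
    active_rate_mean: float = 8.0
    passive_rate_band: tuple[float, float] = (1.0, 4.0)
    active_rate_band: tuple[float, float] = (5.0, 10.0)
    rate_jitter_cv: float = 0.13
    rate_jitter_ar: float = 0.7   # sniff-to-sniff rate autocorrelation
    regime_dwell_mean: float = 10.0
    inhalation_fraction: float = 0.33          # active sniffing
    passive_inhalation_fraction: float = 0.35  # resting breathing
    # call--exhalation coupling
    exh_coupling_beta: float = 0.85      # ms exhalation per ms ultrasound
    exh_noise_sd: float = 0.015          # natural exhalation variability
    call_onset_jitter_mean: float = 0.005
    call_onset_jitter_sd: float = 0.002
    # call probability process
    call_prob_process: str = "latent"    # "latent" (rat) | "markov" (mouse)
    call_prob_mean: float = 0.1875       # mean P(call) per active sniff
    call_prob_sd: float = 0.15
    call_prob_fwhm: float = 1.5          # s, latent fluctuation FWHM
    bout_entry_prob: float = 0.2         # markov: P(enter bout state)
    bout_exit_prob: float = 0.45         # markov: P(leave bout state)
    bout_call_prob: float = 0.92         # markov: P(call | bout state)
    # call shape
    call_duration_mean: float = 0.040
    call_duration_sd: float = 0.015
    call_duration_min: float = 0.005
    subsyllable_gap_rate: float = 1.4    # mean gaps per call (Poisson)
    subsyllable_gap_range: tuple[float, float] = (0.003, 0.018)
    truncation_frac: float = 0.9         # cap: call <= frac of exhalation
    # audio
    call_freq_band: tuple[float, float] = (30_000.0, 90_000.0)
    snr_db: float = 12.0
    crosstalk_db: float = -20.0
    audio_rate: float = 250_000.0
    # pressure
    pressure_rate: float = 1000.0
    plateau_frac: float = 0.12           # |pressure| during call / exh peak
    pressure_noise_sd: float = 0.005
    tubing_fc_hz: float = 40.0           # tubing low-pass corner
    tubing_delay_s: float = 0.004        # tubing propagation delay
    n_subjects: int = 2

    def __post_init__(self) -> None:
        if min(self.passive_rate_mean, self.active_rate_mean) <= 0:
            raise ValueError("breathing rates must be positive")
        for frac in (self.inhalation_fraction,
                     self.passive_inhalation_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("inhalation fractions must lie in [0, 1]")
        if self.call_duration_mean <= 0 or self.call_duration_min <= 0:
            raise ValueError("call durations must be positive")
        if self.audio_rate < 2 * self.call_freq_band[1]:
            raise ValueError(
                f"audio rate {self.audio_rate} violates Nyquist for call "
                f"band top {self.call_freq_band[1]} Hz")
        if self.n_subjects not in (1, 2):
            raise ValueError("one or two subjects supported")


def rat_config(**overrides) -> GeneratorConfig:
    """Rat preset (the defaults)."""
    return replace(GeneratorConfig(), **overrides)


def mouse_config(**overrides) -> GeneratorConfig:
    """Mouse preset: weaker exhalation coupling, higher call band, shorter
    inhalation fraction, persistent bout-state call process, one subject
    (male; detected calls in mixed-sex recordings are attributed to him)."""
    base = GeneratorConfig(
        species="mouse",
        inhalation_fraction=0.20,
        exh_coupling_beta=0.32,
        exh_noise_sd=0.014,
        call_prob_process="markov",
        call_duration_mean=0.046,
        call_freq_band=(50_000.0, 100_000.0),
        n_subjects=1,
    )
    return replace(base, **overrides)


FAST_AUDIO_RATE = 192_000.0
"""Documented fast-audio mode: 192 kHz keeps the rat call band (30-90 kHz)
below Nyquist while reducing sample counts; analysis quantities (slopes,
rates, phases, percentages) do not depend on the audio sampling rate."""


# ---------------------------------------------------------------------------
# ground truth containers

@dataclass
class SubjectTruth:
    """Ground truth for one subject: true sniff landmarks, true calls and
    their sub-syllable emission intervals, and the per-sniff latent call
    probability."""

    sniffs: pd.DataFrame       # inh_onset, inh_offset, exh_offset, regime,
                               # rate, is_vocal
    calls: pd.DataFrame        # sniff_index, onset, offset, duration,
                               # truncated
    emissions: pd.DataFrame    # call_index, onset, offset
    call_prob: np.ndarray      # per sniff

    @property
    def n_vocal(self) -> int:
        return int(self.sniffs["is_vocal"].sum())


@dataclass
class Session:
    """One synthetic recording session."""

    config: GeneratorConfig
    duration: float
    seed: int
    subjects: list[SubjectTruth]
    audio: np.ndarray          # (n_subjects, n_samples) float32
    pressure_clean: list[np.ndarray]      # raw sign convention, per subject
    pressure_distorted: list[np.ndarray]  # after tubing transfer function
    tubing_tf: TransferFunction


# ---------------------------------------------------------------------------
# sniff train

def generate_sniff_train(config: GeneratorConfig, duration: float,
                         rng: np.random.Generator) -> pd.DataFrame:
    """Sniff landmarks with regime labels for one subject.

    Two-state semi-Markov regime switching (passive/active) with
    exponential dwell times; each cycle's rate is jittered around the
    regime mean by an AR(1) process (sniff-to-sniff rate autocorrelation
    ``rate_jitter_ar``, as in real breathing) and clipped to the regime
    band; inhalation duration is the regime's inhalation fraction times
    the cycle.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    # regime schedule covering the session
    boundaries = [0.0]
    labels = []
    state = rng.integers(2) == 1  # True = active
    while boundaries[-1] < duration:
        labels.append("active" if state else "passive")
        boundaries.append(boundaries[-1] +
                          rng.exponential(config.regime_dwell_mean))
        state = not state
    boundaries = np.asarray(boundaries)

    rows = []
    t = 0.2  # leave a flat lead-in so the first inhalation onset is visible
    seg = 0
    phi = np.clip(config.rate_jitter_ar, 0.0, 0.99)
    z = rng.standard_normal()  # normalized AR(1) jitter state
    while t < duration:
        while seg + 1 < boundaries.size - 1 and t >= boundaries[seg + 1]:
            seg += 1
        active = labels[seg] == "active"
        mean = config.active_rate_mean if active else config.passive_rate_mean
        band = config.active_rate_band if active else config.passive_rate_band
        z = phi * z + np.sqrt(1 - phi ** 2) * rng.standard_normal()
        rate = np.clip(mean * (1 + config.rate_jitter_cv * z), *band)
        cycle = 1.0 / rate
        frac = (config.inhalation_fraction if active
                else config.passive_inhalation_fraction)
        rows.append((t, t + frac * cycle, t + cycle,
                     "active" if active else "passive", rate))
        t += cycle
    df = pd.DataFrame(rows, columns=["inh_onset", "inh_offset", "exh_offset",
                                     "regime", "rate"])
    df["is_vocal"] = False
    return df


# ---------------------------------------------------------------------------
# call injection

def _latent_call_prob(sniff_onsets: np.ndarray, active: np.ndarray,
                      config: GeneratorConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Smoothly fluctuating per-sniff call probability (rat process).

    White noise on a fine time grid is smoothed with a Gaussian kernel of
    FWHM ``call_prob_fwhm`` seconds, rescaled to unit SD, then mapped to
    ``clip(mean + sd * z, 0, 1)`` and sampled at sniff onsets.  Passive
    sniffs get probability zero.
    """
    dt = 0.05
    t_max = sniff_onsets[-1] + 1.0 if sniff_onsets.size else 1.0
    grid = np.arange(0, t_max + dt, dt)
    sigma = config.call_prob_fwhm / (2 * np.sqrt(2 * np.log(2))) / dt
    half = int(np.ceil(3 * sigma))
    kern = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma) ** 2)
    kern /= kern.sum()
    z = np.convolve(rng.standard_normal(grid.size + 2 * half), kern,
                    mode="valid")[:grid.size]
    z /= np.sqrt((kern ** 2).sum())  # unit marginal SD
    p = np.clip(config.call_prob_mean +
                config.call_prob_sd * np.interp(sniff_onsets, grid, z),
                0.0, 1.0)
    p[~active] = 0.0
    return p


def _markov_call_prob(n: int, active: np.ndarray, config: GeneratorConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Persistent bout-state call probability (mouse process).

    A hidden two-state chain over sniffs: outside a bout the subject starts
    one with ``bout_entry_prob``; inside, it calls on each sniff with
    ``bout_call_prob`` and leaves with ``bout_exit_prob``.  Passive sniffs
    reset the state and get probability zero.
    """
    p = np.zeros(n)
    in_bout = False
    for i in range(n):
        if not active[i]:
            in_bout = False
            continue
        if not in_bout and rng.random() < config.bout_entry_prob:
            in_bout = True
        if in_bout:
            p[i] = config.bout_call_prob
            if rng.random() < config.bout_exit_prob:
                in_bout = False
        else:
            p[i] = 0.02
    return p


def inject_calls(train: pd.DataFrame, config: GeneratorConfig,
                 rng: np.random.Generator) -> SubjectTruth:
    """Draw calls per sniff and prolong the host exhalations.

    For a vocal sniff the exhalation becomes
    ``baseline + beta * call_duration + noise``; the inhalation is left
    untouched and all downstream landmarks shift so cycles never overlap.
    Calls longer than ``truncation_frac`` of the available exhalation are
    truncated (flagged).  Silent sniffs receive the same exhalation noise,
    so at ``beta = 0`` vocal and silent exhalation-duration distributions
    coincide.
    """
    if len(train) == 0:
        raise ValueError("sniff train is empty")
    n = len(train)
    onsets0 = train["inh_onset"].to_numpy()
    inh_dur = (train["inh_offset"] - train["inh_onset"]).to_numpy()
    exh_dur0 = (train["exh_offset"] - train["inh_offset"]).to_numpy()
    active = (train["regime"] == "active").to_numpy()

    if config.call_prob_process == "latent":
        p = _latent_call_prob(onsets0, active, config, rng)
        vocal = rng.random(n) < p
    elif config.call_prob_process == "markov":
        p = _markov_call_prob(n, active, config, rng)
        vocal = rng.random(n) < p
    else:
        raise ValueError(f"unknown call_prob_process "
                         f"{config.call_prob_process!r}")

    eps = rng.normal(0.0, config.exh_noise_sd, n)
    eps = np.clip(eps, -0.4 * exh_dur0, None)
    jit = np.clip(rng.normal(config.call_onset_jitter_mean,
                             config.call_onset_jitter_sd, n), 0.001, None)
    dur = np.clip(rng.normal(config.call_duration_mean,
                             config.call_duration_sd, n),
                  config.call_duration_min, None)

    beta = config.exh_coupling_beta
    f = config.truncation_frac
    # longest call that still fits: d <= f * (E0 + beta*d + eps - jitter)
    dmax = f * (exh_dur0 + eps - jit) / max(1.0 - f * beta, 1e-6)
    truncated = vocal & (dur > dmax)
    dur = np.where(truncated, np.maximum(dmax, config.call_duration_min), dur)
    vocal &= dur >= config.call_duration_min

    exh_dur = exh_dur0 + eps + np.where(vocal, beta * dur, 0.0)
    exh_dur = np.maximum(exh_dur, inh_dur * 0.2)  # keep cycles sane

    # rebuild landmarks with cumulative shifts; inhalations untouched
    cycles = inh_dur + exh_dur
    inh_onset = onsets0[0] + np.concatenate([[0.0], np.cumsum(cycles[:-1])])
    inh_offset = inh_onset + inh_dur
    exh_offset = inh_offset + exh_dur

    sniffs = train.copy()
    sniffs["inh_onset"] = inh_onset
    sniffs["inh_offset"] = inh_offset
    sniffs["exh_offset"] = exh_offset
    sniffs["inh_duration"] = inh_dur
    sniffs["exh_duration"] = exh_dur
    sniffs["instant_rate"] = 1.0 / cycles
    sniffs["is_vocal"] = vocal

    call_rows = []
    emission_rows = []
    vocal_idx = np.flatnonzero(vocal)
    lo_gap, hi_gap = config.subsyllable_gap_range
    for ci, i in enumerate(vocal_idx):
        onset = inh_offset[i] + jit[i]
        d = dur[i]
        offset = onset + d
        call_rows.append((i, onset, offset, d, bool(truncated[i])))
        # sub-syllable gaps: brief (<20 ms) silences inside the emission
        max_gaps = int((d - 0.004) // 0.010)
        n_gaps = min(rng.poisson(config.subsyllable_gap_rate), max_gaps) \
            if config.subsyllable_gap_rate > 0 else 0
        if n_gaps <= 0:
            emission_rows.append((ci, onset, offset))
            continue
        # place gap centers with minimum spacing by jittering a regular grid
        centers = (np.arange(1, n_gaps + 1) / (n_gaps + 1) * d
                   + rng.uniform(-0.15, 0.15, n_gaps) * d / (n_gaps + 1))
        cursor = onset
        for c in np.sort(centers):
            g = rng.uniform(lo_gap, min(hi_gap, d / (2 * n_gaps)))
            g_start = onset + c - g / 2
            g_end = g_start + g
            if g_start - cursor >= 0.002 and offset - g_end >= 0.002:
                emission_rows.append((ci, cursor, g_start))
                cursor = g_end
        emission_rows.append((ci, cursor, offset))
    calls = pd.DataFrame(call_rows, columns=["sniff_index", "onset", "offset",
                                             "duration", "truncated"])
    emissions = pd.DataFrame(emission_rows,
                             columns=["call_index", "onset", "offset"])
    return SubjectTruth(sniffs=sniffs, calls=calls, emissions=emissions,
                        call_prob=p)


def _trim_truth(subject: SubjectTruth, duration: float) -> SubjectTruth:
    """Drop sniffs (and their calls) not fully inside the rendered session.

    Exhalation prolongation shifts late landmarks past the nominal session
    end; those cycles are not rendered and cannot be recovered."""
    keep = subject.sniffs["exh_offset"] <= duration
    sniffs = subject.sniffs[keep].reset_index(drop=False)
    n_keep = len(sniffs)
    calls = subject.calls[subject.calls["sniff_index"] < n_keep]
    calls = calls.reset_index(drop=True)
    emissions = subject.emissions[
        subject.emissions["call_index"] < len(calls)].reset_index(drop=True)
    sniffs = sniffs.drop(columns=["index"])
    return SubjectTruth(sniffs=sniffs, calls=calls, emissions=emissions,
                        call_prob=subject.call_prob[:n_keep])


# ---------------------------------------------------------------------------
# audio synthesis

def _fm_contour(duration: float, band: tuple[float, float],
                rng: np.random.Generator):
    """Random smooth frequency-modulation contour within the call band.

    A cubic spline through a few control points drawn around a random
    center frequency, clipped to the band; returns a callable f(t)."""
    lo, hi = band
    margin = 0.1 * (hi - lo)
    f0 = rng.uniform(lo + margin, hi - margin)
    n_ctrl = max(3, int(duration / 0.015) + 2)
    tk = np.linspace(0.0, duration, n_ctrl)
    fk = np.clip(f0 + rng.normal(0.0, 0.06 * (hi - lo), n_ctrl),
                 lo + 1000, hi - 1000)
    return CubicSpline(tk, fk, bc_type="natural")


def synthesize_audio(subjects: list[SubjectTruth], config: GeneratorConfig,
                     duration: float, rng: np.random.Generator) -> np.ndarray:
    """Render two-channel (one per subject) ultrasonic audio.

    Each emission interval becomes a frequency-modulated tone at
    ``snr_db`` (power relative to the broadband-noise power inside the
    18-100 kHz analysis band) on the subject's own microphone, plus a
    ``crosstalk_db``-attenuated copy on the far microphone.  Raised-cosine
    amplitude ramps (1 ms) avoid onset/offset clicks.
    """
    fs = config.audio_rate
    if fs < 2 * config.call_freq_band[1]:
        raise ValueError("audio sampling rate violates Nyquist for call band")
    n = int(round(duration * fs))
    n_ch = len(subjects)
    audio = np.empty((n_ch, n), dtype=np.float32)
    for ch in range(n_ch):
        audio[ch] = rng.standard_normal(n).astype(np.float32)
    # tone amplitude for the requested SNR over in-band noise power
    band_power = (100_000.0 - 18_000.0) / (fs / 2)  # unit-variance noise
    amp = np.sqrt(2 * 10 ** (config.snr_db / 10) * band_power)
    xtalk = 10 ** (config.crosstalk_db / 20) \
        if np.isfinite(config.crosstalk_db) else 0.0

    for ch, subj in enumerate(subjects):
        for ci, call in subj.calls.iterrows():
            contour = _fm_contour(call["duration"], config.call_freq_band, rng)
            ems = subj.emissions[subj.emissions["call_index"] == ci]
            for _, em in ems.iterrows():
                i0 = int(round(em["onset"] * fs))
                i1 = min(int(round(em["offset"] * fs)), n)
                if i1 - i0 < 8:
                    continue
                t = np.arange(i0, i1) / fs
                freq = np.clip(contour(t - call["onset"]),
                               config.call_freq_band[0],
                               min(config.call_freq_band[1], 0.45 * fs))
                phase = 2 * np.pi * np.cumsum(freq) / fs
                tone = np.sin(phase + rng.uniform(0, 2 * np.pi))
                m = i1 - i0
                ramp_n = min(int(0.001 * fs), m // 3)
                env = np.ones(m)
                if ramp_n > 0:
                    r = 0.5 * (1 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
                    env[:ramp_n] = r
                    env[-ramp_n:] = r[::-1]
                tone = (amp * env * tone).astype(np.float32)
                audio[ch, i0:i1] += tone
                if n_ch == 2 and xtalk > 0:
                    audio[1 - ch, i0:i1] += xtalk * tone
    return audio


# ---------------------------------------------------------------------------
# pressure synthesis

def make_tubing_tf(config: GeneratorConfig,
                   n_freqs: int = 4097) -> TransferFunction:
    """Analytic tubing transfer function: first-order low-pass at
    ``tubing_fc_hz`` plus a pure delay of ``tubing_delay_s``, on a dense
    0-500 Hz grid."""
    freqs = np.linspace(0.0, config.pressure_rate / 2, n_freqs)
    gain = np.exp(-2j * np.pi * freqs * config.tubing_delay_s) / (
        1.0 + 1j * freqs / config.tubing_fc_hz)
    return TransferFunction(freqs=freqs, gain=gain)


def identity_tf(sampling_rate: float = 1000.0,
                n_freqs: int = 4097) -> TransferFunction:
    """Unity-gain, zero-phase transfer function (no tubing distortion)."""
    freqs = np.linspace(0.0, sampling_rate / 2, n_freqs)
    return TransferFunction(freqs=freqs, gain=np.ones(n_freqs, dtype=complex))


def synthesize_pressure(subject: SubjectTruth, config: GeneratorConfig,
                        duration: float, rng: np.random.Generator,
                        tf: TransferFunction | None = None,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Render one subject's intranasal pressure at ``pressure_rate``.

    Returns ``(clean, distorted)`` in the raw acquisition sign convention
    (inhalation = decrease in measured pressure).  Silent sniffs are
    near-sinusoidal with inhaled and exhaled areas balanced; vocal sniffs
    hold a near-zero-flow plateau (``plateau_frac`` of the exhalation peak)
    for the duration of the call, then release the exhalation peak, so the
    peak always falls after the call offset.  ``distorted`` is the clean
    trace passed through the tubing transfer function.
    """
    fs = config.pressure_rate
    n = int(round(duration * fs))
    y = np.zeros(n)  # inhalation-positive while rendering
    sn = subject.sniffs
    calls = subject.calls.set_index("sniff_index") if len(subject.calls) \
        else None
    for i, row in sn.iterrows():
        on, off, end = row["inh_onset"], row["inh_offset"], row["exh_offset"]
        i0, i1 = int(np.ceil(on * fs)), min(int(np.ceil(off * fs)), n)
        i2 = min(int(np.ceil(end * fs)), n)
        if i0 >= n:
            break
        t_inh = np.arange(i0, i1) / fs
        ti = max(off - on, 1e-3)
        y[i0:i1] = np.sin(np.pi * (t_inh - on) / ti)
        te = max(end - off, 1e-3)
        a_exh = ti / te  # balances inhaled/exhaled areas for a half-sine
        if row["is_vocal"] and calls is not None and i in calls.index:
            c = calls.loc[i]
            c_on, c_off = float(c["onset"]), float(c["offset"])
            p = config.plateau_frac * max(a_exh, 0.3)
            a_v = max(a_exh, 0.3)
            # descend to the plateau before the call
            j0, j1 = i1, min(int(np.ceil(c_on * fs)), n)
            if j1 > j0:
                tt = (np.arange(j0, j1) / fs - off) / max(c_on - off, 1e-3)
                y[j0:j1] = -p * np.sin(0.5 * np.pi * np.clip(tt, 0, 1))
            # plateau while the call is produced
            k0, k1 = j1, min(int(np.ceil(c_off * fs)), n)
            y[k0:k1] = -p
            # exhalation peak after the call, returning to zero at cycle end
            r0, r1 = k1, i2
            if r1 > r0:
                rr = max(end - c_off, 1e-3)
                tt = (np.arange(r0, r1) / fs - c_off) / rr
                y[r0:r1] = -a_v * np.sin(np.pi * np.clip(tt, 0, 1)) \
                    - p * (1 - np.clip(tt, 0, 1))
        else:
            t_exh = np.arange(i1, i2) / fs
            y[i1:i2] = -a_exh * np.sin(np.pi * (t_exh - off) / te)
    y += rng.normal(0.0, config.pressure_noise_sd, n)
    clean = -y  # raw convention: inhalation lowers measured pressure
    if tf is None:
        tf = make_tubing_tf(config)
    distorted = apply_transfer_function(clean, tf, sampling_rate=fs)
    return clean, distorted


# ---------------------------------------------------------------------------
# session assembly

def generate_session(config: GeneratorConfig, duration: float,
                     seed: int) -> Session:
    """Generate one full session: per-subject ground truth, two-channel
    audio and per-subject pressure traces, deterministically from ``seed``."""
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(2 * config.n_subjects + 1)
    subjects = []
    for s in range(config.n_subjects):
        rng = np.random.default_rng(streams[s])
        train = generate_sniff_train(config, duration, rng)
        subjects.append(_trim_truth(inject_calls(train, config, rng),
                                    duration))
    rng_audio = np.random.default_rng(streams[config.n_subjects])
    audio = synthesize_audio(subjects, config, duration, rng_audio)
    tf = make_tubing_tf(config)
    clean_list, dist_list = [], []
    for s, subj in enumerate(subjects):
        rng_p = np.random.default_rng(streams[config.n_subjects + 1 + s])
        clean, dist = synthesize_pressure(subj, config, duration, rng_p, tf)
        clean_list.append(clean)
        dist_list.append(dist)
    return Session(config=config, duration=duration, seed=seed,
                   subjects=subjects, audio=audio,
                   pressure_clean=clean_list, pressure_distorted=dist_list,
                   tubing_tf=tf)


# ---------------------------------------------------------------------------
# flat key-value config files

def config_to_text(config: GeneratorConfig) -> str:
    lines = []
    for key, val in asdict(config).items():
        if isinstance(val, tuple):
            val = ",".join(str(v) for v in val)
        lines.append(f"{key} = {val}")
    return "\n".join(lines) + "\n"


def config_from_text(text: str) -> GeneratorConfig:
    """Parse a flat ``key = value`` config file (comments with '#')."""
    fields = {f.name: f.type for f in
              GeneratorConfig.__dataclass_fields__.values()}
    kwargs = {}
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, raw = line.partition("=")
        key, raw = key.strip(), raw.strip()
        if key not in fields:
            raise ValueError(f"unknown config key {key!r}")
        default = getattr(GeneratorConfig(), key)
        if isinstance(default, tuple):
            kwargs[key] = tuple(float(v) for v in raw.split(","))
        elif isinstance(default, bool):
            kwargs[key] = raw.lower() in ("1", "true", "yes")
        elif isinstance(default, int) and not isinstance(default, bool):
            kwargs[key] = int(raw)
        elif isinstance(default, float):
            kwargs[key] = float(raw)
        else:
            kwargs[key] = raw
    return GeneratorConfig(**kwargs)
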