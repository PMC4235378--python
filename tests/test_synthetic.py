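"""Synthetic-data generator: sniff trains, call injection, audio and
pressure rendering, reproducibility and calibration."""

import numpy as np
import pytest
from scipy import stats

from vocalsniff import detection, synthetic
from vocalsniff.synthetic import (GeneratorConfig, generate_session,
                                  generate_sniff_train, inject_calls,
                                  mouse_config, rat_config,
                                  synthesize_pressure, make_tubing_tf,
                                  identity_tf)


def _active_only(**kw):
    """Config pinned to a single 8 Hz regime with no rate jitter."""
    base = dict(active_rate_mean=8.0, passive_rate_mean=8.0,
                active_rate_band=(8.0, 8.0), passive_rate_band=(8.0, 8.0),
                rate_jitter_cv=0.0, passive_inhalation_fraction=0.33,
                regime_dwell_mean=1.0)  # both regimes visited quickly
    base.update(kw)
    return rat_config(**base)


class TestSniffTrain:
    def test_fixed_rate_gives_reciprocal_cycles(self):
        cfg = _active_only()
        train = generate_sniff_train(cfg, 20.0, np.random.default_rng(0))
        cycles = (train["exh_offset"] - train["inh_onset"]).to_numpy()
        assert np.allclose(cycles, 0.125)

    def test_inhalation_fraction_product(self):
        cfg = _active_only(active_rate_mean=1 / 0.120,
                           passive_rate_mean=1 / 0.120,
                           active_rate_band=(1 / 0.120, 1 / 0.120),
                           passive_rate_band=(1 / 0.120, 1 / 0.120))
        train = generate_sniff_train(cfg, 20.0, np.random.default_rng(0))
        inh = (train["inh_offset"] - train["inh_onset"]).to_numpy()
        assert np.allclose(inh, 0.33 * 0.120, atol=1e-9)

    def test_landmarks_strictly_increasing(self):
        cfg = rat_config()
        train = generate_sniff_train(cfg, 60.0, np.random.default_rng(1))
        landmarks = np.column_stack([train["inh_onset"], train["inh_offset"],
                                     train["exh_offset"]]).ravel()
        assert np.all(np.diff(landmarks) > -1e-12)

    def test_regime_dwell_matches_exponential_mean(self):
        """Empirical mean dwell within 10% of regime_dwell_mean."""
        cfg = rat_config()
        rng = np.random.default_rng(2)
        train = generate_sniff_train(cfg, 6000.0, rng)
        regimes = train["regime"].to_numpy()
        onsets = train["inh_onset"].to_numpy()
        switch = np.flatnonzero(regimes[1:] != regimes[:-1])
        dwell = np.diff(onsets[switch])
        assert dwell.mean() == pytest.approx(cfg.regime_dwell_mean, rel=0.10)

    def test_non_positive_duration_rejected(self):
        with pytest.raises(ValueError):
            generate_sniff_train(rat_config(), 0.0,
                                 np.random.default_rng(0))


class TestInjectCalls:
    def test_exhalation_prolonged_by_beta_times_duration(self):
        """Deterministic check: beta=0.85, 40 ms call, 84 ms baseline
        exhalation -> 118 ms exhalation."""
        cfg = _active_only(exh_noise_sd=0.0, call_onset_jitter_sd=0.0,
                           call_duration_sd=0.0, call_duration_mean=0.040,
                           call_prob_mean=1.0, call_prob_sd=0.0,
                           subsyllable_gap_rate=0.0)
        rng = np.random.default_rng(0)
        train = generate_sniff_train(cfg, 5.0, rng)
        subj = inject_calls(train, cfg, rng)
        vocal = subj.sniffs[subj.sniffs["is_vocal"]]
        exh = (vocal["exh_offset"] - vocal["inh_offset"]).to_numpy()
        baseline = 0.125 * (1 - 0.33)
        assert np.allclose(exh, baseline + 0.85 * 0.040, atol=1e-9)

    def test_zero_beta_leaves_exhalations_identical(self):
        cfg = _active_only(exh_coupling_beta=0.0, call_prob_mean=0.5,
                           call_prob_sd=0.0)
        rng = np.random.default_rng(1)
        train = generate_sniff_train(cfg, 400.0, rng)
        subj = inject_calls(train, cfg, rng)
        s = subj.sniffs
        exh = (s["exh_offset"] - s["inh_offset"]).to_numpy()
        vocal = s["is_vocal"].to_numpy()
        ks = stats.ks_2samp(exh[vocal], exh[~vocal])
        assert ks.pvalue > 0.01

    def test_constant_probability_vocal_fraction(self):
        """With a constant latent probability p the vocal fraction is a
        binomial draw around p."""
        p = 0.3
        cfg = _active_only(call_prob_mean=p, call_prob_sd=0.0)
        rng = np.random.default_rng(2)
        train = generate_sniff_train(cfg, 600.0, rng)
        subj = inject_calls(train, cfg, rng)
        active = subj.sniffs[subj.sniffs["regime"] == "active"]
        n = len(active)
        frac = active["is_vocal"].mean()
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / n)

    def test_calls_conserved_and_inside_exhalation(self):
        """One call per vocal sniff; every call starts after the
        inhalation offset and ends before the exhalation offset."""
        cfg = rat_config()
        rng = np.random.default_rng(3)
        train = generate_sniff_train(cfg, 300.0, rng)
        subj = inject_calls(train, cfg, rng)
        assert len(subj.calls) == subj.sniffs["is_vocal"].sum()
        s = subj.sniffs
        for _, c in subj.calls.iterrows():
            row = s.iloc[int(c["sniff_index"])]
            assert c["onset"] > row["inh_offset"]
            assert c["offset"] < row["exh_offset"] + 1e-12

    def test_oversized_call_truncated_and_flagged(self):
        cfg = _active_only(call_duration_mean=0.500, call_duration_sd=0.0,
                           call_prob_mean=1.0, call_prob_sd=0.0,
                           exh_noise_sd=0.0)
        rng = np.random.default_rng(4)
        train = generate_sniff_train(cfg, 5.0, rng)
        subj = inject_calls(train, cfg, rng)
        assert subj.calls["truncated"].all()
        s = subj.sniffs
        for _, c in subj.calls.iterrows():
            row = s.iloc[int(c["sniff_index"])]
            avail = row["exh_offset"] - c["onset"]
            assert c["duration"] <= 0.9 * (row["exh_offset"] -
                                           row["inh_offset"]) + 1e-9
            assert c["offset"] <= row["exh_offset"] + 1e-9

    def test_subsyllable_gaps_short_and_inside_call(self):
        cfg = rat_config()
        rng = np.random.default_rng(5)
        train = generate_sniff_train(cfg, 300.0, rng)
        subj = inject_calls(train, cfg, rng)
        for ci, grp in subj.emissions.groupby("call_index"):
            call = subj.calls.iloc[int(ci)]
            assert grp["onset"].iloc[0] == pytest.approx(call["onset"])
            assert grp["offset"].iloc[-1] == pytest.approx(call["offset"])
            gaps = (grp["onset"].to_numpy()[1:] -
                    grp["offset"].to_numpy()[:-1])
            assert np.all(gaps > 0)
            assert np.all(gaps < 0.020)

    def test_beta_recovery_within_tolerance(self):
        """Regressing true exhalation durations on true call durations
        recovers the coupling slope within +/-0.03 at n >= 1000."""
        cfg = rat_config()
        rng = np.random.default_rng(6)
        train = generate_sniff_train(cfg, 5000.0, rng)
        subj = inject_calls(train, cfg, rng)
        assert len(subj.calls) >= 1000
        s = subj.sniffs
        exh = (s["exh_offset"] - s["inh_offset"]).to_numpy()[
            subj.calls["sniff_index"]]
        fit = stats.linregress(subj.calls["duration"], exh)
        assert fit.slope == pytest.approx(cfg.exh_coupling_beta, abs=0.03)


class TestAudio:
    def test_call_peak_frequency_inside_band(self):
        cfg = _active_only(call_prob_mean=1.0, call_prob_sd=0.0,
                           call_duration_mean=0.050, call_duration_sd=0.0,
                           subsyllable_gap_rate=0.0,
                           audio_rate=synthetic.FAST_AUDIO_RATE,
                           n_subjects=1)
        sess = generate_session(cfg, 3.0, seed=0)
        params = detection.default_params_for(cfg.audio_rate)
        spec = detection.compute_spectrogram(sess.audio[0], cfg.audio_rate,
                                             params)
        call = sess.subjects[0].calls.iloc[0]
        inside = (spec.times >= call["onset"] + 0.002) & \
                 (spec.times <= call["offset"] - 0.002)
        peaks = spec.peak_freq[inside] * 1000
        assert np.all(peaks >= cfg.call_freq_band[0] - 1000)
        assert np.all(peaks <= cfg.call_freq_band[1] + 1000)

    def test_infinite_crosstalk_attenuation_leaves_noise(self):
        cfg = _active_only(crosstalk_db=-np.inf,
                           audio_rate=synthetic.FAST_AUDIO_RATE)
        sess = generate_session(cfg, 3.0, seed=1)
        subj0 = sess.subjects[0]
        # far channel (1) inside subject-0 calls must look like pure noise
        fs = cfg.audio_rate
        for _, c in subj0.calls.iterrows():
            i0, i1 = int(c["onset"] * fs), int(c["offset"] * fs)
            seg = sess.audio[1, i0:i1]
            own = sess.audio[0, i0:i1]
            if seg.size < 100:
                continue
            # far channel stays at the unit noise floor, own channel well
            # above it
            assert seg.std() == pytest.approx(1.0, abs=0.1)
            assert own.std() > 1.5

    def test_band_energy_rise_matches_snr(self):
        """In-band power during calls vs silence differs by ~snr_db."""
        cfg = _active_only(call_prob_mean=1.0, call_prob_sd=0.0,
                           subsyllable_gap_rate=0.0, snr_db=15.0,
                           audio_rate=synthetic.FAST_AUDIO_RATE,
                           n_subjects=1)
        sess = generate_session(cfg, 5.0, seed=2)
        fs = cfg.audio_rate
        sos_band = None
        from scipy import signal as sps
        sos_band = sps.butter(6, [18_000, 90_000], "bandpass", fs=fs,
                              output="sos")
        x = sps.sosfiltfilt(sos_band, sess.audio[0])
        mask = np.zeros(x.size, dtype=bool)
        for _, c in sess.subjects[0].calls.iterrows():
            i0 = int((c["onset"] + 0.003) * fs)
            i1 = int((c["offset"] - 0.003) * fs)
            mask[i0:i1] = True
        p_call = np.mean(x[mask] ** 2)
        p_silence = np.mean(x[~mask] ** 2)
        gain_db = 10 * np.log10(p_call / p_silence - 1.0)
        assert gain_db == pytest.approx(15.0, abs=2.0)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError):
            rat_config(audio_rate=100_000.0)


class TestPressure:
    def test_silent_train_periodicity(self):
        """A silent 8 Hz train has its first autocorrelation peak near
        125 ms."""
        cfg = _active_only(call_prob_mean=0.0, call_prob_sd=0.0,
                           exh_noise_sd=0.0, pressure_noise_sd=0.0)
        rng = np.random.default_rng(0)
        train = generate_sniff_train(cfg, 20.0, rng)
        subj = inject_calls(train, cfg, rng)
        clean, _ = synthesize_pressure(subj, cfg, 20.0,
                                       np.random.default_rng(1),
                                       tf=identity_tf())
        x = clean - clean.mean()
        acf = np.correlate(x, x, mode="full")[x.size - 1:]
        acf /= acf[0]
        # first local maximum after the initial dip
        lag = np.argmax(acf[60:200]) + 60
        assert abs(lag - 125) <= 5

    def test_identity_tf_keeps_trace(self):
        cfg = rat_config()
        rng = np.random.default_rng(2)
        train = generate_sniff_train(cfg, 10.0, rng)
        subj = inject_calls(train, cfg, rng)
        clean, distorted = synthesize_pressure(subj, cfg, 10.0,
                                               np.random.default_rng(3),
                                               tf=identity_tf())
        assert np.allclose(clean, distorted, atol=1e-9)

    def test_call_plateau_is_low_flow(self):
        """|relative pressure| during the call stays below 20% of the
        exhalation peak."""
        cfg = _active_only(call_prob_mean=1.0, call_prob_sd=0.0,
                           pressure_noise_sd=0.0, subsyllable_gap_rate=0.0)
        rng = np.random.default_rng(4)
        train = generate_sniff_train(cfg, 10.0, rng)
        subj = inject_calls(train, cfg, rng)
        clean, _ = synthesize_pressure(subj, cfg, 10.0,
                                       np.random.default_rng(5),
                                       tf=identity_tf())
        fs = cfg.pressure_rate
        for _, c in subj.calls.iterrows():
            row = subj.sniffs.iloc[int(c["sniff_index"])]
            if c["truncated"] or row["exh_offset"] > 10.0 - 0.002:
                continue  # clipped release never reaches the full peak
            plateau = np.abs(clean[int(c["onset"] * fs) + 2:
                                   int(c["offset"] * fs) - 1])
            release = np.abs(clean[int(c["offset"] * fs):
                                   int(row["exh_offset"] * fs)])
            if plateau.size == 0 or release.size == 0:
                continue  # call truncated at the rendered session edge
            assert plateau.max() < 0.2 * release.max()

    def test_raw_sign_convention(self):
        """Inhalations decrease the raw measured pressure."""
        cfg = _active_only(call_prob_mean=0.0, pressure_noise_sd=0.0)
        rng = np.random.default_rng(6)
        train = generate_sniff_train(cfg, 5.0, rng)
        subj = inject_calls(train, cfg, rng)
        clean, _ = synthesize_pressure(subj, cfg, 5.0,
                                       np.random.default_rng(7),
                                       tf=identity_tf())
        row = subj.sniffs.iloc[2]
        fs = cfg.pressure_rate
        inh = clean[int(row["inh_onset"] * fs) + 1:
                    int(row["inh_offset"] * fs) - 1]
        assert inh.mean() < 0


class TestReproducibility:
    def test_same_seed_bit_identical(self):
        cfg = rat_config(audio_rate=synthetic.FAST_AUDIO_RATE)
        a = generate_session(cfg, 5.0, seed=42)
        b = generate_session(cfg, 5.0, seed=42)
        assert np.array_equal(a.audio, b.audio)
        assert np.array_equal(a.pressure_clean[0], b.pressure_clean[0])
        assert a.subjects[0].sniffs.equals(b.subjects[0].sniffs)
        assert a.subjects[0].calls.equals(b.subjects[0].calls)

    def test_different_seeds_differ(self):
        cfg = rat_config(audio_rate=synthetic.FAST_AUDIO_RATE)
        a = generate_session(cfg, 5.0, seed=1)
        b = generate_session(cfg, 5.0, seed=2)
        assert not np.array_equal(a.audio, b.audio)


class TestConfig:
    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(active_rate_mean=-1.0)
        with pytest.raises(ValueError):
            GeneratorConfig(inhalation_fraction=1.5)
        with pytest.raises(ValueError):
            GeneratorConfig(n_subjects=3)

    def test_text_round_trip(self):
        cfg = mouse_config(snr_db=17.5)
        text = synthetic.config_to_text(cfg)
        back = synthetic.config_from_text(text)
        assert back == cfg

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError):
            synthetic.config_from_text("no_such_key = 3\n")
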