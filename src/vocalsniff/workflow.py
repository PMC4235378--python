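"""End-to-end orchestration: run the detection -> sniff -> coupling -> bout
chain on a session (in memory or from files) and validate detections
against synthetic ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, bouts, coupling, detection, respiration
from .synthetic import Session


@dataclass
class SessionManifest:
    """Paths and metadata locating one recorded (or simulated) session."""

    subjects: list[str]
    audio_paths: list[str]
    pressure_paths: list[str]
    species: str = "rat"
    tf_path: str | None = None
    seed: int = 0

    def validate(self) -> None:
        if len(self.audio_paths) not in (1, 2):
            raise ValueError("manifest needs one or two audio channels")
        if len(self.pressure_paths) != len(self.subjects):
            raise ValueError("one pressure file per subject required")
        for p in [*self.audio_paths, *self.pressure_paths] + (
                [self.tf_path] if self.tf_path else []):
            if not Path(p).exists():
                raise FileNotFoundError(f"manifest references missing file {p}")


@dataclass
class SubjectResult:
    """Per-subject analysis products."""

    sniffs: pd.DataFrame
    calls: pd.DataFrame
    call_events: pd.DataFrame
    regression: dict | None = None
    phases: dict | None = None


def analyze_subject(call_events: pd.DataFrame, pressure_raw: np.ndarray,
                    pressure_rate: float = 1000.0,
                    tf: respiration.TransferFunction | None = None,
                    min_vocal_for_stats: int = 10) -> SubjectResult:
    """Sniff segmentation + call linkage + coupling statistics for one
    subject.  ``pressure_raw`` is in the acquisition sign convention; the
    tubing transfer function, when given, is inverted first."""
    x = pressure_raw
    if tf is not None:
        x = respiration.correct_tubing_distortion(x, tf,
                                                  sampling_rate=pressure_rate)
    trace = respiration.preprocess(x, sampling_rate=pressure_rate)
    sniffs = respiration.segment_sniffs(trace)
    calls, sniffs = coupling.link_calls_to_sniffs(call_events, sniffs)
    regression = None
    phases = None
    if len(calls) >= min_vocal_for_stats:
        regression = coupling.prolongation_regression(calls, sniffs)
        phases = coupling.phase_locking(calls, sniffs)
    return SubjectResult(sniffs=sniffs, calls=calls, call_events=call_events,
                         regression=regression, phases=phases)


def analyze_session(session: Session) -> list[SubjectResult]:
    """Full in-memory pipeline on a synthetic session: detect calls on all
    channels, assign callers, then per-subject sniff analysis."""
    cfg = session.config
    subjects = [str(s) for s in range(cfg.n_subjects)]
    events = detection.detect_calls(
        [session.audio[ch] for ch in range(cfg.n_subjects)],
        cfg.audio_rate, subjects=subjects)
    results = []
    for s in range(cfg.n_subjects):
        ev = events[events["subject"] == subjects[s]].reset_index(drop=True)
        results.append(analyze_subject(ev, session.pressure_distorted[s],
                                       cfg.pressure_rate, session.tubing_tf))
    return results


def run_pipeline(manifest: SessionManifest, out_dir,
                 surrogate_windows: list[int] | None = None,
                 n_surrogates: int = 200) -> dict:
    """Run the full chain on files referenced by a manifest.

    Writes per-subject sniff and call tables, a bout LLR matrix and a JSON
    summary (slopes, phase statistics, bout distributions, parameters,
    config hash) into ``out_dir``; returns the summary dict.
    """
    from . import io as vio

    manifest.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    channels = []
    rate = None
    for p in manifest.audio_paths:
        data, r = vio.read_wav(p)
        channels.append(data)
        rate = r
    tf = vio.read_tf_csv(manifest.tf_path) if manifest.tf_path else None
    events = detection.detect_calls(channels, rate,
                                    subjects=manifest.subjects)
    if surrogate_windows is None:
        surrogate_windows = [4, 8, 12, 16, 32, 64, 128, 256]
    summary: dict = {
        "package_version": __version__,
        "seed": manifest.seed,
        "species": manifest.species,
        "config_hash": hashlib.sha256(
            json.dumps(manifest.__dict__, sort_keys=True, default=str)
            .encode()).hexdigest()[:16],
        "parameters": {
            "entropy_threshold_bits": 6.5,
            "min_segment_dur_s": 0.003,
            "bounding_silence_s": 0.020,
            "sonic_ratio_max": 1.0,
            "sniff_threshold_sd": 0.0,
            "sniff_hysteresis_sd": 0.05,
            "min_inhalation_s": 0.020,
            "n_surrogates": n_surrogates,
            "surrogate_windows": surrogate_windows,
        },
        "subjects": {},
    }
    for s, name in enumerate(manifest.subjects):
        ev = events[events["subject"] == name].reset_index(drop=True)
        pressure, prate = vio.read_pressure_csv(manifest.pressure_paths[s])
        res = analyze_subject(ev, pressure, prate, tf)
        vio.write_events_csv(out / f"sniffs_{name}.csv", res.sniffs)
        vio.write_events_csv(out / f"calls_{name}.csv", res.calls)
        subj_summary: dict = {
            "n_sniffs": int(len(res.sniffs)),
            "n_calls": int(len(res.calls)),
        }
        if res.regression:
            subj_summary["regression"] = res.regression
        if res.phases:
            subj_summary["median_onset_phase"] = float(
                np.median(res.phases["onset_phases"]))
            subj_summary["median_offset_phase"] = float(
                np.median(res.phases["offset_phases"]))
            subj_summary["mean_inh_frac"] = res.phases["mean_inh_frac"]
        vector = res.sniffs["is_vocal"].to_numpy().astype(int)
        if vector.any():
            lengths = bouts.extract_bouts(vector)
            dist = bouts.bout_distribution(lengths)
            subj_summary["bout_distribution"] = {
                int(k): float(v) for k, v in dist.items()}
            llr = bouts.llr_vs_window(vector, surrogate_windows,
                                      n_surrogates=n_surrogates,
                                      seed=manifest.seed)
            llr.to_csv(out / f"llr_{name}.csv")
            subj_summary["llr_vs_window"] = {
                int(w): [float(v) for v in row]
                for w, row in llr.iterrows()}
        summary["subjects"][name] = subj_summary
    for key, val in _finite_check(summary):
        raise ValueError(f"non-finite summary value at {key}: {val}")
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 sort_keys=True))
    return summary


def _finite_check(obj, prefix=""):
    """Yield (path, value) for any non-finite numeric leaf."""
    if isinstance(obj, dict):
        for k, v in obj.items():
            yield from _finite_check(v, f"{prefix}.{k}")
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            yield from _finite_check(v, f"{prefix}[{i}]")
    elif isinstance(obj, float) and not np.isfinite(obj):
        yield prefix, obj


def match_events(detected: pd.DataFrame, truth: pd.DataFrame,
                 min_overlap: float = 0.5) -> pd.DataFrame:
    """Greedy one-to-one matching of detected to true calls.

    Two events match when their temporal intersection over union is at
    least ``min_overlap``.  Returns a table of matched pairs with onset and
    offset errors (detected minus true, seconds).
    """
    det_on = detected["onset"].to_numpy()
    det_off = detected["offset"].to_numpy()
    used = np.zeros(len(detected), dtype=bool)
    rows = []
    for it, tr in truth.iterrows():
        inter = (np.minimum(det_off, tr["offset"]) -
                 np.maximum(det_on, tr["onset"]))
        union = (np.maximum(det_off, tr["offset"]) -
                 np.minimum(det_on, tr["onset"]))
        with np.errstate(invalid="ignore", divide="ignore"):
            iou = np.where((inter > 0) & ~used, inter / union, 0.0)
        if iou.size and iou.max() >= min_overlap:
            k = int(np.argmax(iou))
            used[k] = True
            rows.append((it, k, det_on[k] - tr["onset"],
                         det_off[k] - tr["offset"]))
    return pd.DataFrame(rows, columns=["truth_index", "detected_index",
                                       "onset_error", "offset_error"])


def evaluate_against_truth(detected_events: pd.DataFrame,
                           session: Session,
                           min_overlap: float = 0.5) -> dict:
    """Recall, precision, timing errors and caller-assignment accuracy of
    detections against a synthetic session's ground truth."""
    truth_frames = []
    for s, subj in enumerate(session.subjects):
        t = subj.calls[["onset", "offset"]].copy()
        t["subject"] = str(s)
        truth_frames.append(t)
    truth = pd.concat(truth_frames, ignore_index=True) if truth_frames \
        else pd.DataFrame(columns=["onset", "offset", "subject"])
    n_truth = len(truth)
    n_det = len(detected_events)
    if n_det == 0:
        return {"recall": 0.0, "precision": np.nan, "n_truth": n_truth,
                "n_detected": 0, "median_onset_error": np.nan,
                "median_offset_error": np.nan, "assignment_accuracy": np.nan}
    matches = match_events(detected_events, truth, min_overlap)
    correct_subject = 0
    for _, m in matches.iterrows():
        det_subj = detected_events.iloc[int(m["detected_index"])]["subject"]
        tr_subj = truth.iloc[int(m["truth_index"])]["subject"]
        if str(det_subj) == str(tr_subj):
            correct_subject += 1
    n_match = len(matches)
    return {
        "recall": n_match / n_truth if n_truth else np.nan,
        "precision": n_match / n_det,
        "n_truth": n_truth,
        "n_detected": n_det,
        "median_onset_error": (float(np.median(np.abs(
            matches["onset_error"]))) if n_match else np.nan),
        "median_offset_error": (float(np.median(np.abs(
            matches["offset_error"]))) if n_match else np.nan),
        "assignment_accuracy": (correct_subject / n_match
                                if n_match else np.nan),
    }
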