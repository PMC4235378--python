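"""File formats: WAV audio, pressure CSV with metadata sidecar, event and
sniff tables, transfer functions, session manifests.

CSV dialect: comma-separated, header row, UTF-8, '.' decimal, times in
seconds with 6 decimals.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .respiration import TransferFunction

TIME_FMT = "%.6f"


def write_wav(path, samples: np.ndarray, sampling_rate: float) -> None:
    wavfile.write(str(path), int(round(sampling_rate)),
                  np.asarray(samples, dtype=np.float32))


def read_wav(path) -> tuple[np.ndarray, float]:
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        data = data.astype(np.float32) / 32768.0
    return np.asarray(data), float(rate)


def write_pressure_csv(path, samples: np.ndarray,
                       sampling_rate: float = 1000.0) -> None:
    """Single-column pressure CSV plus a JSON sidecar with the rate."""
    path = Path(path)
    pd.DataFrame({"pressure": samples}).to_csv(path, index=False,
                                               float_format=TIME_FMT)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({"sampling_rate_hz": sampling_rate}))


def read_pressure_csv(path) -> tuple[np.ndarray, float]:
    path = Path(path)
    samples = pd.read_csv(path)["pressure"].to_numpy()
    sidecar = path.with_suffix(path.suffix + ".json")
    rate = 1000.0
    if sidecar.exists():
        rate = float(json.loads(sidecar.read_text())["sampling_rate_hz"])
    return samples, rate


def write_events_csv(path, events: pd.DataFrame) -> None:
    """Ground-truth / detected event table.

    Columns: subject, onset_s, offset_s, kind (call, inh_on, inh_off,
    exh_off) -- or the CallEvent schema when present."""
    events.to_csv(path, index=False, float_format=TIME_FMT)


def read_events_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_tf_csv(path, tf: TransferFunction) -> None:
    pd.DataFrame({"freq_hz": tf.freqs, "gain_real": tf.gain.real,
                  "gain_imag": tf.gain.imag}).to_csv(path, index=False)


def read_tf_csv(path) -> TransferFunction:
    df = pd.read_csv(path)
    return TransferFunction(freqs=df["freq_hz"].to_numpy(),
                            gain=(df["gain_real"].to_numpy() +
                                  1j * df["gain_imag"].to_numpy()))


def truth_events_table(subjects) -> pd.DataFrame:
    """Flatten per-subject ground truth into the events CSV schema."""
    rows = []
    for s, subj in enumerate(subjects):
        for _, c in subj.calls.iterrows():
            rows.append((str(s), c["onset"], c["offset"], "call"))
        for _, r in subj.sniffs.iterrows():
            rows.append((str(s), r["inh_onset"], r["inh_onset"], "inh_on"))
            rows.append((str(s), r["inh_offset"], r["inh_offset"], "inh_off"))
            rows.append((str(s), r["exh_offset"], r["exh_offset"], "exh_off"))
    return pd.DataFrame(rows, columns=["subject", "onset_s", "offset_s",
                                       "kind"])
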