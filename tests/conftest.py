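"""Shared fixtures.

The expensive fixtures run the full pipeline (audio synthesis, entropy
detection, sniff segmentation, call linkage) on pools of synthetic
sessions at the generator's default study conditions; they are
session-scoped so every test that needs end-to-end products shares one
computation.  Rat sessions use the generator's documented 192 kHz
fast-audio mode (analysis quantities do not depend on the audio sampling
rate); mouse sessions need the full 250 kHz because the mouse call band
reaches 100 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from vocalsniff import synthetic, workflow


@dataclass
class PipelineRun:
    """One synthetic session with its full-pipeline products."""

    session: synthetic.Session
    results: list  # one SubjectResult per subject
    events: pd.DataFrame  # all detected call events, both subjects


def _run_pool(config, durations, seeds):
    runs = []
    for dur, seed in zip(durations, seeds):
        session = synthetic.generate_session(config, dur, seed)
        results = workflow.analyze_session(session)
        events = pd.concat([r.call_events for r in results],
                           ignore_index=True)
        # audio is only needed for detection; drop it so the pooled
        # fixtures do not retain hundreds of MB per session
        session.audio = np.empty((0, 0), dtype=np.float32)
        runs.append(PipelineRun(session=session, results=results,
                                events=events))
    return runs


@pytest.fixture(scope="session")
def rat_pool():
    """Four rat sessions (two subjects each) through the full pipeline."""
    cfg = synthetic.rat_config(audio_rate=synthetic.FAST_AUDIO_RATE)
    return _run_pool(cfg, [220.0] * 4, [101, 102, 103, 104])


@pytest.fixture(scope="session")
def mouse_pool():
    """Two mouse sessions (single subject) through the full pipeline."""
    cfg = synthetic.mouse_config()
    return _run_pool(cfg, [600.0] * 4, [201, 202, 203, 204])


@pytest.fixture(scope="session")
def rat_truth_long():
    """A long rat ground-truth realization (no audio), for statistics that
    only need the generator's sniff/call bookkeeping."""
    cfg = synthetic.rat_config()
    rng = np.random.default_rng(7)
    train = synthetic.generate_sniff_train(cfg, 2500.0, rng)
    return synthetic.inject_calls(train, cfg, rng)
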