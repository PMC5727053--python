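"""Shared fixtures: montages, sinusoid segments, and session-scoped synthetic
corpora (expensive generators are built once and reused read-only)."""

from __future__ import annotations

import numpy as np
import pytest

from dfhm.montage import default_montage
from dfhm.preprocess import Segment
from dfhm.synthetic import generate_labeled_dfhm_set


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture
def make_segment():
    """Factory for single-or-multi-channel sinusoid test segments."""

    def _make(freqs, amps=None, rate=500.0, duration_s=10.0, channels=None, phase=0.0):
        freqs = np.atleast_1d(freqs).astype(float)
        amps = np.ones_like(freqs) if amps is None else np.atleast_1d(amps).astype(float)
        t = np.arange(int(rate * duration_s)) / rate
        data = np.stack([a * np.sin(2 * np.pi * f * t + phase) for f, a in zip(freqs, amps)])
        chans = channels or [f"ch{i}" for i in range(len(freqs))]
        return Segment(data=data, start_s=0.0, task_id="task", subject_id="s0",
                       rate=rate, channels=chans)

    return _make


@pytest.fixture(scope="session")
def labeled_set(montage):
    """A rule-labeled archetype map corpus (540 maps, 1 z-unit margin)."""
    return generate_labeled_dfhm_set(n_maps=540, margin=1.0, montage=montage, seed=1)
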