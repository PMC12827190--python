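"""Shared fixtures: small synthetic datasets generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import mecg


@pytest.fixture(scope="session")
def short_spec() -> mecg.SyntheticSpec:
    """One minute of synthetic beats at 75 bpm with mild LF/HF modulation."""
    return mecg.SyntheticSpec(duration_s=60.0, seed=0)


@pytest.fixture(scope="session")
def short_truth(short_spec) -> mecg.GroundTruth:
    return mecg.simulate_rr(short_spec)


@pytest.fixture(scope="session")
def clean_ecg(short_truth) -> mecg.CardiacTrace:
    """Noise-free ECG-like trace rendered from the short ground truth."""
    return mecg.synthesize_ecg(short_truth, rate=600.0)


@pytest.fixture(scope="session")
def short_dataset(short_spec):
    """27 MEG-like channels + 2 reference + 1 ECG channel, 60 s."""
    return mecg.make_dataset(short_spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
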