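"""Shared fixtures: one full default synthetic session reused across the
suite (generation is deterministic, so session scope is safe), plus a small
fast configuration for structural tests."""

from __future__ import annotations


import numpy as np
import pytest

import cogload as cl


@pytest.fixture(scope="session")
def default_session() -> cl.Recording:
    """Full default-protocol session: 24 blocks, 1440 events, 256 Hz."""
    return cl.generate_session(cl.SynthConfig(seed=11))


@pytest.fixture(scope="session")
def default_epochs(default_session) -> cl.EpochSet:
    """EOG-cleaned, epoched, target-free trials of the default session."""
    cleaned = cl.remove_eog(default_session)
    return cl.discard_targets(cl.segment_epochs(cleaned))


@pytest.fixture(scope="session")
def fb_cache(default_epochs):
    """Per-band trial covariances + ERP epochs of the default subject."""
    return cl.FeatureCache.build(default_epochs, variety="both")


@pytest.fixture()
def small_config() -> cl.SynthConfig:
    """One block per context per level, 20 letters: fast structural checks."""
    return cl.SynthConfig(
        seed=5,
        n_blocks_per_context_per_level=1,
        letters_per_block=20,
    )


def make_epochs(rng: np.random.Generator, n_trials: int = 8, n_channels: int = 4,
                n_samples: int = 64, sampling_rate: float = 256.0,
                data: np.ndarray | None = None) -> cl.EpochSet:
    """Hand-built epoch set with alternating workload labels."""
    if data is None:
        data = rng.standard_normal((n_trials, n_channels, n_samples))
    n_trials = data.shape[0]
    workload = np.array(["low", "high"] * (n_trials // 2 + 1))[:n_trials]
    return cl.EpochSet(
        data=data,
        sampling_rate=sampling_rate,
        workload=workload,
        context=np.array(["relax"] * n_trials),
        block=np.arange(n_trials) % 2,
        half=np.ones(n_trials, dtype=int),
        is_target=np.zeros(n_trials, dtype=bool),
        channel_labels=[f"C{i}" for i in range(data.shape[1])],
    )
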