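"""Shared fixtures: small synthetic records and epoch sets, generated at test time."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from attnpipe.montage import CHANNELS_64, PALETTE
from attnpipe.records import EpochSet
from attnpipe.synthetic import GeneratorParams, simulate_session
from attnpipe.task_design import TrialSchedule, build_eeg_schedule


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def one_block_schedule() -> TrialSchedule:
    """One 84-trial one-cue block plus one two-cue block (168 trials)."""
    return build_eeg_schedule(np.random.default_rng(7), n_blocks_per_cond=1)


@pytest.fixture(scope="session")
def small_record(one_block_schedule):
    """A short continuous record with default signal structure."""
    gen = GeneratorParams(subject_seed=3)
    return simulate_session(gen, one_block_schedule, np.random.default_rng(11))


def make_epochs(
    n_trials: int = 28,
    n_channels: int = 64,
    srate: float = 100.0,
    tmin: float = -0.5,
    n_samples: int = 151,
    data: np.ndarray | None = None,
    colors: np.ndarray | None = None,
    conditions: np.ndarray | None = None,
    lock: str = "target",
    seed: int = 0,
    channel_names: list[str] | None = None,
) -> EpochSet:
    """Hand-built epoch set with controllable content (all-zero by default)."""
    from attnpipe.montage import POSTERIOR_17

    rng = np.random.default_rng(seed)
    if data is None:
        data = np.zeros((n_trials, n_channels, n_samples))
    n_trials = data.shape[0]
    if colors is None:
        colors = np.array(PALETTE)[rng.integers(0, 7, n_trials)]
    if conditions is None:
        conditions = np.full(n_trials, "one")
    times = tmin + np.arange(data.shape[2]) / srate
    meta = pd.DataFrame({
        "trial_index": np.arange(n_trials),
        "cue_condition": conditions,
        "cued_colors": colors,
        "target_color": colors,
        "is_target": np.ones(n_trials, dtype=int),
        "coherence": np.full(n_trials, 0.44),
    })
    if channel_names is None:
        nc = data.shape[1]
        channel_names = list(CHANNELS_64) if nc == 64 else (
            list(POSTERIOR_17) if nc == 17 else list(CHANNELS_64[:nc]))
    return EpochSet(data, srate, times, lock, channel_names, meta)
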