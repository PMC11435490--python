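"""Shared fixtures: synthetic walks and small CSV helpers.

Expensive fixtures are session-scoped; every trace is generated
programmatically so the repository ships no binary data.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trunkgait import RunConfig, SyntheticSpec, detect_events, generate_trace


@pytest.fixture(scope="session")
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture(scope="session")
def clean_spec() -> SyntheticSpec:
    """Noise-free, perfectly periodic walk with known events."""
    return SyntheticSpec(
        stride_time=1.1, n_strides=26, hr_v=2.0, hr_ml=1.8, hr_ap=1.9,
        stance_left=0.62, stance_right=0.62, paretic_side="left", seed=0,
    )


@pytest.fixture(scope="session")
def clean_walk(clean_spec):
    """(trace, truth) for the noise-free walk."""
    return generate_trace(clean_spec)


@pytest.fixture(scope="session")
def clean_events(clean_walk, config):
    trace, _ = clean_walk
    return detect_events(trace, config)


@pytest.fixture(scope="session")
def noisy_walk():
    """A realistic walk with noise and variability (IC-group-like)."""
    spec = SyntheticSpec(
        stride_time=1.15, n_strides=26, hr_v=1.7, hr_ml=1.5, hr_ap=1.6,
        stance_left=0.63, stance_right=0.615, paretic_side="right", seed=7,
        noise_sigma={"V": 0.033, "ML": 0.033, "AP": 0.033}, noise_corr=0.0,
        stride_cv=0.01, amp_jitter=0.015, timing_jitter=0.0055,
    )
    return generate_trace(spec)


@pytest.fixture()
def trace_csv(tmp_path, clean_walk, config):
    """The clean walk written to the documented CSV schema."""
    from trunkgait.io_config import write_accel_csv

    trace, _ = clean_walk
    path = tmp_path / "walk.csv"
    write_accel_csv(trace, path, config)
    return path


def make_trace_csv(path, n_rows=3000, fs=100.0, columns=("time", "acc_ap", "acc_ml", "acc_v"),
                   time_override=None):
    """Write a minimal schema-conforming trace CSV with sinusoidal content."""
    t = np.arange(n_rows) / fs if time_override is None else time_override
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        columns[0]: t,
        columns[1]: np.sin(2 * np.pi * 1.0 * np.arange(n_rows) / fs),
        columns[2]: np.sin(2 * np.pi * 0.9 * np.arange(n_rows) / fs),
        columns[3]: np.cos(2 * np.pi * 1.8 * np.arange(n_rows) / fs) + 0.01 * rng.standard_normal(n_rows),
    })
    df.to_csv(path, index=False)
    return path
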