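"""Shared fixtures: simulated study data reused across the suite.

Simulation runs are expensive, so the canonical study traces (three
point-to-point repetitions, three rod-oscillation runs, one noisy replay)
are session-scoped and generated once.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuromc import (
    ModelConfig,
    noisy_replay,
    run_oscillation,
    run_point_to_point,
    sample_cpg_frequencies,
    sample_ep_variations,
)

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def cfg() -> ModelConfig:
    return ModelConfig.default()


@pytest.fixture(scope="session")
def p2p_study(cfg):
    """Three point-to-point runs with naturally jittered equilibrium postures."""
    schedules = sample_ep_variations(3, seed=11, cfg=cfg)
    traces = [run_point_to_point(s, cfg, seed=11) for s in schedules]
    return schedules, traces


@pytest.fixture(scope="session")
def osc_traces(cfg):
    """Three rod-oscillation runs with CPG frequencies from 3.8 +/- 0.2 Hz."""
    freqs = [3.8, *sample_cpg_frequencies(2, seed=7)]
    return [run_oscillation(float(f), cfg, seed=7) for f in freqs]


@pytest.fixture(scope="session")
def noisy_run(cfg, p2p_study):
    """(clean, high-noise replay) pair for the first point-to-point run."""
    schedules, traces = p2p_study
    noisy = noisy_replay(traces[0], schedules[0], "high", seed=42, cfg=cfg)
    return traces[0], noisy


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
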