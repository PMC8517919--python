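"""Shared fixtures: small synthetic cohorts and hand-built posteriors."""

from __future__ import annotations

import numpy as np
import pytest

from burstnet.containers import RegionalRecording, StatePosterior
from burstnet.simulate import SimulationConfig, simulate_resting


@pytest.fixture(scope="session")
def small_resting():
    """A 4-region, 40 s, 2-per-group resting cohort with ground truth."""
    cfg = SimulationConfig(n_regions=4, n_epochs=4, seed=11)
    recs, gt = simulate_resting(cfg, 2)
    return cfg, recs, gt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_recording(data: np.ndarray, fs: float = 100.0,
                   group: str = "control", **kwargs) -> RegionalRecording:
    labels = [f"R{i:02d}" for i in range(data.shape[0])]
    return RegionalRecording(subject_id="test", group=group, fs=fs,
                             region_labels=labels, data=data, **kwargs)


def make_posterior(gamma: np.ndarray, fs: float = 100.0,
                   sample_indices: np.ndarray | None = None,
                   n_samples: int | None = None) -> StatePosterior:
    """StatePosterior wrapper around an explicit K x T' gamma matrix."""
    gamma = np.asarray(gamma, dtype=float)
    K, T = gamma.shape
    if sample_indices is None:
        sample_indices = np.arange(T)
    if n_samples is None:
        n_samples = int(sample_indices.max()) + 1
    A = np.full((K, K), 1.0 / K)
    covs = np.stack([np.eye(3)] * K)
    return StatePosterior(
        region_id="R00", gamma=gamma, transition_matrix=A,
        state_covariances=covs, startprob=np.full(K, 1.0 / K),
        objective_trace=np.array([0.0]), sample_indices=sample_indices,
        n_samples=n_samples, fs=fs, window_s=0.23)
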