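"""Core data containers shared across the pipeline.

The analysis operates on per-subject *regional* recordings: an R x T real
matrix of source-space ("virtual sensor") time courses, one row per atlas
region, at a known sampling rate. Downstream stages attach hidden-Markov
state posteriors, beta-band amplitude envelopes, binary burst trains,
burst-coincidence connectomes and trial tensors to these recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

GROUPS = ("control", "patient")


def _check_intervals(intervals: Sequence[tuple[int, int]], n_samples: int,
                     what: str = "interval") -> list[tuple[int, int]]:
    """Validate a sorted, non-overlapping list of half-open sample intervals."""
    out: list[tuple[int, int]] = []
    prev_end = 0
    for lo, hi in intervals:
        lo, hi = int(lo), int(hi)
        if not (0 <= lo < hi <= n_samples):
            raise ValueError(f"{what} ({lo}, {hi}) outside [0, {n_samples})")
        if lo < prev_end:
            raise ValueError(f"{what} ({lo}, {hi}) overlaps or is unsorted")
        out.append((lo, hi))
        prev_end = hi
    return out


@dataclass
class RegionalRecording:
    """One subject's regional time courses plus bookkeeping metadata.

    Parameters
    ----------
    subject_id : str
        Unique subject identifier.
    group : str
        ``"patient"`` or ``"control"``.
    fs : float
        Sampling rate in Hz.
    region_labels : list of str
        Ordered region names; length must equal ``data.shape[0]``.
    data : ndarray, shape (R, T)
        Regional time courses (float64).
    epochs : list of (int, int)
        Half-open sample intervals of clean, contiguous segments. Conditioning
        treats the recording as contiguous; burst visits never span an epoch
        boundary.
    events : list of int, optional
        Event (button-press) sample indices for task recordings.
    symptom_score : float, optional
        Non-negative symptom-severity score.
    """

    subject_id: str
    group: str
    fs: float
    region_labels: list[str]
    data: np.ndarray
    epochs: list[tuple[int, int]] = field(default_factory=list)
    events: list[int] | None = None
    symptom_score: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (regions x samples) matrix")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.region_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.region_labels)} labels for {self.data.shape[0]} rows")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if not self.epochs:
            self.epochs = [(0, self.data.shape[1])]
        self.epochs = _check_intervals(self.epochs, self.data.shape[1], "epoch")
        if self.events is not None:
            self.events = [int(e) for e in self.events]
            for e in self.events:
                if not 0 <= e < self.data.shape[1]:
                    raise ValueError(f"event sample {e} outside recording")
        if self.symptom_score is not None and self.symptom_score < 0:
            raise ValueError("symptom_score must be non-negative")

    @property
    def n_regions(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, **kwargs) -> "RegionalRecording":
        base = dict(
            subject_id=self.subject_id, group=self.group, fs=self.fs,
            region_labels=list(self.region_labels), data=self.data.copy(),
            epochs=list(self.epochs),
            events=None if self.events is None else list(self.events),
            symptom_score=self.symptom_score,
        )
        base.update(kwargs)
        return RegionalRecording(**base)


@dataclass
class StatePosterior:
    """Per-region HMM state posteriors on the embedded time base.

    ``gamma[k, t]`` is the probability of state ``k`` at embedded column
    ``t``; ``sample_indices[t]`` maps that column back to the original
    sample index (the centre of the embedding window). Samples trimmed at
    epoch edges by the embedding are absent from this map.
    """

    region_id: str
    gamma: np.ndarray                  # (K, T')
    transition_matrix: np.ndarray      # (K, K) row-stochastic
    state_covariances: np.ndarray      # (K, L, L)
    startprob: np.ndarray              # (K,)
    objective_trace: np.ndarray        # per-iteration log-likelihood
    sample_indices: np.ndarray         # (T',) int, original sample index
    n_samples: int                     # T of the source series
    fs: float
    window_s: float
    converged: bool = True
    n_collapse_repairs: int = 0

    def __post_init__(self) -> None:
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        col = self.gamma.sum(axis=0)
        if self.gamma.size and not np.allclose(col, 1.0, atol=1e-6):
            raise ValueError("gamma columns must sum to 1")
        rows = np.asarray(self.transition_matrix).sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-6):
            raise ValueError("transition rows must sum to 1")

    @property
    def n_states(self) -> int:
        return self.gamma.shape[0]


@dataclass
class BetaEnvelope:
    """Beta-band (13-30 Hz by default) Morlet amplitude envelope."""

    region_id: str
    env: np.ndarray
    fs: float
    band: tuple[float, float] = (13.0, 30.0)
    wavelet_cycles: int = 7

    def __post_init__(self) -> None:
        self.env = np.asarray(self.env, dtype=np.float64)
        if np.any(self.env < 0):
            raise ValueError("envelope must be non-negative")


def visits_from_binary(b: np.ndarray,
                       epochs: Sequence[tuple[int, int]] | None = None
                       ) -> list[tuple[int, int]]:
    """Maximal runs of 1 in a binary series, split at epoch boundaries."""
    b = np.asarray(b).astype(bool)
    if epochs is None:
        epochs = [(0, len(b))]
    visits: list[tuple[int, int]] = []
    for lo, hi in epochs:
        seg = b[lo:hi]
        if not seg.any():
            continue
        d = np.diff(seg.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if seg[0]:
            starts = np.r_[0, starts]
        if seg[-1]:
            ends = np.r_[ends, len(seg)]
        visits.extend((int(s) + lo, int(e) + lo) for s, e in zip(starts, ends))
    return visits


def binary_from_visits(visits: Sequence[tuple[int, int]], n_samples: int) -> np.ndarray:
    b = np.zeros(n_samples, dtype=np.uint8)
    for lo, hi in visits:
        b[lo:hi] = 1
    return b


@dataclass
class BurstTrain:
    """Binary burst indicator for one region with its explicit visit list."""

    region_id: str
    b: np.ndarray
    fs: float
    visits: list[tuple[int, int]] = field(default=None)  # type: ignore[assignment]
    epochs: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=np.uint8)
        if self.b.ndim != 1:
            raise ValueError("b must be 1-D")
        if self.visits is None:
            self.visits = visits_from_binary(self.b, self.epochs)
        else:
            self.visits = _check_intervals(self.visits, len(self.b), "visit")
            if not np.array_equal(binary_from_visits(self.visits, len(self.b)), self.b):
                raise ValueError("visits do not reconstruct b")

    @classmethod
    def from_visits(cls, region_id: str, visits: Sequence[tuple[int, int]],
                    n_samples: int, fs: float,
                    epochs: Sequence[tuple[int, int]] | None = None) -> "BurstTrain":
        b = binary_from_visits(visits, n_samples)
        return cls(region_id=region_id, b=b, fs=fs,
                   visits=visits_from_binary(b, epochs),
                   epochs=None if epochs is None else list(epochs))

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def occupancy(self) -> float:
        return float(self.b.mean()) if len(self.b) else 0.0


@dataclass
class BurstSummary:
    """Per-region burst metrics for one recording.

    ``burst_amplitude`` is the mean over visits of the per-visit envelope
    maximum; it is NaN (with ``amplitude_defined=False``) for an empty train.
    """

    region_id: str
    burst_amplitude: float
    nonburst_amplitude: float
    total_burst_time: float
    mean_duration_s: float
    count_rate_hz: float
    n_visits: int
    amplitude_defined: bool = True


@dataclass
class Connectome:
    """Symmetric region x region Jaccard burst-coincidence matrix.

    Diagonal fixed at 0 by convention; ``union_empty_mask`` marks pairs whose
    union of burst samples was empty (J reported as 0 there).
    """

    labels: list[str]
    J: np.ndarray
    union_empty_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=np.float64)
        R = len(self.labels)
        if self.J.shape != (R, R):
            raise ValueError("J shape does not match labels")
        if not np.allclose(self.J, self.J.T):
            raise ValueError("J must be symmetric")
        if np.any(self.J < -1e-12) or np.any(self.J > 1 + 1e-12):
            raise ValueError("J values must lie in [0, 1]")
        if self.union_empty_mask is None:
            self.union_empty_mask = np.zeros_like(self.J, dtype=bool)

    @property
    def n_regions(self) -> int:
        return len(self.labels)

    @property
    def n_edges(self) -> int:
        R = self.n_regions
        return R * (R - 1) // 2

    def edge_values(self) -> np.ndarray:
        iu = np.triu_indices(self.n_regions, k=1)
        return self.J[iu]


@dataclass
class TrialTensor:
    """Trial-locked binary burst indicators and matched envelope values.

    ``B`` has shape (time-within-trial, trials); ``trial_time_axis`` gives
    seconds relative to the button press and always contains 0.
    """

    region_id: str
    B: np.ndarray
    env: np.ndarray
    trial_time_axis: np.ndarray
    fs: float
    condition: str = "press"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.B = np.asarray(self.B, dtype=np.uint8)
        self.env = np.asarray(self.env, dtype=np.float64)
        self.trial_time_axis = np.asarray(self.trial_time_axis, dtype=np.float64)
        if self.B.shape != self.env.shape:
            raise ValueError("B and env shapes differ")
        if self.B.shape[0] != len(self.trial_time_axis):
            raise ValueError("time axis length mismatch")
        t = self.trial_time_axis
        if len(t) and not (t.min() <= 0.0 <= t.max()):
            raise ValueError("trial time axis must include 0")

    @property
    def n_trials(self) -> int:
        return self.B.shape[1]


@dataclass
class WindowSpec:
    """Trial-time analysis windows (seconds relative to the button press).

    The rebound (PMBR) window defaults to 0.45-0.85 s after the press; the
    movement (MRBD) window defaults to (-0.3, 0.1) s around it. Windows must
    not overlap.
    """

    pmbr: tuple[float, float] = (0.45, 0.85)
    mrbd: tuple[float, float] = (-0.3, 0.1)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("pmbr", self.pmbr), ("mrbd", self.mrbd)):
            if not lo < hi:
                raise ValueError(f"{name} window must have lo < hi")
        if self.mrbd[1] > self.pmbr[0] and self.pmbr[1] > self.mrbd[0]:
            raise ValueError("pmbr and mrbd windows overlap")
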