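"""Trial-locked burst dynamics for the motor task.

Binary burst trains are epoched into +/-3 s windows around each button
press. The burst-probability course at trial time t is the fraction of
trials bursting at t; window statistics summarise the rebound (PMBR) and
movement (MRBD) windows; and the coincidence course generalises the
Jaccard index across the trial dimension, one value per trial time point.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .containers import (BetaEnvelope, BurstTrain, TrialTensor, WindowSpec,
                         visits_from_binary)

logger = logging.getLogger(__name__)


def epoch_trials(train: BurstTrain, env: BetaEnvelope, events: list[int],
                 half_window_s: float = 3.0,
                 condition: str = "press") -> TrialTensor:
    """Slice a burst train and envelope into a time-within-trial x trials tensor.

    Events closer than the half window to either record edge are dropped
    (and counted in ``n_dropped``).
    """
    if len(train.b) != len(env.env):
        raise ValueError("train and envelope lengths differ")
    half = int(round(half_window_s * train.fs))
    T = len(train.b)
    cols_b, cols_e = [], []
    dropped = 0
    for e in events:
        lo, hi = e - half, e + half
        if lo < 0 or hi > T:
            dropped += 1
            continue
        cols_b.append(train.b[lo:hi])
        cols_e.append(env.env[lo:hi])
    if dropped:
        logger.info("epoch_trials: dropped %d edge trial(s)", dropped)
    if not cols_b:
        raise ValueError("no usable trials (all within the edge guard)")
    B = np.stack(cols_b, axis=1)
    E = np.stack(cols_e, axis=1)
    axis = (np.arange(-half, half) ) / train.fs
    return TrialTensor(region_id=train.region_id, B=B, env=E,
                       trial_time_axis=axis, fs=train.fs,
                       condition=condition, n_dropped=dropped)


def burst_probability_course(t: TrialTensor) -> np.ndarray:
    """P(burst at trial time t) = bursting trials / total trials."""
    if t.n_trials < 1:
        raise ValueError("tensor has no trials")
    return t.B.mean(axis=1)


def _window_mask(axis: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (axis >= lo) & (axis < hi)


@dataclass
class WindowStats:
    """Per-subject burst statistics in the PMBR/MRBD windows."""

    pmbr_probability: float
    pmbr_amplitude: float
    modulation: float            # mean course over PMBR - mean over MRBD
    amplitude_defined: bool
    n_trials_with_visit: int


def window_burst_stats(t: TrialTensor, w: WindowSpec | None = None
                       ) -> WindowStats:
    """Probability, amplitude and modulation statistics for the windows.

    A burst visit contributes to the PMBR amplitude if it intersects the
    window at all (it fell within, began, or ended during it). Per-trial
    means of per-visit envelope maxima are averaged across trials that
    contain at least one qualifying visit.
    """
    w = w or WindowSpec()
    course = burst_probability_course(t)
    pm = _window_mask(t.trial_time_axis, w.pmbr)
    mm = _window_mask(t.trial_time_axis, w.mrbd)
    if not pm.any() or not mm.any():
        raise ValueError("window outside the trial time axis")
    pmbr_probability = float(course[pm].mean())
    modulation = pmbr_probability - float(course[mm].mean())

    pm_idx = np.flatnonzero(pm)
    lo_w, hi_w = pm_idx[0], pm_idx[-1] + 1
    trial_means = []
    for j in range(t.n_trials):
        visits = visits_from_binary(t.B[:, j])
        maxima = [float(t.env[s:e, j].max())
                  for s, e in visits if s < hi_w and e > lo_w]
        if maxima:
            trial_means.append(float(np.mean(maxima)))
    defined = bool(trial_means)
    amp = float(np.mean(trial_means)) if defined else np.nan
    return WindowStats(pmbr_probability=pmbr_probability,
                       pmbr_amplitude=amp, modulation=modulation,
                       amplitude_defined=defined,
                       n_trials_with_visit=len(trial_means))


def coincidence_course(ta: TrialTensor, tb: TrialTensor
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Jaccard index across trials at each trial time point.

    Returns ``(course, union_empty_mask)``; time points with an empty union
    across trials carry 0 and a set mask bit.
    """
    if ta.n_trials != tb.n_trials:
        raise ValueError("tensors have different trial counts")
    if ta.B.shape[0] != tb.B.shape[0]:
        raise ValueError("tensors have different trial lengths")
    A = ta.B.astype(bool)
    B = tb.B.astype(bool)
    inter = (A & B).sum(axis=1).astype(float)
    union = (A | B).sum(axis=1).astype(float)
    mask = union == 0
    course = np.where(mask, 0.0, inter / np.where(mask, 1.0, union))
    return course, mask


def window_coincidence(ta: TrialTensor, tb: TrialTensor,
                       window: tuple[float, float] = (0.45, 0.85)) -> float:
    """Mean coincidence course over a trial-time window (e.g. the PMBR)."""
    course, _ = coincidence_course(ta, tb)
    m = _window_mask(ta.trial_time_axis, window)
    if not m.any():
        raise ValueError("window outside the trial time axis")
    return float(course[m].mean())
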