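"""Burst-state identification, binarization, and burst summary metrics.

Of the K HMM states, the *burst state* is the one whose posterior
probability course correlates most with the beta-band amplitude envelope.
Its probability course is binarized at a strict 2/3 threshold; maximal
runs of the binary indicator (within epochs) are burst *visits*, and the
summary metrics — burst amplitude, total burst time, burst duration,
burst count rate — are computed from the visit list and the envelope.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .containers import (BetaEnvelope, BurstSummary, BurstTrain,
                         StatePosterior, visits_from_binary)

logger = logging.getLogger(__name__)

BURST_THRESHOLD = 2.0 / 3.0


def beta_envelopes(data: np.ndarray, fs: float,
                   band: tuple[float, float] = (13.0, 30.0),
                   cycles: int = 7, freq_step: float = 1.0,
                   region_ids: list[str] | None = None) -> list[BetaEnvelope]:
    """Morlet amplitude envelopes for an R x T matrix (one call per subject).

    A continuous Morlet wavelet transform is evaluated at ``freq_step`` Hz
    steps across the band (13..30 Hz by default) and the coefficient moduli
    are averaged across frequencies. Wavelets are MNE's (zero-mean Morlet,
    ``cycles`` cycles per frequency); the convolution is channel-batched,
    which matches ``mne.time_frequency.tfr_array_morlet`` to rounding
    error.
    """
    from mne.time_frequency import morlet
    from scipy.signal import fftconvolve

    lo, hi = band
    if hi >= fs / 2:
        raise ValueError(f"band upper edge {hi} Hz at or above Nyquist")
    if not 0 < lo < hi:
        raise ValueError("need 0 < low < high")
    data = np.atleast_2d(np.asarray(data, dtype=np.float64))
    if region_ids is None:
        region_ids = [f"R{i:02d}" for i in range(data.shape[0])]
    freqs = np.arange(lo, hi + 1e-9, freq_step)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wavelets = morlet(fs, freqs, n_cycles=cycles, zero_mean=True)
    acc = np.zeros(data.shape)
    for w in wavelets:
        acc += np.abs(fftconvolve(data, w[None, :], mode="same", axes=-1))
    env = acc / len(wavelets)
    return [BetaEnvelope(region_id=rid, env=env[r], fs=fs, band=(lo, hi),
                         wavelet_cycles=cycles)
            for r, rid in enumerate(region_ids)]


def beta_envelope(x: np.ndarray, fs: float,
                  band: tuple[float, float] = (13.0, 30.0),
                  cycles: int = 7, freq_step: float = 1.0,
                  region_id: str = "region") -> BetaEnvelope:
    """Single-series convenience wrapper around :func:`beta_envelopes`."""
    return beta_envelopes(np.asarray(x)[None, :], fs, band, cycles, freq_step,
                          [region_id])[0]


def select_burst_state(posterior: StatePosterior, env: BetaEnvelope
                       ) -> tuple[int, np.ndarray]:
    """Index of the state most correlated with the beta envelope.

    Pearson correlations between each state's probability course and the
    envelope (sampled at the posterior's time base) are returned alongside;
    constant rows are excluded (NaN correlation). Ties resolve to the
    lowest state index.
    """
    e = env.env[posterior.sample_indices]
    K = posterior.n_states
    corrs = np.full(K, np.nan)
    e_sd = e.std()
    for k in range(K):
        g = posterior.gamma[k]
        if g.std() < 1e-12 or e_sd < 1e-12:
            continue
        corrs[k] = float(np.corrcoef(g, e)[0, 1])
    if np.all(np.isnan(corrs)):
        raise ValueError("all state/envelope correlations undefined")
    best = int(np.nanargmax(corrs))
    tied = np.flatnonzero(np.isclose(corrs, corrs[best], atol=1e-12))
    if tied.size > 1:
        best = int(tied[0])
        logger.info("burst-state tie between states %s; selecting %d",
                    tied.tolist(), best)
    return best, corrs


def binarize(posterior: StatePosterior, state: int,
             threshold: float = BURST_THRESHOLD,
             epochs: list[tuple[int, int]] | None = None) -> BurstTrain:
    """Binary burst train: 1 where the state's probability strictly exceeds
    ``threshold``. Samples trimmed by the embedding count as non-burst."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    b = np.zeros(posterior.n_samples, dtype=np.uint8)
    b[posterior.sample_indices] = (posterior.gamma[state] > threshold)
    visits = visits_from_binary(b, epochs)
    return BurstTrain(region_id=posterior.region_id, b=b, fs=posterior.fs,
                      visits=visits,
                      epochs=None if epochs is None else list(epochs))


def summarize(train: BurstTrain, env: BetaEnvelope,
              record_duration_s: float | None = None) -> BurstSummary:
    """Per-region burst metrics from a train and its matched envelope."""
    if len(train.b) != len(env.env):
        raise ValueError("train and envelope lengths differ")
    T = len(train.b)
    if record_duration_s is None:
        record_duration_s = T / train.fs
    total = sum(hi - lo for lo, hi in train.visits)
    total_burst_time = total / T if T else 0.0
    n = train.n_visits
    count_rate = n / record_duration_s
    if n == 0:
        non_burst = float(env.env.mean()) if T else np.nan
        return BurstSummary(region_id=train.region_id, burst_amplitude=np.nan,
                            nonburst_amplitude=non_burst, total_burst_time=0.0,
                            mean_duration_s=np.nan, count_rate_hz=0.0,
                            n_visits=0, amplitude_defined=False)
    maxima = [float(env.env[lo:hi].max()) for lo, hi in train.visits]
    mean_dur = total / n / train.fs
    outside = env.env[train.b == 0]
    non_burst = float(outside.mean()) if outside.size else np.nan
    return BurstSummary(region_id=train.region_id,
                        burst_amplitude=float(np.mean(maxima)),
                        nonburst_amplitude=non_burst,
                        total_burst_time=float(total_burst_time),
                        mean_duration_s=float(mean_dur),
                        count_rate_hz=float(count_rate),
                        n_visits=n, amplitude_defined=True)


GLOBAL_METRICS = ("burst_amplitude", "nonburst_amplitude", "total_burst_time",
                  "mean_duration_s", "count_rate_hz")


def global_collapse(summaries: list[BurstSummary]
                    ) -> tuple[dict[str, float], dict[str, int]]:
    """Collapse per-region summaries to per-subject global means.

    Regions with an undefined (NaN) value for a metric are excluded from
    that metric's mean; the exclusion counts are returned alongside.
    """
    if not summaries:
        raise ValueError("no summaries to collapse")
    means: dict[str, float] = {}
    excluded: dict[str, int] = {}
    for m in GLOBAL_METRICS:
        vals = np.array([getattr(s, m) for s in summaries], dtype=float)
        ok = np.isfinite(vals)
        excluded[m] = int((~ok).sum())
        if not ok.any():
            raise ValueError(f"metric {m!r} undefined in every region")
        if excluded[m]:
            logger.info("global_collapse: %d region(s) excluded for %s",
                        excluded[m], m)
        means[m] = float(vals[ok].mean())
    return means, excluded


def detect_bursts(posterior: StatePosterior, env: BetaEnvelope,
                  threshold: float = BURST_THRESHOLD,
                  epochs: list[tuple[int, int]] | None = None
                  ) -> tuple[BurstTrain, int, np.ndarray]:
    """Select the burst state and binarize it in one step."""
    state, corrs = select_burst_state(posterior, env)
    train = binarize(posterior, state, threshold, epochs)
    return train, state, corrs
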