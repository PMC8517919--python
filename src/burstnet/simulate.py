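"""Synthetic regional recordings with planted burst structure.

The generator emulates source-space MEG-style data: per region, a 1/f
coloured background at unit variance plus transient, beta-dominant burst
packets (a Tukey-windowed carrier drawn from the beta band with a small
broadband component). Burst placement is a point process whose pairwise
co-occurrence is controlled explicitly, so the Jaccard coincidence ground
truth is known by construction. A "patient" group carries planted effects:
lower burst amplitude, lower pairwise coincidence (with occupancy held
fixed at rest), and blunted movement-locked modulation of burst
probability in the task.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal.windows import tukey

from .containers import RegionalRecording


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class TaskProfile:
    """Piecewise-constant burst-rate multiplier around a button press.

    ``windows`` is a list of (t_lo, t_hi, multiplier) in seconds relative to
    the press; the multiplier is ``baseline`` (1) outside all windows. The
    default plants movement-related suppression around the press and a
    rebound elevation at 0.45-0.85 s.
    """

    windows: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(-0.3, 0.1, 0.2), (0.45, 0.85, 2.0)])
    baseline: float = 1.0

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full(t.shape, self.baseline)
        for lo, hi, m in self.windows:
            out = np.where((t >= lo) & (t < hi), m, out)
        return out

    @property
    def max_multiplier(self) -> float:
        return max([self.baseline] + [m for _, _, m in self.windows])

    def blunted(self, factor: float) -> "TaskProfile":
        """Shrink the deviation from baseline by ``factor`` (patient profile)."""
        return TaskProfile(
            windows=[(lo, hi, self.baseline + factor * (m - self.baseline))
                     for lo, hi, m in self.windows],
            baseline=self.baseline)


def uniform_coincidence(n_regions: int, total_shared_fraction: float = 0.6
                        ) -> np.ndarray:
    """Uniform pairwise co-occurrence matrix.

    Each region shares a fraction ``total_shared_fraction`` of its burst
    events equally across the other regions, so every off-diagonal entry is
    ``total_shared_fraction / (n_regions - 1)`` and row sums stay below 1.
    """
    if n_regions < 2:
        return np.eye(max(n_regions, 1))
    c = total_shared_fraction / (n_regions - 1)
    C = np.full((n_regions, n_regions), c)
    np.fill_diagonal(C, 1.0)
    return C


@dataclass
class SimulationConfig:
    """Parameters of the synthetic burst generator.

    Defaults follow the study conditions the pipeline is aimed at: 78
    regions, recordings resampled to 100 Hz, 10 s resting epochs, bursts of
    ~0.3 s mean duration at 0.6 visits/s (planted occupancy ~0.18, below
    the saturation bound), beta-band carriers, and a patient group with
    burst amplitude scaled by 0.8 and pairwise coincidence by 0.7.
    """

    n_regions: int = 78
    fs: float = 100.0
    epoch_length_s: float = 10.0
    n_epochs: int = 24
    burst_rate_hz: float = 0.6
    burst_duration_mean_s: float = 0.3
    burst_duration_sigma: float = 0.4     # log-space SD of log-normal durations
    burst_amplitude: float = 3.0          # relative to unit-variance background
    subject_amplitude_sd: float = 0.15    # log-space between-subject jitter
    coincidence_matrix: np.ndarray | None = None
    group_amplitude_factor: float = 0.8
    group_coincidence_factor: float = 0.7
    group_modulation_factor: float = 0.5
    task_profile: TaskProfile = field(default_factory=TaskProfile)
    noise_exponent: float = 1.0
    carrier_band: tuple[float, float] = (13.0, 30.0)
    broadband_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.burst_rate_hz < 0:
            raise ValueError("burst_rate_hz must be >= 0")
        if self.burst_rate_hz * self.burst_duration_mean_s >= 1:
            raise ValueError(
                "occupancy saturation: burst_rate_hz x mean duration must be < 1")
        for name in ("group_amplitude_factor", "group_coincidence_factor",
                     "group_modulation_factor"):
            v = getattr(self, name)
            if not 0 <= v:
                raise ValueError(f"{name} must be non-negative")
        if self.coincidence_matrix is None:
            self.coincidence_matrix = uniform_coincidence(self.n_regions)
        C = np.asarray(self.coincidence_matrix, dtype=float)
        if C.shape != (self.n_regions, self.n_regions):
            raise ValueError("coincidence_matrix shape mismatch")
        if not np.allclose(C, C.T):
            raise ValueError("coincidence_matrix must be symmetric")
        if not np.allclose(np.diag(C), 1.0):
            raise ValueError("coincidence_matrix diagonal must be 1")
        if np.any(C < 0) or np.any(C > 1):
            raise ValueError("co-occurrence probabilities must lie in [0, 1]")
        off = C - np.diag(np.diag(C))
        if np.any(off.sum(axis=1) > 1.0 + 1e-12):
            raise ValueError(
                "row sums of off-diagonal co-occurrence must not exceed 1")
        self.coincidence_matrix = C
        lo, hi = self.carrier_band
        if not 0 < lo < hi:
            raise ValueError("carrier_band must satisfy 0 < low < high")
        if hi >= self.fs / 2:
            raise ValueError("carrier_band upper edge must be below Nyquist")

    @property
    def n_samples(self) -> int:
        return int(round(self.n_epochs * self.epoch_length_s * self.fs))

    @property
    def epochs(self) -> list[tuple[int, int]]:
        per = int(round(self.epoch_length_s * self.fs))
        return [(i * per, (i + 1) * per) for i in range(self.n_epochs)]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class SubjectTruth:
    """Planted burst structure for one synthetic subject."""

    subject_id: str
    group: str
    visits: list[list[tuple[int, int]]]          # per region, merged intervals
    visit_amplitudes: list[list[float]]          # per region, per merged visit
    coincidence: np.ndarray                      # planted pairwise co-occurrence
    amplitude_scale: float                       # effective burst amplitude
    events: list[int] | None = None
    profile: TaskProfile | None = None

    @property
    def mean_coincidence(self) -> float:
        C = self.coincidence
        iu = np.triu_indices(C.shape[0], k=1)
        return float(C[iu].mean()) if iu[0].size else 0.0

    def occupancy(self, region: int, n_samples: int) -> float:
        return sum(hi - lo for lo, hi in self.visits[region]) / n_samples


@dataclass
class GroundTruth:
    """Planted structure for a whole simulated cohort."""

    subjects: list[SubjectTruth]
    config: SimulationConfig
    symptom_scores: dict[str, float] | None = None

    def covariates(self) -> np.ndarray:
        """Per-subject planted severity covariate (mean planted coincidence)."""
        return np.array([s.mean_coincidence for s in self.subjects])

    def trains(self, subject: SubjectTruth, n_samples: int, fs: float,
               epochs: Sequence[tuple[int, int]] | None = None):
        """Planted visits as BurstTrain objects (ground-truth burst trains)."""
        from .containers import BurstTrain
        return [BurstTrain.from_visits(f"R{r:02d}", subject.visits[r],
                                       n_samples, fs, epochs)
                for r in range(len(subject.visits))]


# ---------------------------------------------------------------------------
# low-level pieces
# ---------------------------------------------------------------------------

def colored_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance noise with power spectral density ~ 1/f**exponent."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    nz = f > 0
    shape[nz] = f[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def burst_packet(n: int, fs: float, carrier_hz: float, phase: float,
                 broadband_fraction: float, rng: np.random.Generator
                 ) -> np.ndarray:
    """Amplitude-modulated carrier packet with a small broadband component."""
    t = np.arange(n) / fs
    win = tukey(n, alpha=0.5)
    carrier = np.cos(2 * np.pi * carrier_hz * t + phase)
    bb = rng.standard_normal(n)
    bb_sd = bb.std()
    if bb_sd > 0:
        bb = bb / bb_sd
    return win * (carrier + broadband_fraction * bb)


def _merge_events(events: list[tuple[int, int, float]]
                  ) -> tuple[list[tuple[int, int]], list[float]]:
    """Merge overlapping (start, end, amplitude) into disjoint visits.

    The amplitude recorded for a merged visit is the maximum of its parts.
    """
    if not events:
        return [], []
    events = sorted(events)
    merged: list[tuple[int, int]] = []
    amps: list[float] = []
    cur_lo, cur_hi, cur_amp = events[0]
    for lo, hi, amp in events[1:]:
        if lo < cur_hi:
            cur_hi = max(cur_hi, hi)
            cur_amp = max(cur_amp, amp)
        else:
            merged.append((cur_lo, cur_hi))
            amps.append(cur_amp)
            cur_lo, cur_hi, cur_amp = lo, hi, amp
    merged.append((cur_lo, cur_hi))
    amps.append(cur_amp)
    return merged, amps


def _duration_samples(cfg: SimulationConfig, rng: np.random.Generator) -> int:
    mu = math.log(cfg.burst_duration_mean_s) - cfg.burst_duration_sigma ** 2 / 2
    d = rng.lognormal(mu, cfg.burst_duration_sigma)
    return max(3, int(round(d * cfg.fs)))


def _subject_coincidence(cfg: SimulationConfig, group: str) -> np.ndarray:
    C = cfg.coincidence_matrix.copy()
    if group == "patient":
        off = ~np.eye(cfg.n_regions, dtype=bool)
        C[off] = C[off] * cfg.group_coincidence_factor
    return C


def _event_catalogue_resting(cfg: SimulationConfig, C: np.ndarray,
                             compensate_occupancy: bool,
                             rng: np.random.Generator
                             ) -> list[list[tuple[int, int]]]:
    """Draw burst intervals per region: shared per-pair events + independent.

    Shared events for pair (i, j) occur at rate ``rate * C[i, j]`` and place
    an identical interval in both regions, giving direct control of the
    planted co-occurrence. The independent rate makes each region's total
    event rate equal ``burst_rate_hz`` (so a patient coincidence deficit
    does not change occupancy).
    """
    R, rate = cfg.n_regions, cfg.burst_rate_hz
    per_region: list[list[tuple[int, int]]] = [[] for _ in range(R)]
    if rate == 0:
        return per_region
    epochs = cfg.epochs
    off = C - np.diag(np.diag(C))
    shared_row = off.sum(axis=1)
    if compensate_occupancy:
        indep_rate = rate * (1.0 - shared_row)
    else:
        base_off = cfg.coincidence_matrix - np.eye(R)
        indep_rate = rate * (1.0 - base_off.sum(axis=1))
    indep_rate = np.clip(indep_rate, 0.0, None)

    def draw(rate_hz: float, targets: tuple[int, ...]) -> None:
        for lo, hi in epochs:
            span = hi - lo
            k = rng.poisson(rate_hz * span / cfg.fs)
            for _ in range(k):
                d = _duration_samples(cfg, rng)
                if d >= span:
                    d = span - 1
                start = lo + int(rng.integers(0, span - d))
                for r in targets:
                    per_region[r].append((start, start + d))

    for i in range(R):
        for j in range(i + 1, R):
            if off[i, j] > 0:
                draw(rate * off[i, j], (i, j))
    for r in range(R):
        if indep_rate[r] > 0:
            draw(indep_rate[r], (r,))
    return per_region


def _render_subject(cfg: SimulationConfig, subject_id: str, group: str,
                    intervals: list[list[tuple[int, int]]],
                    C: np.ndarray, rng: np.random.Generator,
                    events: list[int] | None = None,
                    profile: TaskProfile | None = None,
                    n_samples: int | None = None,
                    epochs: list[tuple[int, int]] | None = None
                    ) -> tuple[RegionalRecording, SubjectTruth]:
    """Render background + burst packets and record the ground truth."""
    T = cfg.n_samples if n_samples is None else n_samples
    epochs = cfg.epochs if epochs is None else epochs
    amp_scale = cfg.burst_amplitude * math.exp(
        rng.normal(0.0, cfg.subject_amplitude_sd))
    if group == "patient":
        amp_scale *= cfg.group_amplitude_factor

    data = np.empty((cfg.n_regions, T))
    visits: list[list[tuple[int, int]]] = []
    visit_amps: list[list[float]] = []
    lo_f, hi_f = cfg.carrier_band
    for r in range(cfg.n_regions):
        x = colored_noise(T, cfg.noise_exponent, rng)
        ev: list[tuple[int, int, float]] = []
        for (s, e) in intervals[r]:
            amp = amp_scale * math.exp(rng.normal(0.0, 0.1))
            f_c = rng.uniform(lo_f, hi_f)
            phase = rng.uniform(0, 2 * np.pi)
            packet = burst_packet(e - s, cfg.fs, f_c, phase,
                                  cfg.broadband_fraction, rng)
            x[s:e] += amp * packet
            ev.append((s, e, amp))
        merged, amps = _merge_events(ev)
        visits.append(merged)
        visit_amps.append(amps)
        data[r] = x

    labels = [f"R{r:02d}" for r in range(cfg.n_regions)]
    rec = RegionalRecording(subject_id=subject_id, group=group, fs=cfg.fs,
                            region_labels=labels, data=data, epochs=epochs,
                            events=events)
    truth = SubjectTruth(subject_id=subject_id, group=group, visits=visits,
                         visit_amplitudes=visit_amps, coincidence=C,
                         amplitude_scale=amp_scale, events=events,
                         profile=profile)
    return rec, truth


# ---------------------------------------------------------------------------
# public generators
# ---------------------------------------------------------------------------

def simulate_resting(config: SimulationConfig, n_per_group: int
                     ) -> tuple[list[RegionalRecording], GroundTruth]:
    """Simulate a resting-state cohort (controls first, then patients)."""
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * n_per_group)
    recs: list[RegionalRecording] = []
    subjects: list[SubjectTruth] = []
    idx = 0
    for group, prefix in (("control", "ctl"), ("patient", "pat")):
        for k in range(n_per_group):
            rng = np.random.default_rng(children[idx]); idx += 1
            C = _subject_coincidence(config, group)
            intervals = _event_catalogue_resting(
                config, C, compensate_occupancy=True, rng=rng)
            rec, truth = _render_subject(
                config, f"{prefix}{k:03d}", group, intervals, C, rng)
            recs.append(rec)
            subjects.append(truth)
    return recs, GroundTruth(subjects=subjects, config=config)


def _task_layout(config: SimulationConfig, n_trials: int,
                 rng: np.random.Generator) -> tuple[int, list[int]]:
    """Event sample indices with 3 s half-windows and jittered 0.8-1.2 s ISIs."""
    fs = config.fs
    half = int(round(3.0 * fs))
    events: list[int] = []
    cursor = half
    for _ in range(n_trials):
        events.append(cursor)
        isi = rng.uniform(0.8, 1.2)
        cursor += 2 * half + int(round(isi * fs))
    T = events[-1] + half if events else 0
    return T, events


def _event_catalogue_task(config: SimulationConfig, C: np.ndarray,
                          profile: TaskProfile, T: int, events: list[int],
                          rng: np.random.Generator
                          ) -> list[list[tuple[int, int]]]:
    """Burst intervals whose *centre* rate follows the task profile.

    Candidate centres are drawn from a homogeneous process at the profile's
    maximum rate and thinned by the profile value at the centre (relative to
    the nearest press), so burst probability is modulated symmetrically
    around the planted windows.
    """
    R, rate, fs = config.n_regions, config.burst_rate_hz, config.fs
    per_region: list[list[tuple[int, int]]] = [[] for _ in range(R)]
    if rate == 0 or T == 0:
        return per_region
    ev = np.asarray(events)
    mmax = profile.max_multiplier

    def rel_time(centres: np.ndarray) -> np.ndarray:
        # time of each centre relative to the nearest press
        i = np.searchsorted(ev, centres)
        i = np.clip(i, 1, len(ev) - 1) if len(ev) > 1 else np.zeros_like(i)
        left = ev[np.maximum(i - 1, 0)]
        right = ev[np.minimum(i, len(ev) - 1)]
        nearest = np.where(np.abs(centres - left) <= np.abs(centres - right),
                           left, right)
        return (centres - nearest) / fs

    def draw(rate_hz: float, targets: tuple[int, ...]) -> None:
        n_cand = rng.poisson(rate_hz * mmax * T / fs)
        centres = rng.uniform(0, T, size=n_cand)
        keep = rng.uniform(0, mmax, size=n_cand) < profile(rel_time(centres))
        for c in np.sort(centres[keep]):
            d = _duration_samples(config, rng)
            s = int(round(c - d / 2))
            e = s + d
            if s < 0 or e > T:
                continue
            for r in targets:
                per_region[r].append((s, e))

    off = C - np.diag(np.diag(C))
    for i in range(R):
        for j in range(i + 1, R):
            if off[i, j] > 0:
                draw(rate * off[i, j], (i, j))
    indep = np.clip(rate * (1.0 - off.sum(axis=1)), 0.0, None)
    for r in range(R):
        if indep[r] > 0:
            draw(indep[r], (r,))
    return per_region


def simulate_task(config: SimulationConfig, n_trials: int, n_per_group: int
                  ) -> tuple[list[RegionalRecording], GroundTruth]:
    """Simulate a motor-task cohort with presses and modulated bursting."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 * n_per_group)
    recs: list[RegionalRecording] = []
    subjects: list[SubjectTruth] = []
    idx = 0
    for group, prefix in (("control", "ctl"), ("patient", "pat")):
        profile = (config.task_profile if group == "control"
                   else config.task_profile.blunted(config.group_modulation_factor))
        for k in range(n_per_group):
            rng = np.random.default_rng(children[idx]); idx += 1
            C = _subject_coincidence(config, group)
            T, events = _task_layout(config, n_trials, rng)
            intervals = _event_catalogue_task(config, C, profile, T, events, rng)
            rec, truth = _render_subject(
                config, f"{prefix}{k:03d}", group, intervals, C, rng,
                events=events, profile=profile, n_samples=T,
                epochs=[(0, T)])
            recs.append(rec)
            subjects.append(truth)
    return recs, GroundTruth(subjects=subjects, config=config)


def sample_symptom_scores(ground_truth: GroundTruth, slope: float,
                          noise_sd: float, seed: int,
                          baseline: float = 12.0) -> dict[str, float]:
    """Symptom-severity scores negatively related to planted connectivity.

    ``score = baseline - slope * z(covariate) + noise``, truncated at 0,
    where the covariate is each subject's planted mean pairwise coincidence
    (lower in patients, so patients score stochastically higher).
    """
    rng = np.random.default_rng(seed)
    cov = ground_truth.covariates()
    sd = cov.std()
    z = (cov - cov.mean()) / sd if sd > 0 else np.zeros_like(cov)
    scores = baseline - slope * z + rng.normal(0.0, noise_sd, size=len(cov))
    scores = np.clip(scores, 0.0, None)
    out = {s.subject_id: float(v)
           for s, v in zip(ground_truth.subjects, scores)}
    ground_truth.symptom_scores = out
    return out


def attach_symptom_scores(recordings: list[RegionalRecording],
                          scores: dict[str, float]) -> list[RegionalRecording]:
    """Return copies of the recordings with symptom scores filled in."""
    return [r.copy_with(symptom_score=scores[r.subject_id]) for r in recordings]
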