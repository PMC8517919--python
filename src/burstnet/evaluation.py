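"""Planted-effect recovery and calibration studies on synthetic cohorts.

These routines run the pipeline's stages over many simulated cohorts with
known ground truth and measure how reliably the planted group effects are
recovered and how well the statistical machinery is calibrated. Burst
trains come from the generator's planted visits (the HMM detection path is
validated separately against planted bursts at small scale), so these
studies exercise generator -> burst metrics -> connectivity -> statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bursts, task
from .conditioning import standardize
from .connectivity import connectome, global_mean_connectivity
from .simulate import SimulationConfig, simulate_resting, simulate_task
from .stats import wilcoxon_rank_sum


def _derive_seed(base: int, offset: int) -> int:
    return int((base * 100003 + offset) % (2 ** 31))


# ---------------------------------------------------------------------------
# resting-state planted effects
# ---------------------------------------------------------------------------

@dataclass
class RestingRecovery:
    """Rejection/direction rates over seeds for the resting group tests."""

    amplitude_rejection_rate: float
    connectivity_rejection_rate: float
    amplitude_direction_rate: float
    connectivity_direction_rate: float
    amplitude_envelope_corr: float     # burst amplitude vs mean envelope
    n_seeds: int
    n_per_group: int


def resting_cohort_metrics(cfg: SimulationConfig, n_per_group: int
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                      np.ndarray]:
    """Global burst amplitude, mean envelope, global connectivity per subject.

    Returns ``(groups, amplitude, mean_envelope, connectivity)``.
    """
    recs, gt = simulate_resting(cfg, n_per_group)
    amp, menv, conn, grp = [], [], [], []
    for rec, st in zip(recs, gt.subjects):
        rec = standardize(rec)
        trains = gt.trains(st, rec.n_samples, rec.fs, rec.epochs)
        envs = bursts.beta_envelopes(rec.data, rec.fs,
                                     region_ids=rec.region_labels)
        summaries = [bursts.summarize(t, e) for t, e in zip(trains, envs)]
        means, _ = bursts.global_collapse(summaries)
        amp.append(means["burst_amplitude"])
        menv.append(float(np.mean([e.env.mean() for e in envs])))
        conn.append(global_mean_connectivity(connectome(trains)))
        grp.append(rec.group)
    return (np.array(grp), np.array(amp), np.array(menv), np.array(conn))


def resting_recovery(n_seeds: int = 100, n_per_group: int = 20,
                     n_regions: int = 10, n_epochs: int = 10,
                     seed: int = 0, alpha: float = 0.05) -> RestingRecovery:
    """Planted-effect recovery for the resting workflow.

    Patients carry the configured amplitude (x0.8) and coincidence (x0.7)
    deficits; each seed simulates a fresh cohort and runs the global
    burst-amplitude and global-connectivity rank-sum tests.
    """
    rej_a = rej_c = dir_a = dir_c = 0
    all_amp, all_env = [], []
    for s in range(n_seeds):
        cfg = SimulationConfig(n_regions=n_regions, n_epochs=n_epochs,
                               seed=_derive_seed(seed, s))
        grp, amp, menv, conn = resting_cohort_metrics(cfg, n_per_group)
        pat, ctl = grp == "patient", grp == "control"
        _, pa = wilcoxon_rank_sum(amp[pat], amp[ctl])
        _, pc = wilcoxon_rank_sum(conn[pat], conn[ctl])
        rej_a += pa <= alpha
        rej_c += pc <= alpha
        dir_a += amp[pat].mean() < amp[ctl].mean()
        dir_c += conn[pat].mean() < conn[ctl].mean()
        all_amp.extend(amp)
        all_env.extend(menv)
    r = float(np.corrcoef(all_amp, all_env)[0, 1])
    return RestingRecovery(
        amplitude_rejection_rate=rej_a / n_seeds,
        connectivity_rejection_rate=rej_c / n_seeds,
        amplitude_direction_rate=dir_a / n_seeds,
        connectivity_direction_rate=dir_c / n_seeds,
        amplitude_envelope_corr=r, n_seeds=n_seeds, n_per_group=n_per_group)


# ---------------------------------------------------------------------------
# task planted effects
# ---------------------------------------------------------------------------

@dataclass
class TaskRecovery:
    """Direction-recovery rates for the task contrasts."""

    modulation_direction_rate: float
    amplitude_direction_rate: float
    coincidence_direction_rate: float
    n_seeds: int
    n_per_group: int


def task_cohort_metrics(cfg: SimulationConfig, n_trials: int,
                        n_per_group: int
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                   np.ndarray]:
    """Modulation, PMBR amplitude, and PMBR coincidence per subject."""
    recs, gt = simulate_task(cfg, n_trials, n_per_group)
    mod, amp, coin, grp = [], [], [], []
    for rec, st in zip(recs, gt.subjects):
        rec = standardize(rec)
        trains = gt.trains(st, rec.n_samples, rec.fs, rec.epochs)
        envs = bursts.beta_envelopes(rec.data, rec.fs,
                                     region_ids=rec.region_labels)
        t0 = task.epoch_trials(trains[0], envs[0], rec.events)
        t1 = task.epoch_trials(trains[1], envs[1], rec.events)
        ws = task.window_burst_stats(t0)
        mod.append(ws.modulation)
        amp.append(ws.pmbr_amplitude)
        coin.append(task.window_coincidence(t0, t1))
        grp.append(rec.group)
    return np.array(grp), np.array(mod), np.array(amp), np.array(coin)


def task_recovery(n_seeds: int = 100, n_per_group: int = 20,
                  n_trials: int = 30, seed: int = 0) -> TaskRecovery:
    """Direction recovery of the planted task deficits (patients lower)."""
    d_mod = d_amp = d_coin = 0
    for s in range(n_seeds):
        cfg = SimulationConfig(n_regions=2, seed=_derive_seed(seed, 70000 + s))
        grp, mod, amp, coin = task_cohort_metrics(cfg, n_trials, n_per_group)
        pat, ctl = grp == "patient", grp == "control"
        d_mod += np.nanmean(mod[pat]) < np.nanmean(mod[ctl])
        d_amp += np.nanmean(amp[pat]) < np.nanmean(amp[ctl])
        d_coin += np.nanmean(coin[pat]) < np.nanmean(coin[ctl])
    return TaskRecovery(modulation_direction_rate=d_mod / n_seeds,
                        amplitude_direction_rate=d_amp / n_seeds,
                        coincidence_direction_rate=d_coin / n_seeds,
                        n_seeds=n_seeds, n_per_group=n_per_group)


# ---------------------------------------------------------------------------
# two-regime autoregressive benchmark for the HMM
# ---------------------------------------------------------------------------

def two_regime_series(T: int, fs: float, rng: np.random.Generator,
                      mean_regime_s: float = 1.0
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Alternating low-pass AR(1) and beta-resonant AR(2) regimes.

    Returns ``(x, labels)`` with labels 0 (low-pass) / 1 (beta). Regime
    lengths are exponential with the given mean.
    """
    labels = np.zeros(T, dtype=int)
    state, t = 0, 0
    while t < T:
        length = max(int(rng.exponential(mean_regime_s * fs)), int(0.3 * fs))
        labels[t: t + length] = state
        state = 1 - state
        t += length
    x = np.zeros(T)
    e = rng.standard_normal(T)
    r, theta = 0.95, 2 * np.pi * 20.0 / fs
    a1, a2 = 2 * r * np.cos(theta), -r ** 2
    for t in range(2, T):
        if labels[t] == 0:
            x[t] = 0.9 * x[t - 1] + e[t]
        else:
            x[t] = a1 * x[t - 1] + a2 * x[t - 2] + 0.5 * e[t]
    x = (x - x.mean()) / x.std()
    return x, labels


def hmm_state_recovery(n_seeds: int = 10, T: int = 3000, fs: float = 100.0,
                       seed: int = 0) -> float:
    """Mean decoded-state agreement with ground truth on two-regime data.

    Fits a K=2 embedded HMM per seed and scores the posterior-decoded state
    sequence against the planted regime labels after optimal label
    matching.
    """
    from .hmm import HMMConfig, fit

    agreements = []
    for s in range(n_seeds):
        rng = np.random.default_rng(_derive_seed(seed, 50000 + s))
        x, labels = two_regime_series(T, fs, rng)
        cfg = HMMConfig(n_states=2, seed=_derive_seed(seed, 60000 + s),
                        n_restarts=2, max_iter=50)
        post = fit(x, fs, cfg)
        decoded = np.argmax(post.gamma, axis=0)
        truth = labels[post.sample_indices]
        agree = max(float(np.mean(decoded == truth)),
                    float(np.mean((1 - decoded) == truth)))
        agreements.append(agree)
    return float(np.mean(agreements))


# ---------------------------------------------------------------------------
# statistical calibration
# ---------------------------------------------------------------------------

def ranksum_type1_rate(n_sims: int = 2000, n: int = 20, alpha: float = 0.05,
                       seed: int = 0) -> float:
    """Empirical type-I error of the rank-sum test under the Gaussian null."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        _, p = wilcoxon_rank_sum(x, y)
        hits += p <= alpha
    return hits / n_sims


def null_auc_calibration(n_seeds: int = 100, n_subjects: int = 20,
                         n_features: int = 40, seed: int = 0,
                         cfg=None) -> tuple[float, float]:
    """Mean and SD of the cross-validated AUC on label-independent features."""
    from .classify import ClassifierConfig, FeatureTable, svm_cv

    cfg = cfg or ClassifierConfig(n_folds=5, n_trees=30, n_resamples=3,
                                  importance="impurity", max_recursion=3)
    aucs = []
    for s in range(n_seeds):
        rng = np.random.default_rng(_derive_seed(seed, 80000 + s))
        X = rng.standard_normal((n_subjects, n_features))
        y = np.arange(n_subjects) % 2
        ft = FeatureTable(X=X, y=y,
                          feature_names=[f"f{i}" for i in range(n_features)],
                          subject_ids=[f"s{i}" for i in range(n_subjects)])
        aucs.append(svm_cv(ft, cfg, seed=_derive_seed(seed, 90000 + s)).mean_auc)
    return float(np.mean(aucs)), float(np.std(aucs, ddof=1))


def null_permutation_pvalues(n_runs: int = 30, n_perm: int = 15,
                             n_subjects: int = 12, n_features: int = 20,
                             seed: int = 0) -> np.ndarray:
    """Permutation-test p-values on null data (should be ~uniform)."""
    from .classify import ClassifierConfig, FeatureTable, permutation_test

    cfg = ClassifierConfig(n_folds=3, n_trees=15, n_resamples=2,
                           importance="impurity", max_recursion=2)
    ps = []
    for s in range(n_runs):
        rng = np.random.default_rng(_derive_seed(seed, 95000 + s))
        X = rng.standard_normal((n_subjects, n_features))
        y = np.arange(n_subjects) % 2
        ft = FeatureTable(X=X, y=y,
                          feature_names=[f"f{i}" for i in range(n_features)],
                          subject_ids=[f"s{i}" for i in range(n_subjects)])
        res = permutation_test(ft, cfg, n_perm=n_perm,
                               seed=_derive_seed(seed, 97000 + s))
        ps.append(res.permutation_p)
    return np.asarray(ps)
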