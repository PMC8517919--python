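"""Univariate time-delay-embedded hidden Markov model.

Each regional time course is lag-embedded over a short window (230 ms by
default) and modelled with a K-state HMM whose states are zero-mean
Gaussians with full covariance over the embedded vector. A state is thus
characterised by an autocovariance pattern — i.e. a spectro-temporal
signature — which is what lets one state latch onto transient pan-spectral
bursts. Inference is maximum-likelihood EM (Baum-Welch) with scaled
forward-backward recursions, random restarts, and a k-means-based
initialisation; regions are always fit independently of one another.

Means are fixed at zero because the series are standardized before
fitting; all state structure lives in the covariances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla

from .containers import StatePosterior


@dataclass
class HMMConfig:
    """Settings for the per-region embedded HMM fit."""

    n_states: int = 3
    window_s: float = 0.230
    inference: str = "em"
    max_iter: int = 100
    tol: float = 1e-5          # relative change of log-likelihood
    n_restarts: int = 3
    seed: int = 0
    pca_dims: int | None = None

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("n_states must be >= 2")
        if self.inference != "em":
            raise ValueError("inference must be 'em'")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be >= 1")

    def n_lags(self, fs: float) -> int:
        L = int(round(self.window_s * fs))
        if L < 3:
            raise ValueError("embedding window shorter than 3 samples")
        if L % 2 == 0:
            raise ValueError(
                f"window_s x fs must round to an odd lag count, got {L}")
        return L


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

def embed(x: np.ndarray, fs: float, window_s: float
          ) -> tuple[np.ndarray, np.ndarray]:
    """Time-delay embed a univariate series.

    Returns ``(E, sample_indices)`` where ``E`` is L lags x T' with
    ``E[l, t] = x[t + l]`` (lag ``l - (L-1)/2`` relative to the window
    centre) and ``sample_indices[t]`` is the original sample index of the
    window centre, ``t + (L-1)/2``.
    """
    x = np.asarray(x, dtype=np.float64)
    L = int(round(window_s * fs))
    if L < 3:
        raise ValueError("embedding window shorter than 3 samples")
    if len(x) <= L:
        raise ValueError(f"series of length {len(x)} shorter than window ({L})")
    E = np.lib.stride_tricks.sliding_window_view(x, L).T.copy()
    offset = (L - 1) // 2
    idx = np.arange(E.shape[1]) + offset
    return E, idx


# ---------------------------------------------------------------------------
# scaled recursions (generic: operate on a frame log-likelihood matrix)
# ---------------------------------------------------------------------------

def forward_backward(startprob: np.ndarray, transmat: np.ndarray,
                     framelogprob: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior state probabilities by scaled forward-backward.

    Parameters are linear-domain; ``framelogprob`` is T x K. Returns
    ``(gamma, xi_sum, loglik)`` with ``gamma`` T x K and ``xi_sum`` the
    K x K matrix of expected transition counts.
    """
    T, K = framelogprob.shape
    # scale emissions per frame to avoid under/overflow at any T
    fl = framelogprob - framelogprob.max(axis=1, keepdims=True)
    B = np.exp(fl)
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = startprob * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ transmat) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (transmat @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    if T > 1:
        xi_sum = transmat * (alpha[:-1].T @ (B[1:] * beta[1:] / c[1:, None]))
    else:
        xi_sum = np.zeros((K, K))
    loglik = float(np.log(c).sum() + framelogprob.max(axis=1).sum())
    return gamma, xi_sum, loglik


def viterbi(startprob: np.ndarray, transmat: np.ndarray,
            framelogprob: np.ndarray) -> np.ndarray:
    """Most probable state path; ties resolve to the lowest state index."""
    T, K = framelogprob.shape
    with np.errstate(divide="ignore"):
        log_start = np.log(startprob)
        log_A = np.log(transmat)
    delta = log_start + framelogprob[0]
    psi = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        scores = delta[:, None] + log_A
        psi[t] = np.argmax(scores, axis=0)      # first max -> lowest index
        delta = scores[psi[t], np.arange(K)] + framelogprob[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


# ---------------------------------------------------------------------------
# zero-mean Gaussian emissions
# ---------------------------------------------------------------------------

def _state_loglik(E: np.ndarray, covs: np.ndarray) -> np.ndarray:
    """T' x K log-density of embedded columns under zero-mean Gaussians."""
    L, T = E.shape
    K = covs.shape[0]
    out = np.empty((T, K))
    for k in range(K):
        Lc = np.linalg.cholesky(covs[k])
        z = sla.solve_triangular(Lc, E, lower=True)
        quad = np.einsum("lt,lt->t", z, z)
        logdet = 2.0 * np.log(np.diag(Lc)).sum()
        out[:, k] = -0.5 * (L * np.log(2 * np.pi) + logdet + quad)
    return out


def _safe_cov(S: np.ndarray, n_repairs: list[int]) -> np.ndarray:
    """Return a symmetric positive-definite version of S, jittering if needed."""
    S = 0.5 * (S + S.T)
    jitter = 0.0
    base = max(np.trace(S) / S.shape[0], 1e-12)
    for attempt in range(8):
        try:
            np.linalg.cholesky(S + jitter * np.eye(S.shape[0]))
            if attempt > 0:
                n_repairs[0] += 1
            return S + jitter * np.eye(S.shape[0])
        except np.linalg.LinAlgError:
            jitter = base * 10.0 ** (attempt - 6)
    raise np.linalg.LinAlgError("covariance could not be repaired")


def _kmeans_init(E: np.ndarray, K: int, rng: np.random.Generator
                 ) -> np.ndarray:
    """One-hot responsibilities from a randomized k-means on embedded columns."""
    from sklearn.cluster import KMeans
    T = E.shape[1]
    sub = rng.choice(T, size=min(T, 5000), replace=False)
    km = KMeans(n_clusters=K, n_init=1,
                random_state=int(rng.integers(2 ** 31))).fit(E[:, sub].T)
    labels = km.predict(E.T)
    resp = np.zeros((T, K))
    resp[np.arange(T), labels] = 1.0
    return resp


def _m_step(E: np.ndarray, gamma: np.ndarray, n_repairs: list[int]
            ) -> np.ndarray:
    L, T = E.shape
    K = gamma.shape[1]
    covs = np.empty((K, L, L))
    for k in range(K):
        w = gamma[:, k]
        Nk = w.sum()
        if Nk < 1e-8:
            covs[k] = np.eye(L)
            n_repairs[0] += 1
            continue
        Ew = E * w
        covs[k] = _safe_cov((Ew @ E.T) / Nk, n_repairs)
    return covs


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _embed_epochs(x: np.ndarray, fs: float, window_s: float,
                  epochs: list[tuple[int, int]] | None
                  ) -> tuple[np.ndarray, np.ndarray, list[int]]:
    """Embed each epoch separately; cross-epoch transitions are masked."""
    if epochs is None:
        epochs = [(0, len(x))]
    Es, idxs, lengths = [], [], []
    for lo, hi in epochs:
        seg = x[lo:hi]
        L = int(round(window_s * fs))
        if len(seg) <= L:
            continue
        E, idx = embed(seg, fs, window_s)
        Es.append(E)
        idxs.append(idx + lo)
        lengths.append(E.shape[1])
    if not Es:
        raise ValueError("no epoch longer than the embedding window")
    return np.concatenate(Es, axis=1), np.concatenate(idxs), lengths


def _em_run(E: np.ndarray, lengths: list[int], config: HMMConfig,
            rng: np.random.Generator
            ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray,
                       list[float], bool, int]:
    K = config.n_states
    n_repairs = [0]
    resp = _kmeans_init(E, K, rng)
    covs = _m_step(E, resp, n_repairs)
    transmat = np.full((K, K), 0.1 / max(K - 1, 1))
    np.fill_diagonal(transmat, 0.9)
    startprob = np.full(K, 1.0 / K)

    bounds = np.cumsum([0] + list(lengths))
    trace: list[float] = []
    gamma = resp
    converged = False
    for _ in range(config.max_iter):
        fl = _state_loglik(E, covs)
        gamma = np.empty_like(fl)
        xi_sum = np.zeros((K, K))
        start_acc = np.zeros(K)
        loglik = 0.0
        for s, e in zip(bounds[:-1], bounds[1:]):
            g, x, ll = forward_backward(startprob, transmat, fl[s:e])
            gamma[s:e] = g
            xi_sum += x
            start_acc += g[0]
            loglik += ll
        trace.append(loglik)
        if len(trace) > 1:
            prev = trace[-2]
            if abs(loglik - prev) <= config.tol * abs(prev):
                converged = True
                break
        rows = xi_sum.sum(axis=1, keepdims=True)
        new_A = np.where(rows > 1e-12, xi_sum / np.maximum(rows, 1e-300),
                         transmat)
        transmat = new_A / new_A.sum(axis=1, keepdims=True)
        startprob = start_acc / start_acc.sum()
        covs = _m_step(E, gamma, n_repairs)
    return (gamma, transmat, startprob, covs, trace, converged, n_repairs[0])


def fit(x: np.ndarray, fs: float, config: HMMConfig,
        epochs: list[tuple[int, int]] | None = None,
        region_id: str = "region") -> StatePosterior:
    """Fit the embedded HMM to one regional series.

    Runs ``config.n_restarts`` EM fits from randomized k-means starts and
    keeps the one with the best final log-likelihood. The returned
    posterior's ``sample_indices`` maps embedded columns back to original
    sample indices; the (L-1)/2 samples at each epoch edge are trimmed.
    """
    x = np.asarray(x, dtype=np.float64)
    config.n_lags(fs)   # validates the odd-lag invariant
    E, idx, lengths = _embed_epochs(x, fs, config.window_s, epochs)
    ss = np.random.SeedSequence(config.seed)
    best = None
    for child in ss.spawn(config.n_restarts):
        rng = np.random.default_rng(child)
        run = _em_run(E, lengths, config, rng)
        if best is None or run[4][-1] > best[4][-1]:
            best = run
    gamma, transmat, startprob, covs, trace, converged, n_rep = best
    return StatePosterior(
        region_id=region_id, gamma=gamma.T, transition_matrix=transmat,
        state_covariances=covs, startprob=startprob,
        objective_trace=np.asarray(trace), sample_indices=idx,
        n_samples=len(x), fs=fs, window_s=config.window_s,
        converged=converged, n_collapse_repairs=n_rep)


def decode(posterior: StatePosterior,
           E: np.ndarray | None = None,
           lengths: list[int] | None = None) -> np.ndarray:
    """Viterbi state path under the fitted parameters.

    If the embedded data are not supplied, the path is computed from the
    posterior marginals' log, which coincides with Viterbi when states are
    well separated; supply ``E`` for the exact path.
    """
    if posterior.n_states < 2:
        raise ValueError("decoding requires at least 2 states")
    if E is not None:
        fl = _state_loglik(E, posterior.state_covariances)
    else:
        with np.errstate(divide="ignore"):
            fl = np.log(np.maximum(posterior.gamma.T, 1e-300))
    if lengths is None:
        lengths = [fl.shape[0]]
    bounds = np.cumsum([0] + list(lengths))
    parts = [viterbi(posterior.startprob, posterior.transition_matrix, fl[s:e])
             for s, e in zip(bounds[:-1], bounds[1:])]
    return np.concatenate(parts)
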