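"""Gaussian-emission hidden Markov model with full covariance.

Per-day patient condition is modelled as a latent discrete state chain;
each state emits the day's vector of (normalized, imputed) blood tests and
vital signs from a multivariate normal with a full covariance matrix.
Training is unsupervised Baum-Welch EM on the episode matrices only — no
outcome, diagnosis or phenotype information is ever passed in. All
recursions run in log space: with 23 correlated dimensions and episodes of
up to hundreds of days, scaled arithmetic underflows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.special import logsumexp
from sklearn.cluster import KMeans

__all__ = [
    "HMMParameters",
    "StateDecoding",
    "FitReport",
    "log_emission",
    "forward_backward",
    "fit_em",
    "decode",
]

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class HMMParameters:
    """Initial distribution pi, transition matrix A, and per-state Gaussian
    emission parameters (means, full covariances)."""

    pi: np.ndarray           # (K,)
    A: np.ndarray            # (K, K) row-stochastic
    means: np.ndarray        # (K, D)
    covariances: np.ndarray  # (K, D, D) symmetric positive definite

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]

    @property
    def K(self) -> int:
        return self.means.shape[0]

    @property
    def D(self) -> int:
        return self.means.shape[1]

    def validate(self, atol: float = 1e-10) -> None:
        """Check stochasticity and positive-definiteness; raise ValueError."""
        if self.pi.shape != (self.K,):
            raise ValueError("pi has wrong shape")
        if self.A.shape != (self.K, self.K):
            raise ValueError("A has wrong shape")
        if self.covariances.shape != (self.K, self.D, self.D):
            raise ValueError("covariances have wrong shape")
        if not np.isclose(self.pi.sum(), 1.0, atol=atol):
            raise ValueError("pi does not sum to 1")
        if np.any(self.pi < -atol):
            raise ValueError("pi has negative entries")
        if not np.allclose(self.A.sum(axis=1), 1.0, atol=atol):
            raise ValueError("rows of A do not sum to 1")
        if np.any(self.A < -atol):
            raise ValueError("A has negative entries")
        for k in range(self.K):
            S = self.covariances[k]
            if not np.allclose(S, S.T, atol=1e-8):
                raise ValueError(f"covariance {k} is not symmetric")
            try:
                cholesky(S, lower=True)
            except Exception as exc:
                raise ValueError(f"covariance {k} is not positive definite") from exc

    def permuted(self, perm: np.ndarray) -> "HMMParameters":
        """Relabel states by `perm` (new index i holds old state perm[i])."""
        perm = np.asarray(perm)
        return HMMParameters(
            pi=self.pi[perm],
            A=self.A[np.ix_(perm, perm)],
            means=self.means[perm],
            covariances=self.covariances[perm],
        )

    def to_dict(self) -> dict:
        return {
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    def save(self, path: str | Path, **extra) -> None:
        payload = self.to_dict()
        payload.update(extra)
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_dict(cls, d: dict) -> "HMMParameters":
        return cls(
            pi=np.array(d["pi"]),
            A=np.array(d["A"]),
            means=np.array(d["means"]),
            covariances=np.array(d["covariances"]),
        )

    @classmethod
    def load(cls, path: str | Path) -> "HMMParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class StateDecoding:
    """Per-episode decoding: one state per day plus smoothed posteriors."""

    patient_id: str
    states: np.ndarray   # (T,) ints in [0, K)
    gamma: np.ndarray    # (T, K) posterior state probabilities
    loglik: float


@dataclass
class FitReport:
    loglik_trace: list[float]
    n_iters: int
    converged: bool
    seed: int | None
    init_method: str
    n_restarts: int = 1
    reseeded_states: list[int] = field(default_factory=list)


def _chol_factors(params: HMMParameters) -> list[tuple[np.ndarray, float]]:
    out = []
    for k in range(params.K):
        L = cholesky(params.covariances[k], lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        out.append((L, logdet))
    return out


def log_emission(params: HMMParameters, X: np.ndarray) -> np.ndarray:
    """Log N(x_t; mu_k, Sigma_k) for every day t and state k.

    Parameters
    ----------
    X : (T, D) or (D,) array of complete (imputed) observations.

    Returns
    -------
    (T, K) array of per-state log densities (or (K,) for a single row).
    """
    X = np.asarray(X, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != params.D:
        raise ValueError(f"expected {params.D} columns, got {X.shape[1]}")
    if not np.all(np.isfinite(X)):
        raise ValueError("observations must be finite (impute first)")
    T = X.shape[0]
    out = np.empty((T, params.K))
    for k, (L, logdet) in enumerate(_chol_factors(params)):
        z = solve_triangular(L, (X - params.means[k]).T, lower=True)
        out[:, k] = -0.5 * (params.D * _LOG2PI + logdet + np.sum(z * z, axis=0))
    return out[0] if single else out


def forward_backward(
    params: HMMParameters, X: np.ndarray, patient_id: str = ""
) -> tuple[StateDecoding, np.ndarray]:
    """Log-space forward-backward smoothing.

    Returns the decoding (gamma posteriors, episode log-likelihood; the
    ``states`` field holds the per-day posterior argmax) and the summed
    pairwise posterior matrix needed by the EM transition update.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T = X.shape[0]
    if T == 0:
        raise ValueError("empty episode")
    K = params.K
    logB = np.atleast_2d(log_emission(params, X))
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = np.log(params.A)

    log_alpha = np.empty((T, K))
    log_alpha[0] = logpi + logB[0]
    for t in range(1, T):
        log_alpha[t] = logB[t] + logsumexp(log_alpha[t - 1][:, None] + logA, axis=0)
    loglik = float(logsumexp(log_alpha[-1]))

    log_beta = np.zeros((T, K))
    for t in range(T - 2, -1, -1):
        log_beta[t] = logsumexp(logA + (logB[t + 1] + log_beta[t + 1])[None, :], axis=1)

    log_gamma = log_alpha + log_beta
    log_gamma -= logsumexp(log_gamma, axis=1, keepdims=True)
    gamma = np.exp(log_gamma)

    xi_sum = np.zeros((K, K))
    for t in range(T - 1):
        log_xi = (
            log_alpha[t][:, None]
            + logA
            + (logB[t + 1] + log_beta[t + 1])[None, :]
            - loglik
        )
        xi_sum += np.exp(log_xi)

    dec = StateDecoding(
        patient_id=patient_id,
        states=np.argmax(gamma, axis=1),
        gamma=gamma,
        loglik=loglik,
    )
    return dec, xi_sum


def _viterbi(params: HMMParameters, X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    T, K = X.shape[0], params.K
    logB = np.atleast_2d(log_emission(params, X))
    with np.errstate(divide="ignore"):
        logpi = np.log(params.pi)
        logA = np.log(params.A)
    delta = logpi + logB[0]
    back = np.zeros((T, K), dtype=int)
    for t in range(1, T):
        scores = delta[:, None] + logA
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def decode(
    params: HMMParameters,
    X: np.ndarray,
    method: str = "viterbi",
    patient_id: str = "",
) -> StateDecoding:
    """Assign one state per day: jointly most probable path ("viterbi",
    default) or per-day posterior argmax ("posterior")."""
    if method not in ("viterbi", "posterior"):
        raise ValueError(f"unknown decoding method: {method!r}")
    dec, _ = forward_backward(params, X, patient_id=patient_id)
    if method == "viterbi":
        dec.states = _viterbi(params, X)
    return dec


def _init_params(
    episodes: list[np.ndarray],
    K: int,
    init_method: str,
    cov_reg: float,
    rng: np.random.Generator,
) -> HMMParameters:
    X = np.vstack(episodes)
    N, D = X.shape
    pooled_cov = np.cov(X, rowvar=False) if N > 1 else np.eye(D)
    pooled_cov = np.atleast_2d(pooled_cov) + cov_reg * np.eye(D)
    if init_method == "kmeans" and K > 1:
        km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31)))
        labels = km.fit_predict(X)
        means = km.cluster_centers_.copy()
        covs = np.empty((K, D, D))
        for k in range(K):
            sub = X[labels == k]
            if sub.shape[0] > D:
                covs[k] = np.cov(sub, rowvar=False) + cov_reg * np.eye(D)
            else:
                covs[k] = pooled_cov
    elif init_method == "random" or K == 1:
        idx = rng.choice(N, size=K, replace=False)
        means = X[idx].copy()
        covs = np.repeat(pooled_cov[None], K, axis=0)
    else:
        raise ValueError(f"unknown init method: {init_method!r}")
    pi = np.full(K, 1.0 / K)
    A = np.full((K, K), 0.2 / K) + 0.8 * np.eye(K)
    A /= A.sum(axis=1, keepdims=True)
    return HMMParameters(pi=pi, A=A, means=means, covariances=covs)


def _em_single(
    episodes: list[np.ndarray],
    K: int,
    init_method: str,
    tol: float,
    max_iter: int,
    cov_reg: float,
    rng: np.random.Generator,
) -> tuple[HMMParameters, list[float], bool, list[int]]:
    X_all = np.vstack(episodes)
    D = X_all.shape[1]
    pooled_cov = np.atleast_2d(np.cov(X_all, rowvar=False)) + cov_reg * np.eye(D)
    params = _init_params(episodes, K, init_method, cov_reg, rng)
    trace: list[float] = []
    reseeded: list[int] = []
    converged = False
    eye = np.eye(D)
    for _ in range(max_iter):
        pi_acc = np.zeros(K)
        xi_acc = np.zeros((K, K))
        Nk = np.zeros(K)
        xsum = np.zeros((K, D))
        Sk = np.zeros((K, D, D))
        total_ll = 0.0
        for ep in episodes:
            dec, xi = forward_backward(params, ep)
            total_ll += dec.loglik
            g = dec.gamma
            pi_acc += g[0]
            xi_acc += xi
            Nk += g.sum(axis=0)
            xsum += g.T @ ep
            for k in range(K):
                Sk[k] += (g[:, k : k + 1] * ep).T @ ep
        trace.append(total_ll)

        # M-step
        pi = pi_acc / pi_acc.sum()
        row = xi_acc.sum(axis=1, keepdims=True)
        A = np.where(row > 0, xi_acc / np.where(row > 0, row, 1.0), 1.0 / K)
        A /= A.sum(axis=1, keepdims=True)
        means = params.means.copy()
        covs = params.covariances.copy()
        for k in range(K):
            if Nk[k] < 1e-8:
                # degenerate state: re-seed from a random pooled day
                reseeded.append(k)
                means[k] = X_all[rng.integers(X_all.shape[0])]
                covs[k] = pooled_cov
                continue
            mu = xsum[k] / Nk[k]
            S = Sk[k] / Nk[k] - np.outer(mu, mu)
            S = 0.5 * (S + S.T) + cov_reg * eye
            try:
                cholesky(S, lower=True)
            except Exception:
                reseeded.append(k)
                means[k] = X_all[rng.integers(X_all.shape[0])]
                covs[k] = pooled_cov
                continue
            means[k] = mu
            covs[k] = S
        params = HMMParameters(pi=pi, A=A, means=means, covariances=covs)

        if len(trace) >= 2:
            prev, cur = trace[-2], trace[-1]
            if (cur - prev) < tol * abs(prev):
                converged = True
                break
    return params, trace, converged, reseeded


def fit_em(
    episodes: list[np.ndarray],
    K: int,
    init_method: str = "kmeans",
    n_restarts: int = 3,
    tol: float = 1e-4,
    max_iter: int = 200,
    cov_reg: float = 1e-6,
    seed: int | None = None,
) -> tuple[HMMParameters, FitReport]:
    """Baum-Welch EM over a list of complete (T_i, D) episode matrices.

    Among ``n_restarts`` independently initialized runs the fit with the
    highest final log-likelihood is kept. Stops when the relative
    log-likelihood improvement falls below ``tol``. A ridge ``cov_reg * I``
    is added to every covariance update.
    """
    if len(episodes) == 0:
        raise ValueError("need at least one episode")
    episodes = [np.atleast_2d(np.asarray(e, dtype=float)) for e in episodes]
    total_days = sum(e.shape[0] for e in episodes)
    if K < 1:
        raise ValueError("K must be positive")
    if K > total_days:
        raise ValueError(f"K={K} exceeds total patient-days {total_days}")
    rng = np.random.default_rng(seed)
    best: tuple[HMMParameters, list[float], bool, list[int]] | None = None
    for _ in range(max(1, n_restarts)):
        result = _em_single(episodes, K, init_method, tol, max_iter, cov_reg, rng)
        if best is None or result[1][-1] > best[1][-1]:
            best = result
    params, trace, converged, reseeded = best
    report = FitReport(
        loglik_trace=trace,
        n_iters=len(trace),
        converged=converged,
        seed=seed,
        init_method=init_method,
        n_restarts=max(1, n_restarts),
        reseeded_states=reseeded,
    )
    return params, report


def decode_cohort(
    params: HMMParameters,
    episodes: dict[str, np.ndarray],
    method: str = "viterbi",
) -> dict[str, StateDecoding]:
    """Decode every episode matrix in a {patient_id: (T, D)} mapping."""
    return {
        pid: decode(params, X, method=method, patient_id=pid)
        for pid, X in episodes.items()
    }
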