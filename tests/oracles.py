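"""Independent brute-force oracles for the HMM recursions.

These enumerate all K^T latent paths directly from the joint density, so
they share no code with the dynamic-programming implementations they
check.
"""

import itertools

import numpy as np
from scipy.stats import multivariate_normal


def path_log_joint(params, X, path) -> float:
    lp = np.log(params.pi[path[0]])
    for t in range(1, len(path)):
        lp += np.log(params.A[path[t - 1], path[t]])
    for t, s in enumerate(path):
        lp += multivariate_normal.logpdf(
            X[t], mean=params.means[s], cov=params.covariances[s]
        )
    return float(lp)


def brute_force_loglik(params, X) -> float:
    T = X.shape[0]
    logps = [
        path_log_joint(params, X, path)
        for path in itertools.product(range(params.K), repeat=T)
    ]
    m = max(logps)
    return m + np.log(np.sum(np.exp(np.array(logps) - m)))


def brute_force_viterbi(params, X) -> np.ndarray:
    T = X.shape[0]
    best, best_lp = None, -np.inf
    for path in itertools.product(range(params.K), repeat=T):
        lp = path_log_joint(params, X, path)
        if lp > best_lp:
            best, best_lp = path, lp
    return np.array(best)
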