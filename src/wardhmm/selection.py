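"""State-space size selection and cross-dataset state validation.

The number of hidden states is chosen by a 2-fold concordance procedure:
the training cohort is split in half at the patient level, one model is
fitted per half, both decode the entire cohort, and agreement is measured
on a K x K co-occurrence matrix of patient-days after optimally matching
state labels (Hungarian assignment). A reproducible state space scores
high concordance; the selected K is the largest grid value whose score
clears a threshold, favouring state spaces large enough to capture the
cohort's heterogeneity. The same matching machinery maps states between
models refitted on different datasets and reports the Pearson correlation
of matched state means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import pearsonr

from .hmm import HMMParameters, decode, fit_em

__all__ = [
    "ConcordanceResult",
    "StateMap",
    "concordance_matrix",
    "match_states",
    "concordance_score",
    "select_K",
    "map_across_datasets",
]


@dataclass
class ConcordanceResult:
    K: int
    co_matrix: np.ndarray      # (K, K) patient-day co-occurrence counts
    mapping: np.ndarray        # mapping[i] = state of model B matched to i of A
    score: float               # concordant fraction after matching


@dataclass
class StateMap:
    mapping: dict[int, int | None]   # source state -> target state (None if unmapped)
    mean_correlation: float          # Pearson r over concatenated matched means
    n_unmapped: int


def concordance_matrix(
    decodings_a: dict[str, np.ndarray],
    decodings_b: dict[str, np.ndarray],
    K: int,
) -> np.ndarray:
    """Count patient-days assigned state i by model A and j by model B."""
    if set(decodings_a) != set(decodings_b):
        raise ValueError("decodings must cover identical patient sets")
    co = np.zeros((K, K), dtype=np.int64)
    for pid, sa in decodings_a.items():
        sb = decodings_b[pid]
        sa = np.asarray(sa, dtype=int)
        sb = np.asarray(sb, dtype=int)
        if sa.shape != sb.shape:
            raise ValueError(f"day coverage differs for patient {pid}")
        np.add.at(co, (sa, sb), 1)
    return co


def match_states(co_matrix: np.ndarray) -> np.ndarray:
    """Bijection maximizing matched co-occurrence (Hungarian on -counts).

    Returns perm where state i of model A matches state perm[i] of B."""
    co = np.asarray(co_matrix)
    if co.ndim != 2 or co.shape[0] != co.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    _, cols = linear_sum_assignment(-co)
    return cols


def concordance_score(co_matrix: np.ndarray, mapping: np.ndarray) -> float:
    """Fraction of patient-days concordant under the matched labelling."""
    co = np.asarray(co_matrix, dtype=float)
    total = co.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix")
    matched = co[np.arange(co.shape[0]), np.asarray(mapping)].sum()
    return float(matched / total)


def two_fold_concordance(
    episodes: dict[str, np.ndarray],
    K: int,
    seed: int = 0,
    decode_method: str = "viterbi",
    **fit_kwargs,
) -> ConcordanceResult:
    """Split patients in half, fit one model per half, decode everyone with
    both, and score label-matched agreement."""
    rng = np.random.default_rng(seed)
    pids = sorted(episodes)
    perm = rng.permutation(len(pids))
    half = len(pids) // 2
    fold_a = [pids[i] for i in perm[:half]]
    fold_b = [pids[i] for i in perm[half:]]
    fit_kwargs.setdefault("n_restarts", 1)
    sub = rng.integers(2**31, size=2)
    model_a, _ = fit_em([episodes[p] for p in fold_a], K, seed=int(sub[0]), **fit_kwargs)
    model_b, _ = fit_em([episodes[p] for p in fold_b], K, seed=int(sub[1]), **fit_kwargs)
    dec_a = {p: decode(model_a, x, method=decode_method).states for p, x in episodes.items()}
    dec_b = {p: decode(model_b, x, method=decode_method).states for p, x in episodes.items()}
    co = concordance_matrix(dec_a, dec_b, K)
    mapping = match_states(co)
    return ConcordanceResult(
        K=K, co_matrix=co, mapping=mapping, score=concordance_score(co, mapping)
    )


def select_K(
    episodes: dict[str, np.ndarray],
    K_grid: list[int],
    seed: int = 0,
    threshold: float = 0.8,
    decode_method: str = "viterbi",
    **fit_kwargs,
) -> tuple[int, dict[int, ConcordanceResult]]:
    """Choose the largest K in the grid whose 2-fold concordance clears the
    threshold; if none does, fall back (with a warning) to the argmax-score K."""
    if not K_grid:
        raise ValueError("K grid must be non-empty")
    results: dict[int, ConcordanceResult] = {}
    for K in sorted(K_grid):
        results[K] = two_fold_concordance(
            episodes, K, seed=seed, decode_method=decode_method, **fit_kwargs
        )
    passing = [K for K, r in results.items() if r.score >= threshold]
    if passing:
        return max(passing), results
    import warnings

    best = max(results, key=lambda K: results[K].score)
    warnings.warn(
        f"no K reached concordance {threshold}; returning argmax-score K={best}",
        stacklevel=2,
    )
    return best, results


def map_across_datasets(
    params_a: HMMParameters,
    params_b: HMMParameters,
    decodings_a: dict[str, np.ndarray],
    decodings_b: dict[str, np.ndarray],
    unmapped_floor: float = 0.01,
) -> StateMap:
    """Map states of model A onto model B via shared-cohort co-occurrence.

    A matched pair whose co-occurrence is below ``unmapped_floor`` of all
    patient-days is reported as unmapped. The Pearson correlation is
    computed over the concatenated mean matrices of the mapped pairs.
    """
    K = params_a.K
    co = concordance_matrix(decodings_a, decodings_b, K)
    perm = match_states(co)
    total = co.sum()
    mapping: dict[int, int | None] = {}
    a_rows = []
    b_rows = []
    n_unmapped = 0
    for i in range(K):
        j = int(perm[i])
        if co[i, j] < unmapped_floor * total:
            mapping[i] = None
            n_unmapped += 1
            continue
        mapping[i] = j
        a_rows.append(params_a.means[i])
        b_rows.append(params_b.means[j])
    if len(a_rows) >= 2:
        r = float(pearsonr(np.concatenate(a_rows), np.concatenate(b_rows))[0])
    else:
        r = float("nan")
    return StateMap(mapping=mapping, mean_correlation=r, n_unmapped=n_unmapped)
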