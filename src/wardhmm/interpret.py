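"""Statistical interpretation of decoded states against hold-out labels.

The model never sees outcomes or diagnoses during training, so
associations between a patient's main state (the state most frequently
assigned across the episode) and clinical categories are the evidence that
the latent states carry clinical signal. Associations are tested with a
global Pearson chi-square on the K x C contingency table plus per-cell
standardized Pearson residuals, Bonferroni-corrected across cells at
alpha = 0.001. The module also emits the per-day state distribution and
trajectory tables that clinicians read when labelling states.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, norm

from .config import ASSOCIATION_ALPHA
from .hmm import HMMParameters

__all__ = [
    "AssociationTable",
    "main_state",
    "association_test",
    "state_distribution_by_day",
    "trajectory_table",
    "state_profiles",
    "letter_labels",
]


@dataclass
class AssociationTable:
    contingency: pd.DataFrame   # K x C counts (index: state, columns: category)
    chi2: float
    dof: int
    p_global: float
    residuals: pd.DataFrame     # standardized Pearson residuals
    p_cell: pd.DataFrame        # two-sided normal p per cell
    significant: pd.DataFrame   # booleans at the Bonferroni-corrected level
    alpha: float
    n_cells_corrected: int


def main_state(states: np.ndarray) -> int:
    """The state most frequently assigned over the episode's days; ties are
    broken in favour of the tied state occurring earliest in the episode."""
    states = np.asarray(states, dtype=int)
    if states.size == 0:
        raise ValueError("empty decoding")
    counts = np.bincount(states)
    top = counts.max()
    tied = set(np.where(counts == top)[0])
    for s in states:
        if s in tied:
            return int(s)
    raise AssertionError("unreachable")


def association_test(
    main_states,
    categories,
    alpha: float = ASSOCIATION_ALPHA,
) -> AssociationTable:
    """Chi-square association between main states and a categorical label.

    Per-cell standardized Pearson residuals
    r_ij = (O - E) / sqrt(E (1 - row_i/N) (1 - col_j/N)) are approximately
    standard normal under independence; a cell is flagged significant when
    its two-sided normal p-value clears alpha / (K*C) (Bonferroni over the
    table's cells). Cells with zero expected count are non-testable.
    """
    table = pd.crosstab(pd.Series(main_states, name="state"),
                        pd.Series(categories, name="category"))
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 states and >= 2 categories with nonzero totals")
    O = table.to_numpy(dtype=float)
    N = O.sum()
    row = O.sum(axis=1, keepdims=True)
    col = O.sum(axis=0, keepdims=True)
    E = row @ col / N
    chi2, p_global, dof, _ = chi2_contingency(O, correction=False)

    denom = np.sqrt(E * (1 - row / N) * (1 - col / N))
    with np.errstate(divide="ignore", invalid="ignore"):
        resid = np.where(denom > 0, (O - E) / denom, np.nan)
    p_cell = np.where(np.isfinite(resid), 2 * norm.sf(np.abs(resid)), np.nan)
    n_cells = int(O.size)
    sig = np.where(np.isfinite(p_cell), p_cell < alpha / n_cells, False)

    idx, cols = table.index, table.columns
    return AssociationTable(
        contingency=table,
        chi2=float(chi2),
        dof=int(dof),
        p_global=float(p_global),
        residuals=pd.DataFrame(resid, index=idx, columns=cols),
        p_cell=pd.DataFrame(p_cell, index=idx, columns=cols),
        significant=pd.DataFrame(sig, index=idx, columns=cols),
        alpha=alpha,
        n_cells_corrected=n_cells,
    )


def _day_pick(states: np.ndarray, which) -> int | None:
    T = len(states)
    if which == "first":
        return int(states[0])
    if which == "second":
        return int(states[1]) if T >= 2 else None
    if which == "last":
        return int(states[-1])
    day = int(which)
    return int(states[day]) if day < T else None


def state_distribution_by_day(
    decodings: dict[str, np.ndarray],
    labels: dict[str, str],
    days=("first", "second", "last"),
    K: int | None = None,
) -> pd.DataFrame:
    """Relative state frequency per (requested day, label group).

    Returns a tidy frame (day, group, state, frequency); frequencies sum
    to 1 within each (day, group).
    """
    if K is None:
        K = 1 + max(int(np.max(s)) for s in decodings.values())
    rows = []
    groups = sorted(set(labels.values()))
    for which in days:
        for g in groups:
            counts = np.zeros(K)
            for pid, states in decodings.items():
                if labels[pid] != g:
                    continue
                s = _day_pick(np.asarray(states, dtype=int), which)
                if s is not None:
                    counts[s] += 1
            total = counts.sum()
            for k in range(K):
                rows.append(
                    {
                        "day": which,
                        "group": g,
                        "state": k,
                        "frequency": counts[k] / total if total else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def trajectory_table(
    decodings: dict[str, np.ndarray],
    labels: dict[str, str] | None = None,
    horizon: int = 21,
) -> pd.DataFrame:
    """Long-format (patient, day, state, group) truncated at the horizon;
    day is reported 1-based ("Day 1" is admission day)."""
    rows = []
    for pid, states in sorted(decodings.items()):
        group = labels.get(pid) if labels else None
        for t, s in enumerate(np.asarray(states, dtype=int)[:horizon]):
            rows.append({"patient_id": pid, "day": t + 1, "state": int(s), "group": group})
    return pd.DataFrame(rows)


def state_profiles(
    params: HMMParameters,
    variables: tuple[str, ...],
    decodings: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Per-state emission profile: mean and SD per variable (normalized
    scale) plus each state's occupancy share — the substrate a clinician
    reads when labelling states.

    Occupancy is empirical when decodings are supplied, otherwise the
    stationary distribution of the transition matrix.
    """
    K, D = params.K, params.D
    if len(variables) != D:
        raise ValueError("variable manifest does not match emission dimension")
    if decodings is not None:
        counts = np.zeros(K)
        for states in decodings.values():
            counts += np.bincount(np.asarray(states, dtype=int), minlength=K)
        occupancy = counts / counts.sum()
    else:
        evals, evecs = np.linalg.eig(params.A.T)
        v = np.real(evecs[:, np.argmin(np.abs(evals - 1.0))])
        occupancy = np.abs(v) / np.abs(v).sum()
    rows = []
    for k in range(K):
        sd = np.sqrt(np.diag(params.covariances[k]))
        for d, var in enumerate(variables):
            rows.append(
                {
                    "state": k,
                    "variable": var,
                    "mean": params.means[k, d],
                    "sd": sd[d],
                    "occupancy": occupancy[k],
                }
            )
    return pd.DataFrame(rows)


def letter_labels(
    decodings: dict[str, np.ndarray],
    outcomes: dict[str, str],
    K: int,
    mortality_label: str = "IM",
) -> dict[int, str]:
    """Report labels 'a', 'b', ... assigned by descending relative state
    frequency within the inpatient-mortality group (internal indices stay
    integers)."""
    counts = np.zeros(K)
    for pid, states in decodings.items():
        if outcomes.get(pid) == mortality_label:
            counts += np.bincount(np.asarray(states, dtype=int), minlength=K)
    total = counts.sum()
    freq = counts / total if total else counts
    order = np.argsort(-freq, kind="stable")
    letters = string.ascii_lowercase
    return {int(s): letters[rank] for rank, s in enumerate(order)}
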