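"""Two-step imputation: chained-equation PMM on rich days, then linear
interpolation across poor days.

Rich-information days have few missing cells and plenty of same-day
covariates, so they are completed by multiple imputation with predictive
mean matching (PMM): each variable is regressed on a screened set of other
variables plus phenotypes, and every missing cell receives the observed
value of a donor whose fitted value is nearest the cell's prediction —
imputed values are therefore always observed values of that variable.
Poor-information days are then filled per variable by linear interpolation
in day index within the episode, independent of other variables and
patients. The whole procedure is repeated m times (default 10) with
independent chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import N_IMPUTATIONS, N_VARIABLES, VARIABLES
from .preprocess import EpisodeSeries

__all__ = [
    "ImputationConfig",
    "CompletedDataset",
    "build_predictor_matrix",
    "impute_rich_pmm",
    "impute_poor_linear",
    "two_step_impute",
]

#: provenance codes per cell
OBSERVED, MI, LI = "observed", "MI", "LI"

PHENOTYPE_PREDICTORS = ("age", "sex", "diagnosis")


@dataclass
class ImputationConfig:
    m: int = N_IMPUTATIONS
    n_chain_iters: int = 10
    donors: int = 5
    predictor_corr_threshold: float = 0.8
    missingness_phi_threshold: float = 0.8
    phenotype_predictors: tuple[str, ...] = PHENOTYPE_PREDICTORS

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.donors < 1:
            raise ValueError("donors must be >= 1")


@dataclass
class CompletedDataset:
    """One fully imputed copy of the cohort."""

    episodes: list[EpisodeSeries]       # values complete; masks original
    provenance: list[np.ndarray]        # (T, 23) arrays of {observed, MI, LI}
    imputation_index: int               # 1..m

    def provenance_counts(self) -> dict[str, int]:
        out = {OBSERVED: 0, MI: 0, LI: 0}
        for p in self.provenance:
            for key in out:
                out[key] += int(np.sum(p == key))
        return out


def _phi_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Phi (Pearson) correlation of two binary indicator vectors."""
    a = a.astype(float)
    b = b.astype(float)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rich_day_table(episodes: list[EpisodeSeries]) -> pd.DataFrame:
    """Pool rich-day rows across episodes into one table: the 23 variable
    columns (NaN where unobserved) plus phenotype columns and row keys."""
    rows = []
    for ep in episodes:
        if ep.day_class is None:
            raise ValueError("day classes required; run classify_days first")
        rich = np.where(ep.day_class == "rich")[0]
        for t in rich:
            vals = np.where(ep.mask[t], ep.values[t], np.nan)
            row = dict(zip(VARIABLES, vals))
            row["patient_id"] = ep.patient_id
            row["day"] = int(t)
            for ph in ("age", "sex", "cfs", "diagnosis"):
                if ph in ep.meta:
                    row[ph] = ep.meta[ph]
            rows.append(row)
    return pd.DataFrame(rows)


def build_predictor_matrix(
    rich_df: pd.DataFrame, config: ImputationConfig | None = None
) -> dict[str, list[str]]:
    """Screen predictors per target variable.

    For each target, candidate predictors are the other 22 variables minus
    those highly correlated with the target (|Pearson r| above the
    threshold on pairwise-complete observations), minus the candidates in
    the worst decile of missing fraction, minus those whose missingness
    indicator has |phi| above the threshold against the target's
    missingness; the configured phenotype columns are always appended.
    """
    config = config or ImputationConfig()
    var_df = rich_df[list(VARIABLES)]
    n_obs = var_df.notna().sum()
    for v in VARIABLES:
        if n_obs[v] == 0:
            raise ValueError(f"variable {v!r} has no observed values; cannot model")
    corr = var_df.corr(min_periods=2).to_numpy()
    miss_frac = var_df.isna().mean()
    miss_ind = var_df.isna().to_numpy()

    phenos = [p for p in config.phenotype_predictors if p in rich_df.columns]
    out: dict[str, list[str]] = {}
    for i, target in enumerate(VARIABLES):
        candidates = [j for j in range(N_VARIABLES) if j != i]
        fracs = miss_frac.iloc[candidates]
        cutoff = float(np.quantile(fracs, 0.9))
        keep: list[str] = []
        for j in candidates:
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > config.predictor_corr_threshold:
                continue
            if miss_frac.iloc[j] > cutoff and miss_frac.iloc[j] > 0:
                continue
            phi = _phi_coefficient(miss_ind[:, i], miss_ind[:, j])
            if abs(phi) > config.missingness_phi_threshold:
                continue
            keep.append(VARIABLES[j])
        out[target] = keep + phenos
    return out


def _design_matrix(df: pd.DataFrame, predictors: list[str]) -> np.ndarray:
    """Numeric design matrix with intercept; categoricals one-hot encoded."""
    cols = [np.ones(len(df))]
    for p in predictors:
        s = df[p]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(s.astype(str), prefix=p, drop_first=True)
            for c in sorted(dummies.columns):
                cols.append(dummies[c].to_numpy(dtype=float))
        else:
            cols.append(s.to_numpy(dtype=float))
    return np.column_stack(cols)


def _pmm_fill(
    pred_obs: np.ndarray,
    y_obs: np.ndarray,
    pred_mis: np.ndarray,
    donors: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Donate observed values whose fitted value is nearest each missing
    cell's prediction (k nearest donors, one drawn uniformly)."""
    order = np.argsort(pred_obs, kind="stable")
    sorted_pred = pred_obs[order]
    sorted_y = y_obs[order]
    n = sorted_pred.size
    k = min(donors, n)
    out = np.empty(pred_mis.size)
    pos = np.searchsorted(sorted_pred, pred_mis)
    for i, (p, ins) in enumerate(zip(pred_mis, pos)):
        lo = max(0, ins - k)
        hi = min(n, ins + k)
        window = np.arange(lo, hi)
        d = np.abs(sorted_pred[window] - p)
        nearest = window[np.argsort(d, kind="stable")[:k]]
        out[i] = sorted_y[nearest[rng.integers(nearest.size)]]
    return out


def impute_rich_pmm(
    rich_df: pd.DataFrame,
    predictor_sets: dict[str, list[str]] | None = None,
    config: ImputationConfig | None = None,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Chained-equation PMM over the pooled rich-day table.

    Variables are visited in decreasing-missingness order for
    ``n_chain_iters`` sweeps; ``m`` independent chains with distinct
    sub-seeds return ``m`` completed copies of the table.
    """
    config = config or ImputationConfig()
    if predictor_sets is None:
        predictor_sets = build_predictor_matrix(rich_df, config)
    miss_frac = rich_df[list(VARIABLES)].isna().mean()
    visit_order = [
        v
        for v in sorted(VARIABLES, key=lambda v: -miss_frac[v])
        if miss_frac[v] > 0
    ]
    observed_values = {
        v: rich_df[v].dropna().to_numpy() for v in VARIABLES
    }
    for v in visit_order:
        if observed_values[v].size < config.donors:
            warnings.warn(
                f"variable {v!r}: only {observed_values[v].size} observed values; "
                "donor pool shrunk",
                stacklevel=2,
            )

    ss = np.random.SeedSequence(seed)
    completed: list[pd.DataFrame] = []
    for chain_seed in ss.spawn(config.m):
        rng = np.random.default_rng(chain_seed)
        df = rich_df.copy()
        # initialize missing cells with random observed draws
        for v in visit_order:
            mis = df[v].isna()
            df.loc[mis, v] = rng.choice(observed_values[v], size=int(mis.sum()))
        for _ in range(config.n_chain_iters):
            for v in visit_order:
                mis_mask = rich_df[v].isna().to_numpy()
                X = _design_matrix(df, predictor_sets[v])
                y = rich_df[v].to_numpy(dtype=float)
                X_obs, y_obs = X[~mis_mask], y[~mis_mask]
                beta, *_ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
                pred_obs = X_obs @ beta
                pred_mis = X[mis_mask] @ beta
                df.loc[mis_mask, v] = _pmm_fill(
                    pred_obs, y_obs, pred_mis, config.donors, rng
                )
        completed.append(df)
    return completed


def impute_poor_linear(episode: EpisodeSeries) -> EpisodeSeries:
    """Fill the episode's remaining missing cells by per-variable linear
    interpolation in day index between the nearest flanking non-missing
    values; requires complete first and last days (guaranteed after MI on
    rich endpoints)."""
    ep = episode.copy()
    T = ep.length
    days = np.arange(T)
    for j in range(N_VARIABLES):
        col = ep.values[:, j]
        known = np.isfinite(col)
        if known.all():
            continue
        if not known[0] or not known[-1]:
            raise RuntimeError(
                f"variable {VARIABLES[j]} lacks a flanking value in episode "
                f"{ep.patient_id}; first/last days must be complete before LI"
            )
        ep.values[~known, j] = np.interp(days[~known], days[known], col[known])
    return ep


def two_step_impute(
    episodes: list[EpisodeSeries],
    config: ImputationConfig | None = None,
    seed: int = 0,
) -> list[CompletedDataset]:
    """Full two-step scheme over a preprocessed cohort.

    Rich-day missing cells are multiply imputed by chained-equation PMM
    (step 1); poor-day missing cells are then linearly interpolated within
    each episode (step 2). Returns ``m`` completed datasets with per-cell
    provenance flags. Observed cells are never modified.
    """
    config = config or ImputationConfig()
    rich_df = rich_day_table(episodes)
    completed_tables = impute_rich_pmm(rich_df, config=config, seed=seed)

    datasets: list[CompletedDataset] = []
    keys = list(zip(rich_df["patient_id"], rich_df["day"]))
    row_of = {key: i for i, key in enumerate(keys)}
    for m_idx, table in enumerate(completed_tables, start=1):
        eps_out: list[EpisodeSeries] = []
        prov_out: list[np.ndarray] = []
        values_block = table[list(VARIABLES)].to_numpy(dtype=float)
        for ep in episodes:
            new = ep.copy()
            prov = np.where(ep.mask, OBSERVED, "").astype(object)
            new.values = np.where(ep.mask, ep.values, np.nan)
            for t in range(ep.length):
                if ep.day_class[t] == "rich":
                    row = values_block[row_of[(ep.patient_id, t)]]
                    fill = ~ep.mask[t]
                    new.values[t, fill] = row[fill]
                    prov[t, fill] = MI
            filled_mask = ~np.isfinite(new.values)
            new = impute_poor_linear(new)
            prov[filled_mask] = LI
            eps_out.append(new)
            prov_out.append(prov)
        datasets.append(
            CompletedDataset(
                episodes=eps_out, provenance=prov_out, imputation_index=m_idx
            )
        )
    return datasets
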