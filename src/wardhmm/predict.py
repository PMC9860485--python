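"""Benchmark outcome prediction from raw daily series vs. decoded states.

The question is how much predictive signal survives the compression of 23
daily values into a single state label. Features are built from the first
three admission days only — either the raw (imputed, normalized) values or
one-hot state indicators — optionally with phenotypes. Tuning follows a
repeated nested protocol inside the training cohort: an inner 80/20 split,
5-fold cross-validated grid search on the inner-train part, evaluation on
the inner-test part, repeated 10 times; the best configuration is then
refitted and scored once against the untouched hold-out cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, train_test_split
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import (
    DIAGNOSIS_CODES,
    TUNE_CV_FOLDS,
    TUNE_INNER_TRAIN_FRACTION,
    TUNE_REPEATS,
    VARIABLES,
)
from .preprocess import EpisodeSeries

__all__ = [
    "FeatureSpec",
    "EvalResult",
    "build_features",
    "make_labels",
    "tune_and_evaluate",
    "weighted_auc",
    "compare_representations",
    "DEFAULT_GRIDS",
]

DAY_SETS = {
    "D1": (0,),
    "D2": (1,),
    "D3": (2,),
    "D1D2": (0, 1),
    "D2D3": (1, 2),
    "D1D2D3": (0, 1, 2),
}

#: production hyperparameter grids; the tuned parameters are the penalty
#: strength for logistic regression and, for random forests, tree count,
#: features per split, depth, split/leaf minima and bootstrapping
DEFAULT_GRIDS = {
    "logistic": {"clf__C": [1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3]},
    "rf": {
        "n_estimators": [100, 300],
        "max_depth": [None, 5, 10],
        "max_features": ["sqrt", 0.3],
        "min_samples_split": [2, 10],
        "min_samples_leaf": [1, 5],
        "bootstrap": [True, False],
    },
}


@dataclass(frozen=True)
class FeatureSpec:
    representation: str          # "mvts" or "states"
    days: str = "D1D2D3"         # key into DAY_SETS
    include_phenotype: bool = False

    def __post_init__(self) -> None:
        if self.representation not in ("mvts", "states"):
            raise ValueError("representation must be 'mvts' or 'states'")
        if self.days not in DAY_SETS:
            raise ValueError(f"days must be one of {sorted(DAY_SETS)}")


@dataclass
class EvalResult:
    outcome: str
    model: str
    spec: FeatureSpec
    auc_train_mean: float
    auc_train_sd: float
    auc_test: float
    per_class_auc: dict | None = None
    weighted: bool = False
    best_params: dict = field(default_factory=dict)
    n_repeats: int = TUNE_REPEATS


def build_features(
    episodes: list[EpisodeSeries],
    decodings: dict[str, np.ndarray] | None,
    spec: FeatureSpec,
    K: int | None = None,
    phenotypes: pd.DataFrame | None = None,
    diagnosis_codes: tuple[str, ...] = DIAGNOSIS_CODES,
) -> pd.DataFrame:
    """Deterministic feature table indexed by patient_id.

    mvts: the 23 values of each selected day, concatenated. states: a
    one-hot indicator vector of length K per selected day. Phenotypes (age
    and CFS numeric; sex and diagnosis one-hot over fixed category orders)
    are appended when requested.
    """
    day_idx = DAY_SETS[spec.days]
    rows = []
    index = []
    for ep in episodes:
        if ep.length < 3:
            raise ValueError("episodes must have >= 3 days")
        feats: dict[str, float] = {}
        if spec.representation == "mvts":
            for d in day_idx:
                for j, var in enumerate(VARIABLES):
                    feats[f"d{d + 1}_{var}"] = float(ep.values[d, j])
        else:
            if decodings is None or ep.patient_id not in decodings:
                raise ValueError(f"no decoding for episode {ep.patient_id}")
            if K is None:
                raise ValueError("K required for state features")
            states = np.asarray(decodings[ep.patient_id], dtype=int)
            for d in day_idx:
                for k in range(K):
                    feats[f"d{d + 1}_state{k:02d}"] = float(states[d] == k)
        if spec.include_phenotype:
            if phenotypes is None:
                raise ValueError("phenotype table required")
            ph = phenotypes.loc[ep.patient_id]
            feats["age"] = float(ph["age"])
            feats["cfs"] = float(ph["cfs"])
            feats["sex_M"] = float(ph["sex"] == "M")
            for code in diagnosis_codes:
                feats[f"dx_{code}"] = float(ph["diagnosis"] == code)
        rows.append(feats)
        index.append(ep.patient_id)
    return pd.DataFrame(rows, index=pd.Index(index, name="patient_id"))


def make_labels(meta: pd.DataFrame, task: str) -> pd.Series:
    """Labels per task: 'im' (binary inpatient mortality), 'clinical'
    (5-class outcome), 'diagnosis' (admission-diagnosis multiclass)."""
    meta = meta.set_index("patient_id") if "patient_id" in meta.columns else meta
    if task == "im":
        return (meta["outcome"] == "IM").astype(int)
    if task == "clinical":
        return meta["outcome"].astype(str)
    if task == "diagnosis":
        return meta["diagnosis"].astype(str)
    raise ValueError(f"unknown task {task!r}")


def _make_estimator(model: str, seed: int):
    if model == "logistic":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
            ]
        )
    if model == "rf":
        return RandomForestClassifier(random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _auc(estimator, X, y, classes) -> tuple[float, dict | None]:
    proba = estimator.predict_proba(X)
    if len(classes) == 2:
        return float(roc_auc_score(y, proba[:, 1])), None
    per_class = {}
    prev = {}
    for i, c in enumerate(estimator.classes_):
        y_bin = (np.asarray(y) == c).astype(int)
        prev[c] = y_bin.mean()
        if y_bin.min() == y_bin.max():
            per_class[c] = np.nan
            continue
        per_class[c] = float(roc_auc_score(y_bin, proba[:, i]))
    return (
        weighted_auc(
            [per_class[c] for c in estimator.classes_ if np.isfinite(per_class[c])],
            _renorm([prev[c] for c in estimator.classes_ if np.isfinite(per_class[c])]),
        ),
        per_class,
    )


def _renorm(p):
    p = np.asarray(p, dtype=float)
    return p / p.sum()


def weighted_auc(per_class_auc, class_prevalences) -> float:
    """Class-prevalence-weighted mean of one-vs-rest AUCs."""
    auc = np.asarray(per_class_auc, dtype=float)
    prev = np.asarray(class_prevalences, dtype=float)
    if not np.isclose(prev.sum(), 1.0, atol=1e-8):
        raise ValueError("prevalences must sum to 1")
    return float(np.dot(auc, prev))


def tune_and_evaluate(
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    model: str = "rf",
    seed: int = 0,
    n_repeats: int = TUNE_REPEATS,
    cv_folds: int = TUNE_CV_FOLDS,
    param_grid: dict | None = None,
    outcome: str = "",
    spec: FeatureSpec | None = None,
) -> EvalResult:
    """Repeated inner-split tuning, then one scoring pass on the hold-out.

    Within the training cohort: an 80/20 split; grid search with
    ``cv_folds``-fold CV on the 80%; AUC on the 20%; repeated
    ``n_repeats`` times with distinct sub-seeds. The configuration from
    the best-scoring repeat is refitted on the full training cohort and
    scored once on the hold-out test cohort, which tuning never sees.
    """
    classes = np.unique(y_train)
    if classes.size < 2:
        raise ValueError("labels contain a single class")
    if param_grid is None:
        param_grid = DEFAULT_GRIDS[model]
    overlap = set(X_train.index) & set(X_test.index)
    if overlap:
        raise ValueError(f"train/test cohorts overlap: {sorted(overlap)[:5]} ...")

    multiclass = classes.size > 2
    scoring = "roc_auc_ovr_weighted" if multiclass else "roc_auc"
    ss = np.random.SeedSequence(seed)
    inner_aucs = []
    best_of_repeat = []
    for rep_seed in ss.spawn(n_repeats):
        sub = int(rep_seed.generate_state(1)[0] % (2**31))
        X_in, X_out, y_in, y_out = train_test_split(
            X_train,
            y_train,
            train_size=TUNE_INNER_TRAIN_FRACTION,
            stratify=y_train,
            random_state=sub,
        )
        gs = GridSearchCV(
            _make_estimator(model, sub),
            param_grid,
            cv=cv_folds,
            scoring=scoring,
            n_jobs=1,
        )
        gs.fit(X_in, y_in)
        auc, _ = _auc(gs.best_estimator_, X_out, y_out, classes)
        inner_aucs.append(auc)
        best_of_repeat.append((auc, gs.best_params_, sub))

    best_auc, best_params, best_seed = max(best_of_repeat, key=lambda t: t[0])
    final = _make_estimator(model, best_seed)
    final.set_params(**best_params)
    final.fit(X_train, y_train)
    auc_test, per_class = _auc(final, X_test, y_test, classes)

    return EvalResult(
        outcome=outcome,
        model=model,
        spec=spec or FeatureSpec("mvts"),
        auc_train_mean=float(np.mean(inner_aucs)),
        auc_train_sd=float(np.std(inner_aucs)),
        auc_test=auc_test,
        per_class_auc=per_class,
        weighted=multiclass,
        best_params=best_params,
        n_repeats=n_repeats,
    )


def compare_representations(results: list[EvalResult], margin: float = 0.02) -> pd.DataFrame:
    """Pair mvts vs. states results per (outcome, model, days, phenotype)
    cell and flag whether mvts test AUC >= states test AUC - margin."""
    rows = {}
    for r in results:
        key = (r.outcome, r.model, r.spec.days, r.spec.include_phenotype)
        rows.setdefault(key, {})[r.spec.representation] = r
    out = []
    for (outcome, model, days, pheno), pair in sorted(rows.items()):
        m = pair.get("mvts")
        s = pair.get("states")
        out.append(
            {
                "outcome": outcome,
                "model": model,
                "days": days,
                "phenotype": pheno,
                "auc_mvts": m.auc_test if m else np.nan,
                "auc_states": s.auc_test if s else np.nan,
                "mvts_ge_states": (
                    m.auc_test >= s.auc_test - margin if m and s else None
                ),
            }
        )
    return pd.DataFrame(out)


def results_table(results: list[EvalResult]) -> pd.DataFrame:
    """Flat results table mirroring the benchmark layout."""
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "representation": r.spec.representation,
                "algorithm": r.model,
                "days": r.spec.days,
                "phenotype": r.spec.include_phenotype,
                "auc_train_mean": r.auc_train_mean,
                "auc_train_sd": r.auc_train_sd,
                "auc_test": r.auc_test,
                "weighted": r.weighted,
            }
            for r in results
        ]
    )
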