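"""Regularize irregular observation streams into daily episode matrices.

Raw inpatient data arrives as timestamped events at arbitrary times. The
analysis works on 24-hour bins (calendar days from admission): one value
per variable per day, days classified as rich- or poor-information by how
many variables were observed, episodes filtered by inclusion rules, and
values inverse-rank normalized with a train-fitted transform.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .config import (
    BLOOD_TESTS,
    MAX_POOR_FRACTION,
    MIN_LENGTH_OF_STAY,
    N_BLOOD_TESTS,
    N_VARIABLES,
    RICH_MIN_BLOOD_TESTS,
    RICH_MIN_VITAL_SIGNS,
    TRAIN_FRACTION,
    VARIABLE_INDEX,
    VITAL_SIGNS,
)

__all__ = [
    "EpisodeSeries",
    "CohortSplit",
    "RankNormalizer",
    "bin_daily",
    "bin_cohort",
    "classify_days",
    "apply_inclusion",
    "inverse_rank_normalize",
    "split_cohort",
]


@dataclass
class EpisodeSeries:
    """One admission episode as a day x variable matrix with missingness."""

    patient_id: str
    values: np.ndarray            # (T, 23) float, NaN where unobserved
    mask: np.ndarray              # (T, 23) bool, True where observed
    admit_date: date
    day_class: np.ndarray | None = None  # (T,) "rich" / "poor"
    episode_index: int = 0        # per-patient episode order (0 = first)
    n_rejected: int = 0           # events with timestamps before admission
    meta: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.values.shape[0]

    def copy(self) -> "EpisodeSeries":
        return EpisodeSeries(
            patient_id=self.patient_id,
            values=self.values.copy(),
            mask=self.mask.copy(),
            admit_date=self.admit_date,
            day_class=None if self.day_class is None else self.day_class.copy(),
            episode_index=self.episode_index,
            n_rejected=self.n_rejected,
            meta=dict(self.meta),
        )


@dataclass
class CohortSplit:
    train_ids: list[str]
    test_ids: list[str]
    fraction: float
    seed: int


def bin_daily(
    stream: pd.DataFrame,
    admit_date: date,
    n_days: int | None = None,
    patient_id: str = "",
    episode_index: int = 0,
) -> EpisodeSeries:
    """Collapse a timestamped event stream to one value per variable per day.

    Days are calendar days from admission (midnight boundaries). Within a
    day, a blood test with multiple records keeps the earliest; a vital
    sign keeps the record closest in time to the day's earliest blood-test
    draw (the blood draw anchors the day's clinical snapshot), or the
    earliest vital record on days without any blood test. Events
    timestamped before admission are rejected and counted.
    """
    admit_ts = pd.Timestamp(admit_date)
    if len(stream) == 0:
        T = n_days or 0
        return EpisodeSeries(
            patient_id=patient_id,
            values=np.full((T, N_VARIABLES), np.nan),
            mask=np.zeros((T, N_VARIABLES), dtype=bool),
            admit_date=admit_date,
            episode_index=episode_index,
        )
    df = stream.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    before = df["timestamp"] < admit_ts
    n_rejected = int(before.sum())
    if n_rejected:
        warnings.warn(
            f"{n_rejected} events timestamped before admission rejected",
            stacklevel=2,
        )
        df = df[~before]
    df["day"] = (df["timestamp"].dt.normalize() - admit_ts).dt.days
    T = int(n_days if n_days is not None else df["day"].max() + 1)
    df = df[df["day"] < T]

    values = np.full((T, N_VARIABLES), np.nan)
    mask = np.zeros((T, N_VARIABLES), dtype=bool)

    is_test = df["variable"].isin(BLOOD_TESTS)
    tests = df[is_test].sort_values("timestamp", kind="stable")
    vitals = df[df["variable"].isin(VITAL_SIGNS)]

    # blood tests: earliest record of the day is the unique value
    first_tests = tests.groupby(["day", "variable"], sort=False).first()
    for (day, var), row in first_tests.iterrows():
        values[day, VARIABLE_INDEX[var]] = row["value"]
        mask[day, VARIABLE_INDEX[var]] = True

    if len(vitals):
        # anchor: earliest blood-test timestamp per day (NaT if none)
        anchors = tests.groupby("day")["timestamp"].min()
        v = vitals.copy()
        v["anchor"] = v["day"].map(anchors)
        has_anchor = v["anchor"].notna()
        delta = pd.Series(pd.NaT, index=v.index, dtype="timedelta64[ns]")
        delta[has_anchor] = (v.loc[has_anchor, "timestamp"] - v.loc[has_anchor, "anchor"]).abs()
        # no blood test that day: fall back to earliest vital record
        day_start = admit_ts + pd.to_timedelta(v["day"], unit="D")
        delta[~has_anchor] = v.loc[~has_anchor, "timestamp"] - day_start[~has_anchor]
        v["delta"] = delta
        v = v.sort_values(["delta", "timestamp"], kind="stable")
        chosen = v.groupby(["day", "variable"], sort=False).first()
        for (day, var), row in chosen.iterrows():
            values[day, VARIABLE_INDEX[var]] = row["value"]
            mask[day, VARIABLE_INDEX[var]] = True

    return EpisodeSeries(
        patient_id=patient_id,
        values=values,
        mask=mask,
        admit_date=admit_date,
        episode_index=episode_index,
        n_rejected=n_rejected,
    )


def bin_cohort(
    observations: pd.DataFrame, episodes_meta: pd.DataFrame
) -> list[EpisodeSeries]:
    """Bin every patient's stream; lengths and metadata from the episode
    table (columns: patient_id, admit_date, length_days, ...)."""
    out: list[EpisodeSeries] = []
    grouped = dict(iter(observations.groupby("patient_id")))
    for row in episodes_meta.itertuples(index=False):
        admit = row.admit_date
        if isinstance(admit, str):
            admit = date.fromisoformat(admit)
        stream = grouped.get(row.patient_id, observations.iloc[0:0])
        ep = bin_daily(
            stream,
            admit_date=admit,
            n_days=int(row.length_days),
            patient_id=row.patient_id,
        )
        ep.meta = {
            k: getattr(row, k)
            for k in ("outcome", "age", "sex", "cfs", "diagnosis")
            if hasattr(row, k)
        }
        out.append(ep)
    return out


def classify_days(episode: EpisodeSeries) -> EpisodeSeries:
    """Mark each day rich-information iff >=14 of 17 blood tests and >=4 of
    5 vital signs were observed; poor-information otherwise."""
    test_counts = episode.mask[:, :N_BLOOD_TESTS].sum(axis=1)
    vital_counts = episode.mask[:, N_BLOOD_TESTS:].sum(axis=1)
    rich = (test_counts >= RICH_MIN_BLOOD_TESTS) & (
        vital_counts >= RICH_MIN_VITAL_SIGNS
    )
    episode.day_class = np.where(rich, "rich", "poor")
    return episode


#: exclusion rules in precedence order; each excluded episode logs the
#: first rule it violates
EXCLUSION_REASONS = (
    "not_first_episode",
    "length_below_minimum",
    "endpoint_not_rich",
    "poor_fraction_too_high",
)


def apply_inclusion(
    episodes: list[EpisodeSeries],
    min_los: int = MIN_LENGTH_OF_STAY,
    max_poor_fraction=MAX_POOR_FRACTION,
) -> tuple[list[EpisodeSeries], pd.DataFrame]:
    """Apply the cohort inclusion rules; returns (kept, exclusion log).

    Rules, in order: keep only each patient's first episode; drop stays
    shorter than ``min_los`` days; drop episodes whose first or last day is
    poor-information; drop episodes where poor-information days make up at
    least ``max_poor_fraction`` of the length (strictly fewer are required).
    """
    first_index: dict[str, int] = {}
    for ep in episodes:
        cur = first_index.get(ep.patient_id)
        if cur is None or ep.episode_index < cur:
            first_index[ep.patient_id] = ep.episode_index

    kept: list[EpisodeSeries] = []
    log_rows: list[dict] = []

    def exclude(ep: EpisodeSeries, reason: str) -> None:
        log_rows.append(
            {
                "patient_id": ep.patient_id,
                "episode_index": ep.episode_index,
                "length": ep.length,
                "reason": reason,
            }
        )

    for ep in episodes:
        if ep.day_class is None:
            raise ValueError("classify_days must run before apply_inclusion")
        if ep.episode_index != first_index[ep.patient_id]:
            exclude(ep, "not_first_episode")
            continue
        if ep.length < min_los:
            exclude(ep, "length_below_minimum")
            continue
        if ep.day_class[0] != "rich" or ep.day_class[-1] != "rich":
            exclude(ep, "endpoint_not_rich")
            continue
        n_poor = int(np.sum(ep.day_class == "poor"))
        # strict inequality: n_poor / length < max_poor_fraction
        if n_poor * max_poor_fraction.denominator >= ep.length * max_poor_fraction.numerator:
            exclude(ep, "poor_fraction_too_high")
            continue
        kept.append(ep)

    log = pd.DataFrame(log_rows, columns=["patient_id", "episode_index", "length", "reason"])
    return kept, log


class RankNormalizer:
    """Inverse-rank-normal transform fitted on training data.

    Per variable, observed training values are replaced by
    Phi^-1((rank - 3/8)/(n + 1/4)) (Blom offset, average ranks for ties).
    New values are transformed by interpolating the fitted value->score
    mapping, clamped at the extremes, so the hold-out set never
    contributes ranks (no leakage).
    """

    def __init__(self) -> None:
        self.grids: list[tuple[np.ndarray, np.ndarray]] = []

    def fit(self, train_episodes: list[EpisodeSeries]) -> "RankNormalizer":
        self.grids = []
        all_vals = np.vstack([ep.values for ep in train_episodes])
        all_mask = np.vstack([ep.mask for ep in train_episodes])
        for j in range(N_VARIABLES):
            vals = all_vals[:, j][all_mask[:, j]]
            n = vals.size
            if n < 2:
                raise ValueError(
                    f"variable {j} has {n} observed training values; need >= 2"
                )
            if np.all(vals == vals[0]):
                warnings.warn(
                    f"variable {j} is constant in training data; mapped to 0",
                    stacklevel=2,
                )
                self.grids.append((np.array([vals[0]]), np.array([0.0])))
                continue
            ranks = rankdata(vals, method="average")
            scores = norm.ppf((ranks - 0.375) / (n + 0.25))
            order = np.argsort(vals, kind="stable")
            xs, idx = np.unique(vals[order], return_index=True)
            ys = scores[order][idx]
            self.grids.append((xs, ys))
        return self

    def transform_values(self, x: np.ndarray, j: int) -> np.ndarray:
        xs, ys = self.grids[j]
        if xs.size == 1:
            return np.zeros_like(np.asarray(x, dtype=float))
        return np.interp(x, xs, ys)  # np.interp clamps outside [xs0, xs-1]

    def transform(self, episodes: list[EpisodeSeries]) -> list[EpisodeSeries]:
        out = []
        for ep in episodes:
            new = ep.copy()
            for j in range(N_VARIABLES):
                obs = ep.mask[:, j]
                if obs.any():
                    new.values[obs, j] = self.transform_values(ep.values[obs, j], j)
            out.append(new)
        return out


def inverse_rank_normalize(
    train_episodes: list[EpisodeSeries],
    test_episodes: list[EpisodeSeries] | None = None,
) -> tuple[list[EpisodeSeries], list[EpisodeSeries], RankNormalizer]:
    """Fit the transform on the training episodes and apply it to both
    cohorts; missing entries and masks are untouched."""
    tf = RankNormalizer().fit(train_episodes)
    train_t = tf.transform(train_episodes)
    test_t = tf.transform(test_episodes) if test_episodes is not None else []
    return train_t, test_t, tf


def split_cohort(
    patient_ids: list[str], fraction: float = TRAIN_FRACTION, seed: int = 0
) -> CohortSplit:
    """Uniform random patient-level train/hold-out partition."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    ids = list(patient_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 patients to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(round(fraction * len(ids)))
    n_train = min(max(n_train, 1), len(ids) - 1)
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return CohortSplit(train_ids=train, test_ids=test, fraction=fraction, seed=seed)


def episodes_to_tidy(episodes: list[EpisodeSeries]) -> pd.DataFrame:
    """Tidy CSV schema: patient_id, day, variable, value, observed, day_class."""
    from .config import VARIABLES

    frames = []
    for ep in episodes:
        T = ep.length
        day_class = ep.day_class if ep.day_class is not None else np.full(T, "", dtype=object)
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(ep.patient_id, T * N_VARIABLES),
                    "day": np.repeat(np.arange(T), N_VARIABLES),
                    "variable": np.tile(VARIABLES, T),
                    "value": ep.values.ravel(),
                    "observed": ep.mask.ravel(),
                    "day_class": np.repeat(day_class, N_VARIABLES),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
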