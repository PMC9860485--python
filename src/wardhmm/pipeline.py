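"""Glue: run the preprocessing chain end to end on long-format frames."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import (
    CohortSplit,
    EpisodeSeries,
    RankNormalizer,
    apply_inclusion,
    bin_cohort,
    classify_days,
    inverse_rank_normalize,
    split_cohort,
)

__all__ = ["PreprocessedCohort", "run_preprocess", "episode_matrices"]


@dataclass
class PreprocessedCohort:
    train: list[EpisodeSeries]     # normalized, inclusion-filtered
    test: list[EpisodeSeries]
    split: CohortSplit
    exclusion_log: pd.DataFrame
    normalizer: RankNormalizer


def run_preprocess(
    observations: pd.DataFrame,
    episodes_meta: pd.DataFrame,
    seed: int = 0,
    fraction: float = 0.8,
) -> PreprocessedCohort:
    """Bin, classify, filter, split at patient level, and rank-normalize
    (transform fitted on the training cohort only)."""
    episodes = [classify_days(ep) for ep in bin_cohort(observations, episodes_meta)]
    kept, log = apply_inclusion(episodes)
    split = split_cohort([ep.patient_id for ep in kept], fraction=fraction, seed=seed)
    train_ids = set(split.train_ids)
    train = [ep for ep in kept if ep.patient_id in train_ids]
    test = [ep for ep in kept if ep.patient_id not in train_ids]
    train_t, test_t, tf = inverse_rank_normalize(train, test)
    return PreprocessedCohort(
        train=train_t, test=test_t, split=split, exclusion_log=log, normalizer=tf
    )


def episode_matrices(episodes: list[EpisodeSeries]) -> dict[str, np.ndarray]:
    """{patient_id: (T, D) matrix} for complete (imputed) episodes."""
    out = {}
    for ep in episodes:
        if not np.all(np.isfinite(ep.values)):
            raise ValueError(f"episode {ep.patient_id} still has missing values")
        out[ep.patient_id] = ep.values
    return out
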