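"""Synthetic inpatient cohorts with known latent structure.

Real hospital admission data of this kind is access-restricted, so the
pipeline is exercised on seeded synthetic cohorts that carry their own
ground truth. Each patient contributes one admission episode of at least
three days. A hidden Markov chain with Gaussian emissions generates a
latent daily 23-vector (17 blood tests, 5 vital signs) which is scattered
into irregular timestamped events: blood tests appear at most a couple of
times per day, vitals several times per day, and per-variable daily
missingness produces a mix of rich- and poor-information days. Outcomes
(inpatient mortality vs. discharge categories) are causally linked to the
latent states through a logistic model on mean state occupancy, and the
admission diagnosis is drawn from a per-state affinity distribution, so
every downstream stage has a planted signal to detect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

from .config import (
    BLOOD_TESTS,
    DIAGNOSIS_CODES,
    N_BLOOD_TESTS,
    N_VARIABLES,
    OUTCOMES,
    VARIABLES,
    VITAL_SIGNS,
)
from .hmm import HMMParameters

__all__ = [
    "GroundTruth",
    "PhenotypeRecord",
    "SyntheticEpisode",
    "SamplingConfig",
    "CohortConfig",
    "sample_ground_truth",
    "simulate_state_path",
    "emit_observations",
    "assign_outcome",
    "simulate_cohort",
    "cohort_to_frames",
    "write_cohort",
]


@dataclass
class GroundTruth:
    """The generative model a cohort was drawn from (the test oracle)."""

    K_true: int
    params_true: HMMParameters
    mortality_logit_per_state: np.ndarray  # additive log-odds of IM per state
    base_mortality_logit: float
    diagnosis_affinity: np.ndarray  # (K, C) rows sum to 1
    diagnosis_codes: tuple[str, ...]
    seed: int

    def validate(self) -> None:
        self.params_true.validate(atol=1e-12)
        if not np.allclose(self.diagnosis_affinity.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("diagnosis_affinity rows must sum to 1")

    def variable_sd(self) -> np.ndarray:
        """Across-state average within-state SD per variable."""
        diags = np.array([np.diag(S) for S in self.params_true.covariances])
        return np.sqrt(diags.mean(axis=0))

    def to_dict(self) -> dict:
        return {
            "K_true": self.K_true,
            "params_true": self.params_true.to_dict(),
            "mortality_logit_per_state": self.mortality_logit_per_state.tolist(),
            "base_mortality_logit": self.base_mortality_logit,
            "diagnosis_affinity": self.diagnosis_affinity.tolist(),
            "diagnosis_codes": list(self.diagnosis_codes),
            "seed": self.seed,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            K_true=d["K_true"],
            params_true=HMMParameters.from_dict(d["params_true"]),
            mortality_logit_per_state=np.array(d["mortality_logit_per_state"]),
            base_mortality_logit=d["base_mortality_logit"],
            diagnosis_affinity=np.array(d["diagnosis_affinity"]),
            diagnosis_codes=tuple(d["diagnosis_codes"]),
            seed=d["seed"],
        )


@dataclass
class PhenotypeRecord:
    age: int          # years, >= 65
    sex: str          # "F" or "M"
    cfs: int          # Clinical Frailty Scale, ordinal 1-9
    admission_diagnosis: str  # single-letter top-level code

    def __post_init__(self) -> None:
        if self.age < 65:
            raise ValueError("cohort is restricted to age >= 65")
        if not 1 <= self.cfs <= 9:
            raise ValueError("CFS must be in [1, 9]")


@dataclass
class SyntheticEpisode:
    patient_id: str
    admit_date: date
    true_states: np.ndarray       # (T,)
    latent_daily: np.ndarray      # (T, D) the per-day Gaussian draws
    observations: pd.DataFrame    # long format: variable, timestamp, value
    phenotype: PhenotypeRecord
    outcome: str                  # one of OUTCOMES

    @property
    def length(self) -> int:
        return len(self.true_states)


@dataclass
class SamplingConfig:
    """How each day's latent vector is scattered into timestamped events."""

    blood_test_daily_prob: float | np.ndarray = 0.92
    blood_test_repeat_prob: float = 0.15   # chance of a 2nd same-day draw
    vital_daily_prob: float | np.ndarray = 0.98
    vitals_max_per_day: int = 8
    jitter_sd_fraction: float = 0.01       # duplicate jitter: 1% of var SD

    def blood_probs(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.blood_test_daily_prob, dtype=float), (N_BLOOD_TESTS,)
        )

    def vital_probs(self) -> np.ndarray:
        return np.broadcast_to(
            np.asarray(self.vital_daily_prob, dtype=float), (len(VITAL_SIGNS),)
        )


@dataclass
class CohortConfig:
    n_patients: int = 500
    K: int = 17
    D: int = N_VARIABLES
    separation: float = 2.0
    mean_length: float = 8.0       # shifted Poisson: 3 + Poisson(mean - 3)
    min_length: int = 3
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    survivor_proportions: tuple[float, ...] = (0.70, 0.15, 0.08, 0.07)  # DA PDR PDM PDRM
    base_mortality_logit: float = -2.2
    mortality_logit_scale: float = 1.5
    self_transition: float = 0.75
    covariance: str = "random"
    balanced: bool = False
    diagnosis_codes: tuple[str, ...] = DIAGNOSIS_CODES
    diagnosis_concentration: float = 0.3
    female_fraction: float = 0.472
    admit_start: date = date(2015, 1, 6)
    #: optional per-state multiplier on blood-test observation probability
    #: (hook for state-dependent, i.e. informative, missingness; default MCAR)
    missingness_multiplier_by_state: np.ndarray | None = None
    #: optional per-variable weights adding a continuous presenting-acuity
    #: term to the mortality logit (None: risk is state-driven only),
    #: averaged over the first mortality_value_days days (None: all days)
    mortality_value_weights: np.ndarray | None = None
    mortality_value_days: int | None = None
    #: SD of a per-patient baseline offset added to every day's emissions
    #: (persistent between-patient heterogeneity; 0 disables), optionally
    #: restricted to the listed variable indices
    patient_effect_sd: float = 0.0
    patient_effect_variables: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.mean_length < self.min_length:
            raise ValueError("length distribution must have support >= min_length")
        if self.min_length < 3:
            raise ValueError("episodes must be at least 3 days")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sampling = SamplingConfig(**raw.pop("sampling", {}))
        if "admit_start" in raw and isinstance(raw["admit_start"], str):
            raw["admit_start"] = date.fromisoformat(raw["admit_start"])
        for key in ("survivor_proportions", "diagnosis_codes"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(sampling=sampling, **raw)


def sample_ground_truth(
    K: int,
    D: int,
    separation: float = 2.0,
    seed: int = 0,
    self_transition: float = 0.75,
    base_mortality_logit: float = -2.2,
    mortality_logit_scale: float = 1.5,
    diagnosis_codes: tuple[str, ...] = DIAGNOSIS_CODES,
    diagnosis_concentration: float = 0.3,
    covariance: str = "random",
    balanced: bool = False,
    stationary_weights=None,
) -> GroundTruth:
    """Draw a random K-state, D-dimensional generative model.

    State means are rescaled so the minimum pairwise Euclidean distance
    equals ``separation`` times the average within-state standard
    deviation; covariances are random SPD matrices with average unit
    variance ("random") or identity ("spherical"); transitions are sticky
    Dirichlet rows, or uniform-occupancy sticky rows when ``balanced``.

    ``covariance="spherical"`` with ``balanced=True`` plants a fully
    exchangeable truth: no state has a preferred split axis or outsized
    occupancy, which is the regime where a state count larger than the
    truth is genuinely non-identifiable (used by the state-count recovery
    study; see the methods note).
    """
    if K < 1 or D < 1:
        raise ValueError("K and D must be positive")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if covariance not in ("random", "spherical"):
        raise ValueError("covariance must be 'random' or 'spherical'")
    rng = np.random.default_rng(seed)

    covs = np.empty((K, D, D))
    for k in range(K):
        if covariance == "spherical":
            covs[k] = np.eye(D)
            continue
        W = rng.normal(size=(D, D))
        S = W @ W.T / D + 0.5 * np.eye(D)
        S /= np.mean(np.diag(S))  # average within-state variance = 1
        covs[k] = S
    mean_sd = float(np.sqrt(np.mean([np.diag(S) for S in covs])))

    means = rng.normal(size=(K, D))
    if K > 1:
        means -= means.mean(axis=0)
        dists = np.linalg.norm(means[:, None] - means[None, :], axis=-1)
        min_dist = dists[~np.eye(K, dtype=bool)].min()
        means *= separation * mean_sd / min_dist

    if K == 1:
        pi = np.array([1.0])
        A = np.array([[1.0]])
    elif stationary_weights is not None:
        # sticky chain with an exact target stationary distribution:
        # A = s*I + (1-s) * 1 w^T has stationary vector w
        w = np.asarray(stationary_weights, dtype=float)
        if w.shape != (K,) or np.any(w <= 0):
            raise ValueError("stationary_weights must be K positive values")
        w = w / w.sum()
        A = self_transition * np.eye(K) + (1 - self_transition) * np.tile(w, (K, 1))
        pi = w.copy()
    elif balanced:
        pi = np.full(K, 1.0 / K)
        A = np.full((K, K), (1 - self_transition) / (K - 1))
        np.fill_diagonal(A, self_transition)
    else:
        pi = rng.dirichlet(np.full(K, 2.0))
        A = self_transition * np.eye(K) + (1 - self_transition) * rng.dirichlet(
            np.ones(K), size=K
        )
        A /= A.sum(axis=1, keepdims=True)
        pi /= pi.sum()

    logits = np.linspace(-1.0, 1.0, K) * mortality_logit_scale if K > 1 else np.zeros(1)
    rng.shuffle(logits)

    affinity = rng.dirichlet(
        np.full(len(diagnosis_codes), diagnosis_concentration), size=K
    )
    affinity /= affinity.sum(axis=1, keepdims=True)

    gt = GroundTruth(
        K_true=K,
        params_true=HMMParameters(pi=pi, A=A, means=means, covariances=covs),
        mortality_logit_per_state=logits,
        base_mortality_logit=base_mortality_logit,
        diagnosis_affinity=affinity,
        diagnosis_codes=tuple(diagnosis_codes),
        seed=seed,
    )
    gt.validate()
    return gt


def simulate_state_path(
    gt: GroundTruth, length: int, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Sample a latent state sequence: first state ~ pi, transitions ~ A."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = gt.params_true
    states = np.empty(length, dtype=int)
    states[0] = rng.choice(p.K, p=p.pi)
    for t in range(1, length):
        states[t] = rng.choice(p.K, p=p.A[states[t - 1]])
    return states


def _sample_latent(
    gt: GroundTruth, states: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    p = gt.params_true
    chols = [np.linalg.cholesky(S) for S in p.covariances]
    T = len(states)
    out = np.empty((T, p.D))
    z = rng.standard_normal((T, p.D))
    for t, s in enumerate(states):
        out[t] = p.means[s] + chols[s] @ z[t]
    return out


def emit_observations(
    states: np.ndarray,
    gt: GroundTruth,
    sampling: SamplingConfig | None = None,
    seed: int | np.random.Generator = 0,
    admit_date: date = date(2015, 1, 6),
    latent: np.ndarray | None = None,
    blood_prob_multiplier: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Scatter per-day latent draws into irregular timestamped events.

    Each blood test appears 0-2 times per day (the earliest event carries
    the day's latent value exactly; same-day duplicates get small Gaussian
    jitter), each vital sign 1-``vitals_max_per_day`` times per day when
    present. Timestamps fall strictly within the day.

    Returns the long-format observation frame and the latent daily matrix.
    """
    states = np.asarray(states, dtype=int)
    if states.size == 0:
        raise ValueError("empty state sequence")
    if sampling is None:
        sampling = SamplingConfig()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if latent is None:
        latent = _sample_latent(gt, states, rng)
    var_sd = gt.variable_sd()
    jitter_sd = sampling.jitter_sd_fraction * var_sd

    base_blood = sampling.blood_probs()
    vital_p = sampling.vital_probs()
    rows_var: list[str] = []
    rows_ts: list[pd.Timestamp] = []
    rows_val: list[float] = []
    day0 = pd.Timestamp(admit_date)

    for t, _s in enumerate(states):
        day_start = day0 + pd.Timedelta(days=t)
        blood_p = base_blood
        if blood_prob_multiplier is not None:
            blood_p = np.clip(base_blood * blood_prob_multiplier[states[t]], 0.0, 1.0)
        present = rng.random(N_BLOOD_TESTS) < blood_p
        # blood draws cluster in the morning
        first_frac = rng.uniform(0.2, 0.5, size=N_BLOOD_TESTS)
        for j, name in enumerate(BLOOD_TESTS):
            if not present[j]:
                continue
            value = latent[t, j]
            rows_var.append(name)
            rows_ts.append(day_start + pd.Timedelta(seconds=first_frac[j] * 86_400))
            rows_val.append(value)
            if rng.random() < sampling.blood_test_repeat_prob:
                frac = rng.uniform(first_frac[j], 0.999)
                rows_var.append(name)
                rows_ts.append(day_start + pd.Timedelta(seconds=frac * 86_400))
                rows_val.append(value + rng.normal(0.0, jitter_sd[j]))
        v_present = rng.random(len(VITAL_SIGNS)) < vital_p
        for jj, name in enumerate(VITAL_SIGNS):
            if not v_present[jj]:
                continue
            j = N_BLOOD_TESTS + jj
            n_events = int(rng.integers(1, sampling.vitals_max_per_day + 1))
            fracs = np.sort(rng.uniform(0.01, 0.999, size=n_events))
            for i, frac in enumerate(fracs):
                jit = 0.0 if i == 0 else rng.normal(0.0, jitter_sd[j])
                rows_var.append(name)
                rows_ts.append(day_start + pd.Timedelta(seconds=frac * 86_400))
                rows_val.append(latent[t, j] + jit)

    obs = pd.DataFrame(
        {"variable": rows_var, "timestamp": rows_ts, "value": rows_val}
    ).sort_values("timestamp", kind="stable", ignore_index=True)
    return obs, latent


def assign_outcome(
    states: np.ndarray,
    gt: GroundTruth,
    seed: int | np.random.Generator = 0,
    survivor_proportions: tuple[float, ...] = (0.70, 0.15, 0.08, 0.07),
    latent: np.ndarray | None = None,
    value_weights: np.ndarray | None = None,
    value_days: int | None = None,
) -> str:
    """Draw the episode outcome from the planted logistic mortality model.

    P(inpatient mortality) = logistic(base + mean over days of the
    per-state mortality log-odds); survivors split among DA/PDR/PDM/PDRM.

    With ``value_weights`` (and the episode's latent daily matrix), a
    continuous presenting-acuity term ``w . mean_t(x_t)`` is added to the
    logit, averaged over the first ``value_days`` days (all days when
    None): risk then depends on the continuous physiology, not only on the
    discrete state sequence, as it does for real patients.
    """
    states = np.asarray(states, dtype=int)
    if states.size == 0:
        raise ValueError("empty state sequence")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    logit = gt.base_mortality_logit + float(
        np.mean(gt.mortality_logit_per_state[states])
    )
    if value_weights is not None:
        if latent is None:
            raise ValueError("value_weights requires the latent daily matrix")
        window = latent if value_days is None else latent[:value_days]
        logit += float(np.asarray(value_weights) @ window.mean(axis=0))
    if rng.random() < expit(logit):
        return "IM"
    props = np.asarray(survivor_proportions, dtype=float)
    props = props / props.sum()
    return str(rng.choice(list(OUTCOMES[1:]), p=props))


def _sample_phenotype(
    rng: np.random.Generator, diagnosis: str, female_fraction: float
) -> PhenotypeRecord:
    age = 65 + int(min(rng.poisson(14), 40))
    sex = "F" if rng.random() < female_fraction else "M"
    cfs = int(np.clip(round(rng.normal(5.0, 2.0)), 1, 9))
    return PhenotypeRecord(age=age, sex=sex, cfs=cfs, admission_diagnosis=diagnosis)


def simulate_cohort(
    config: CohortConfig,
    seed: int = 0,
    ground_truth: GroundTruth | None = None,
    emit: bool = True,
) -> tuple[list[SyntheticEpisode], GroundTruth]:
    """Generate one admission episode per patient, reproducibly.

    A single seed drives ground-truth sampling and every per-patient
    stream; identical (config, seed) pairs give identical cohorts. With
    ``emit=False`` the timestamped event scatter is skipped and each
    episode carries only its latent daily matrix (cheaper, for experiments
    that work on complete matrices).
    """
    ss = np.random.SeedSequence(seed)
    gt_seed, cohort_seed = ss.spawn(2)
    if ground_truth is None:
        ground_truth = sample_ground_truth(
            K=config.K,
            D=config.D,
            separation=config.separation,
            seed=int(gt_seed.generate_state(1)[0] % (2**31)),
            self_transition=config.self_transition,
            base_mortality_logit=config.base_mortality_logit,
            mortality_logit_scale=config.mortality_logit_scale,
            diagnosis_codes=config.diagnosis_codes,
            diagnosis_concentration=config.diagnosis_concentration,
            covariance=config.covariance,
            balanced=config.balanced,
        )
    rng = np.random.default_rng(cohort_seed)
    episodes: list[SyntheticEpisode] = []
    width = len(str(max(config.n_patients - 1, 1)))
    for i in range(config.n_patients):
        length = config.min_length + int(
            rng.poisson(config.mean_length - config.min_length)
        )
        states = simulate_state_path(ground_truth, length, rng)
        admit = config.admit_start + timedelta(days=int(rng.integers(0, 365)))
        latent = None
        if config.patient_effect_sd > 0:
            # persistent per-patient baseline offset
            offset = np.zeros(ground_truth.params_true.D)
            idx = (
                np.arange(ground_truth.params_true.D)
                if config.patient_effect_variables is None
                else np.asarray(config.patient_effect_variables, dtype=int)
            )
            offset[idx] = rng.normal(0.0, config.patient_effect_sd, size=idx.size)
            latent = _sample_latent(ground_truth, states, rng) + offset
        if emit:
            obs, latent = emit_observations(
                states,
                ground_truth,
                sampling=config.sampling,
                seed=rng,
                admit_date=admit,
                latent=latent,
                blood_prob_multiplier=config.missingness_multiplier_by_state,
            )
        else:
            if latent is None:
                latent = _sample_latent(ground_truth, states, rng)
            obs = pd.DataFrame(columns=["variable", "timestamp", "value"])
        outcome = assign_outcome(
            states,
            ground_truth,
            rng,
            survivor_proportions=config.survivor_proportions,
            latent=latent,
            value_weights=config.mortality_value_weights,
            value_days=config.mortality_value_days,
        )
        modal = int(np.bincount(states, minlength=ground_truth.K_true).argmax())
        diagnosis = str(
            rng.choice(
                list(ground_truth.diagnosis_codes),
                p=ground_truth.diagnosis_affinity[modal],
            )
        )
        phenotype = _sample_phenotype(rng, diagnosis, config.female_fraction)
        pid = f"P{i:0{width}d}"
        obs.insert(0, "patient_id", pid)
        episodes.append(
            SyntheticEpisode(
                patient_id=pid,
                admit_date=admit,
                true_states=states,
                latent_daily=latent,
                observations=obs,
                phenotype=phenotype,
                outcome=outcome,
            )
        )
    return episodes, ground_truth


def cohort_to_frames(
    episodes: list[SyntheticEpisode],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long observations frame + one-row-per-episode metadata frame."""
    obs = pd.concat([e.observations for e in episodes], ignore_index=True)
    meta = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in episodes],
            "admit_date": [e.admit_date.isoformat() for e in episodes],
            "length_days": [e.length for e in episodes],
            "outcome": [e.outcome for e in episodes],
            "age": [e.phenotype.age for e in episodes],
            "sex": [e.phenotype.sex for e in episodes],
            "cfs": [e.phenotype.cfs for e in episodes],
            "diagnosis": [e.phenotype.admission_diagnosis for e in episodes],
        }
    )
    return obs, meta


def write_cohort(
    episodes: list[SyntheticEpisode],
    ground_truth: GroundTruth,
    out_dir: str | Path,
) -> None:
    """Write observations.csv, episodes.csv and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs, meta = cohort_to_frames(episodes)
    obs = obs.copy()
    obs["timestamp"] = obs["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    obs.to_csv(out / "observations.csv", index=False)
    meta.to_csv(out / "episodes.csv", index=False)
    ground_truth.save(out / "ground_truth.json")
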