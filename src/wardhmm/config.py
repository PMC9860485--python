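"""Protocol constants and the variable manifest.

The pipeline models 23 routinely collected inpatient variables: 17 blood
tests and 5 bedside vital signs. Variable names are a fixed manifest; raw
units are irrelevant downstream because all values are inverse-rank
normalized before modelling.
"""

from __future__ import annotations

from fractions import Fraction

#: 17 commonly requested blood tests.
BLOOD_TESTS: tuple[str, ...] = (
    "haemoglobin",
    "haematocrit",
    "wbc",
    "neutrophils",
    "lymphocytes",
    "monocytes",
    "eosinophils",
    "basophils",
    "platelets",
    "sodium",
    "potassium",
    "urea",
    "creatinine",
    "albumin",
    "alt",
    "alkaline_phosphatase",
    "bilirubin",
)

#: 6 bedside vital-sign variables (blood pressure contributes systolic and
#: diastolic readings), completing the 23-variable panel.
VITAL_SIGNS: tuple[str, ...] = (
    "respiratory_rate",
    "pulse_rate",
    "systolic_bp",
    "diastolic_bp",
    "temperature",
    "oxygen_saturation",
)

#: Full manifest, blood tests first then vitals; column order everywhere.
VARIABLES: tuple[str, ...] = BLOOD_TESTS + VITAL_SIGNS

N_BLOOD_TESTS = len(BLOOD_TESTS)
N_VITAL_SIGNS = len(VITAL_SIGNS)
N_VARIABLES = len(VARIABLES)

#: A day is "rich-information" iff at least this many blood tests ...
RICH_MIN_BLOOD_TESTS = 14
#: ... and at least this many vital signs were observed that day.
RICH_MIN_VITAL_SIGNS = 4

#: Minimum length of stay (days) for an episode to be included.
MIN_LENGTH_OF_STAY = 3

#: Episodes are kept only while poor-information days are STRICTLY fewer
#: than this fraction of the episode length.
MAX_POOR_FRACTION = Fraction(1, 3)

#: Patient-level train fraction for the train/hold-out split.
TRAIN_FRACTION = 0.8

#: Number of multiply-imputed datasets.
N_IMPUTATIONS = 10

#: Default number of hidden states for the production model.
DEFAULT_N_STATES = 17

#: Cell-wise significance level before Bonferroni correction.
ASSOCIATION_ALPHA = 0.001

#: Outcome-prediction tuning protocol: inner 80/20 split, 5-fold CV grid
#: search on the inner-train part, repeated 10 times.
TUNE_INNER_TRAIN_FRACTION = 0.8
TUNE_CV_FOLDS = 5
TUNE_REPEATS = 10

#: Outcome labels: inpatient mortality; discharged alive; 30-day
#: post-discharge readmission; 30-day post-discharge mortality; both.
OUTCOMES: tuple[str, ...] = ("IM", "DA", "PDR", "PDM", "PDRM")

#: Default top-level admission-diagnosis code alphabet (ICD-10 chapters
#: commonly seen in older-adult emergency admissions).
DIAGNOSIS_CODES: tuple[str, ...] = ("C", "D", "I", "K", "N", "R")

VARIABLE_INDEX: dict[str, int] = {v: i for i, v in enumerate(VARIABLES)}
BLOOD_TEST_COLUMNS = tuple(range(N_BLOOD_TESTS))
VITAL_COLUMNS = tuple(range(N_BLOOD_TESTS, N_VARIABLES))


def is_blood_test(variable: str) -> bool:
    return variable in BLOOD_TESTS


def is_vital_sign(variable: str) -> bool:
    return variable in VITAL_SIGNS
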