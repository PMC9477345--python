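"""ICU-cohort preprocessing: binarization operators and a synthetic cohort.

Five binary features are derived from each patient's record: an age cut, two
body-mass-index (BMI) indicator bits, and threshold tests on the
*accumulation score* of the daily minima of two physiological series over
the first seven ICU days — the PaO2/FiO2 oxygenation index (mmHg) and the
urine output (ml/d).  The accumulation score weights day i by 8 - i
(weights 7..1), emphasising the days right after admission.

The five bits feed a 2-module tree-SHM — a Biometric block (age and the two
BMI bits) and a Physiology block (the two accumulated scores) — whose output
is the patient's vital status.  Because no patient-level dataset is
publicly deposited, a synthetic cohort generator provides a stand-in with
marginal medians on the scale of the real cohort and outcomes produced by a
planted tree-SHM over the binarized bits, so the downstream learner has
recoverable structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import Bits, GroundTruthSHM, LabeledDataset, TreeStructure, as_bits
from .synthetic import generate_ground_truth

SURVIVOR = "survivor"
NON_SURVIVOR = "non-survivor"

#: Fixed order of the five binary features.
FEATURE_NAMES = ("age", "bmi_1", "bmi_2", "acc_pao2fio2", "acc_urine")

#: Biometric block (age + 2 BMI bits) and Physiology block (2 Acc bits).
COVID_STRUCTURE = TreeStructure((3, 2))

N_DAYS = 7


@dataclass(frozen=True)
class BinarizationRules:
    """Threshold rules mapping continuous patient features to the five bits.

    The BMI cuts must satisfy ``bmi_low < bmi_mid < bmi_high``; the second
    BMI bit is 1 inside [bmi_low, bmi_mid) or at/above bmi_high.  The
    polarity of each accumulated score follows the rule tables: a *low*
    accumulated PaO2/FiO2 maps to 1, a *high* accumulated urine output
    maps to 1.
    """

    age_cut: float = 60.0
    bmi_mid: float = 26.0
    bmi_low: float = 24.2
    bmi_high: float = 32.0
    pf_cut: float = 298.0
    urine_cut: float = 9584.0

    def __post_init__(self) -> None:
        if not self.bmi_low < self.bmi_mid < self.bmi_high:
            raise ValueError(
                f"BMI cuts must be strictly ordered, got "
                f"{self.bmi_low}, {self.bmi_mid}, {self.bmi_high}"
            )

    def to_json(self) -> dict:
        return {
            "age_cut": self.age_cut,
            "bmi_mid": self.bmi_mid,
            "bmi_low": self.bmi_low,
            "bmi_high": self.bmi_high,
            "pf_cut": self.pf_cut,
            "urine_cut": self.urine_cut,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "BinarizationRules":
        return cls(**obj)


@dataclass
class PatientSeries:
    """One patient: static attributes plus per-day measurement lists.

    ``daily_values[param]`` holds one list of within-day measurements for
    each of ICU days 1..7.
    """

    patient_id: str
    age: float
    bmi: float
    daily_values: dict[str, list[list[float]]]
    outcome: str

    def __post_init__(self) -> None:
        if self.age <= 0 or self.bmi <= 0:
            raise ValueError("age and BMI must be positive")
        if self.outcome not in (SURVIVOR, NON_SURVIVOR):
            raise ValueError(f"outcome must be '{SURVIVOR}' or '{NON_SURVIVOR}'")
        for param, days in self.daily_values.items():
            if len(days) != N_DAYS:
                raise ValueError(
                    f"{param}: expected {N_DAYS} days, got {len(days)}"
                )

    @property
    def died(self) -> bool:
        return self.outcome == NON_SURVIVOR


def accumulation_score(x: Sequence[float]) -> float:
    """Weighted 7-day sum with weight 8 - i for day i (weights 7..1)."""
    vals = np.asarray(x, dtype=float)
    if vals.shape != (N_DAYS,):
        raise ValueError(f"expected {N_DAYS} daily values, got shape {vals.shape}")
    weights = np.arange(N_DAYS, 0, -1, dtype=float)
    return float(weights @ vals)


def daily_min_sequence(
    measurements: Sequence[Sequence[float]], impute: bool = False
) -> list[float]:
    """Per-day minima over the within-day measurement lists.

    An empty day is an error unless ``impute`` carries the previous day's
    minimum forward (the first day can never be imputed).
    """
    if len(measurements) != N_DAYS:
        raise ValueError(f"expected {N_DAYS} days, got {len(measurements)}")
    minima: list[float] = []
    for day, values in enumerate(measurements, start=1):
        if len(values) == 0:
            if impute and minima:
                minima.append(minima[-1])
                continue
            raise ValueError(f"day {day} has no measurements")
        minima.append(float(min(values)))
    return minima


def binarize_patient(
    p: PatientSeries, rules: BinarizationRules | None = None, impute: bool = False
) -> Bits:
    """Five bits (age, BMI-1, BMI-2, Acc-PaO2/FiO2, Acc-urine) per the rules."""
    rules = rules or BinarizationRules()
    age_bit = int(p.age >= rules.age_cut)
    bmi1 = int(p.bmi >= rules.bmi_mid)
    bmi2 = int(rules.bmi_low <= p.bmi < rules.bmi_mid or p.bmi >= rules.bmi_high)
    acc_pf = accumulation_score(
        daily_min_sequence(p.daily_values["pao2fio2"], impute=impute)
    )
    acc_urine = accumulation_score(
        daily_min_sequence(p.daily_values["urine"], impute=impute)
    )
    pf_bit = int(acc_pf < rules.pf_cut)
    urine_bit = int(acc_urine >= rules.urine_cut)
    return (age_bit, bmi1, bmi2, pf_bit, urine_bit)


@dataclass(frozen=True)
class CohortLabeling:
    """Distinct bit patterns with their mortality ratios and labels."""

    patterns: pd.DataFrame  # columns: pattern, count, deaths, ratio, label
    threshold: float
    n_patients: int

    @property
    def n_patterns(self) -> int:
        return len(self.patterns)

    def to_dataset(self, structure: TreeStructure = COVID_STRUCTURE) -> LabeledDataset:
        records = [
            (tuple(row.pattern), int(row.label))
            for row in self.patterns.itertuples()
        ]
        return LabeledDataset.from_records(records, structure)


def cohort_mortality_labels(
    patients: Iterable[tuple[Sequence[int], str | int]],
    threshold: float = 0.75,
    strict_inequality: bool = False,
) -> CohortLabeling:
    """Group identical bit patterns and label them by mortality ratio.

    A pattern's label is 1 when its ratio of non-survivors reaches the
    threshold (``>=`` by default, ``>`` with ``strict_inequality``); label 1
    therefore marks high-mortality patterns.
    """
    counts: dict[Bits, list[int]] = {}
    n_patients = 0
    for bits, outcome in patients:
        bits = as_bits(bits)
        died = (
            outcome == NON_SURVIVOR if isinstance(outcome, str) else bool(outcome)
        )
        entry = counts.setdefault(bits, [0, 0])
        entry[0] += 1
        entry[1] += int(died)
        n_patients += 1
    if n_patients == 0:
        raise ValueError("empty cohort")
    rows = []
    for bits in sorted(counts):
        count, deaths = counts[bits]
        ratio = deaths / count
        label = int(ratio > threshold if strict_inequality else ratio >= threshold)
        rows.append(
            {"pattern": bits, "count": count, "deaths": deaths,
             "ratio": ratio, "label": label}
        )
    return CohortLabeling(pd.DataFrame(rows), threshold, n_patients)


# -- synthetic cohort ------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated patients plus the planted ground truth behind their outcomes."""

    patients: list[PatientSeries]
    planted: GroundTruthSHM
    rules: BinarizationRules
    structure: TreeStructure

    def binarized(self, impute: bool = False) -> list[tuple[Bits, str]]:
        return [
            (binarize_patient(p, self.rules, impute=impute), p.outcome)
            for p in self.patients
        ]


def _daily_series(
    rng: np.random.Generator, level: float, day_sigma: float, n_meas: int = 3
) -> list[list[float]]:
    """Seven days of within-day measurement lists around a patient level."""
    days = []
    for _ in range(N_DAYS):
        base = level * float(np.exp(rng.normal(0.0, day_sigma)))
        extra = base * np.exp(np.abs(rng.normal(0.0, 0.1, size=n_meas - 1)))
        days.append([base] + [float(v) for v in extra])
    return days


def generate_synthetic_cohort(
    rng: np.random.Generator,
    n_patients: int = 63,
    structure: TreeStructure = COVID_STRUCTURE,
    rules: BinarizationRules | None = None,
    planted: GroundTruthSHM | None = None,
    noise_p: float = 0.0,
) -> SyntheticCohort:
    """Synthetic ICU cohort with outcomes driven by a planted tree-SHM.

    Static and physiological marginals are calibrated so cohort medians sit
    on the scale of the real admission statistics (age ~ 62 y, BMI ~ 29,
    PaO2/FiO2 ~ 92 mmHg, urine ~ 780 ml/d) while every binarization
    threshold splits the cohort; the PaO2/FiO2 weekly level uses a
    two-component severity mixture whose low mode is deliberately extreme so
    the accumulated-minimum cut at 298 separates patient groups.  The vital
    status is the planted model's output on the patient's five bits, flipped
    independently with probability ``noise_p``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    rules = rules or BinarizationRules()
    if planted is None:
        planted = generate_ground_truth(rng, structure, reject_constant=True)
    elif planted.structure != structure:
        raise ValueError("planted model was built for a different structure")
    patients: list[PatientSeries] = []
    for idx in range(n_patients):
        age = float(np.clip(rng.normal(62.0, 9.0), 20.0, 95.0))
        bmi = float(np.exp(rng.normal(np.log(29.0), 0.17)))
        if rng.random() < 0.30:  # refractory-hypoxemia mode
            pf_level = float(np.exp(rng.normal(np.log(7.0), 0.6)))
        else:
            pf_level = float(np.exp(rng.normal(np.log(125.0), 0.45)))
        urine_level = float(np.exp(rng.normal(np.log(780.0), 1.2)))
        daily = {
            "pao2fio2": _daily_series(rng, pf_level, 0.15),
            "urine": _daily_series(rng, urine_level, 0.20),
        }
        probe = PatientSeries(
            patient_id=f"synthetic-{idx:03d}",
            age=age,
            bmi=bmi,
            daily_values=daily,
            outcome=SURVIVOR,
        )
        bits = binarize_patient(probe, rules)
        label = planted.evaluate_code(
            int("".join(map(str, bits)), 2)
        )
        if noise_p > 0 and rng.random() < noise_p:
            label = 1 - label
        probe.outcome = NON_SURVIVOR if label == 1 else SURVIVOR
        patients.append(probe)
    return SyntheticCohort(patients, planted, rules, structure)
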