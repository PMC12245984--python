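"""Derived predictors, eligibility filtering and preclinical staging.

Covers the full variable catalogue used by the model space: demographics
(age, log age, gender, BMI and BMI z score), genetics (GRS2), immunology
(IA-2A positivity or the seven-level autoantibody-combination factor) and
metabolism (fasting C-peptide, time-averaged OGTT glucose and C-peptide,
HbA1c and composite scores held in a data-driven score registry).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import (
    AUTOANTIBODIES,
    Cohort,
    EmptyCohortError,
    OGTT_MINUTES,
    Participant,
)


class MissingInputError(KeyError):
    """A score or feature needs an input the participant record lacks."""


class StagingError(ValueError):
    """Participant violates the staging domain (e.g. zero autoantibodies)."""


class AgeRangeError(ValueError):
    """Age lies below the support of the BMI reference table."""


# ---------------------------------------------------------------------------
# thresholds


@dataclass(frozen=True)
class GlycaemiaThresholds:
    """Diabetes-range exclusion limits and the impaired (dysglycaemia) band.

    Exclusion uses the diabetes-range criteria (fasting >= 7.0 mmol/l,
    2 h >= 11.1 mmol/l, HbA1c >= 48 mmol/mol, all inclusive).  Stage 2 versus
    stage 1 is split by the impaired-glycaemia band (fasting >= 5.6 mmol/l,
    2 h >= 7.8 mmol/l or HbA1c >= 39 mmol/mol).
    """

    diabetes_fasting: float = 7.0
    diabetes_2h: float = 11.1
    diabetes_hba1c: float = 48.0
    impaired_fasting: float = 5.6
    impaired_2h: float = 7.8
    impaired_hba1c: float = 39.0


DEFAULT_THRESHOLDS = GlycaemiaThresholds()


@dataclass(frozen=True)
class StageLabel:
    value: str  # "single_ab" | "stage1" | "stage2"

    def __post_init__(self):
        if self.value not in ("single_ab", "stage1", "stage2"):
            raise ValueError(f"unknown stage {self.value!r}")


def _is_hyperglycaemic(p: Participant, thr: GlycaemiaThresholds) -> list[str]:
    reasons = []
    if p.ogtt_glucose[0] >= thr.diabetes_fasting:
        reasons.append("fasting_glucose")
    if p.ogtt_glucose[-1] >= thr.diabetes_2h:
        reasons.append("2h_glucose")
    if p.hba1c >= thr.diabetes_hba1c:
        reasons.append("hba1c")
    return reasons


def _is_incomplete(p: Participant) -> bool:
    values = [p.age, p.bmi, p.grs2, p.hba1c, p.followup_time]
    values += list(p.ogtt_glucose) + list(p.ogtt_cpeptide)
    return (
        any(v is None or not np.isfinite(v) for v in values)
        or len(p.ogtt_glucose) != len(OGTT_MINUTES)
        or len(p.ogtt_cpeptide) != len(OGTT_MINUTES)
    )


def apply_eligibility_filters(
    cohort: Cohort, thresholds: GlycaemiaThresholds = DEFAULT_THRESHOLDS
) -> tuple[Cohort, pd.DataFrame]:
    """Remove baseline-hyperglycaemic and incomplete participants.

    Returns the eligible cohort and an exclusion log with one row per removed
    participant (``id``, ``reason``).  Any diabetes-range criterion at
    baseline excludes (thresholds inclusive); records with missing or
    non-finite fields are excluded as ``incomplete``.
    """
    keep, log = [], []
    for p in cohort:
        if _is_incomplete(p):
            log.append({"id": p.id, "reason": "incomplete"})
            continue
        reasons = _is_hyperglycaemic(p, thresholds)
        if reasons:
            log.append({"id": p.id, "reason": "hyperglycaemia:" + "+".join(reasons)})
        else:
            keep.append(p)
    return (
        Cohort(keep, provenance=cohort.provenance),
        pd.DataFrame(log, columns=["id", "reason"]),
    )


def assign_stage(
    participant: Participant, thresholds: GlycaemiaThresholds = DEFAULT_THRESHOLDS
) -> StageLabel:
    """Preclinical stage: single autoantibody, stage 1 (multiple autoantibodies,
    normoglycaemia) or stage 2 (multiple autoantibodies with dysglycaemia)."""
    n_ab = participant.n_autoantibodies
    if n_ab == 0:
        raise StagingError(f"{participant.id}: no autoantibodies")
    if n_ab == 1:
        return StageLabel("single_ab")
    dysglycaemic = (
        participant.ogtt_glucose[0] >= thresholds.impaired_fasting
        or participant.ogtt_glucose[-1] >= thresholds.impaired_2h
        or participant.hba1c >= thresholds.impaired_hba1c
    )
    return StageLabel("stage2" if dysglycaemic else "stage1")


# ---------------------------------------------------------------------------
# OGTT area under the curve


def auc_over_ogtt(
    times: Sequence[float], values: Sequence[float], time_average: bool = True
) -> float:
    """Trapezoidal area under an OGTT analyte curve.

    With ``time_average=True`` (default) the area is divided by the total
    duration so the result stays in the analyte's concentration units.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.ndim != 1 or t.size < 2 or v.shape != t.shape:
        raise ValueError("need >= 2 matched time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    area = float(np.trapezoid(v, t))
    return area / float(t[-1] - t[0]) if time_average else area


# ---------------------------------------------------------------------------
# BMI z score via LMS reference tables


def load_lms_tables(path=None) -> pd.DataFrame:
    """Load an LMS (lambda-mu-sigma) BMI-for-age reference table.

    The packaged default, ``bmi_lms_synthetic.csv``, is a synthetic reference
    with realistic growth-curve shape shipped so the package is
    self-contained; substitute a published table (same columns: ``gender``,
    ``age``, ``L``, ``M``, ``S``) for real analyses.
    """
    if path is None:
        with resources.files("t1dpred.data").joinpath("bmi_lms_synthetic.csv").open() as fh:
            return pd.read_csv(fh)
    return pd.read_csv(str(path))


def bmi_zscore(
    bmi: float, age: float, gender: str, reference: pd.DataFrame
) -> float:
    """Age- and gender-adjusted BMI z score via the LMS transform.

    Adults are harmonised to the paediatric scale by using the age-20
    reference row for every age of 20 years or more.  L, M and S are
    interpolated linearly in age within the table's support; ages below the
    support raise :class:`AgeRangeError`.
    """
    if bmi <= 0 or age <= 0:
        raise ValueError("bmi and age must be positive")
    sub = reference[reference["gender"] == gender].sort_values("age")
    if sub.empty:
        raise ValueError(f"no reference rows for gender {gender!r}")
    ages = sub["age"].to_numpy(dtype=float)
    eff_age = min(age, 20.0)
    if eff_age < ages[0]:
        raise AgeRangeError(f"age {age} below table support {ages[0]}")
    eff_age = min(eff_age, ages[-1])
    L = float(np.interp(eff_age, ages, sub["L"].to_numpy(dtype=float)))
    M = float(np.interp(eff_age, ages, sub["M"].to_numpy(dtype=float)))
    S = float(np.interp(eff_age, ages, sub["S"].to_numpy(dtype=float)))
    if abs(L) < 1e-12:
        return float(np.log(bmi / M) / S)
    return float(((bmi / M) ** L - 1.0) / (L * S))


# ---------------------------------------------------------------------------
# score registry

_MGDL_PER_MMOLL = 18.016  # glucose molar mass conversion


def _transform(value: float, transform: str) -> float:
    if transform in (None, "identity"):
        return float(value)
    if transform == "log":
        if value <= 0:
            raise ValueError("log transform needs a positive input")
        return float(np.log(value))
    if transform == "glucose_mgdl":
        return float(value) * _MGDL_PER_MMOLL
    raise ValueError(f"unknown transform {transform!r}")


@dataclass(frozen=True)
class ScoreRegistry:
    """Data-driven registry of composite risk scores.

    Each entry is linear in (transformed) participant inputs:
    ``score = intercept + sum(coef_k * transform_k(input_k))``.  Entries are
    data, not code, so published coefficient sets can be swapped in without
    touching the package.
    """

    entries: Mapping[str, Mapping]

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def names(self) -> list[str]:
        return sorted(self.entries)

    def required_inputs(self, name: str) -> list[str]:
        return [t["input"] for t in self.entries[name].get("terms", [])]


def load_score_registry(path=None) -> ScoreRegistry:
    """Load a YAML score registry; defaults to the packaged registry.

    The packaged Index60 entry carries its published coefficients; the other
    classical-score entries are synthetic placeholders (documented in the
    file) so the pipeline runs end-to-end without the primary sources.
    """
    if path is None:
        with resources.files("t1dpred.data").joinpath(
            "score_registry_synthetic.yaml"
        ).open() as fh:
            raw = yaml.safe_load(fh)
    else:
        with open(str(path)) as fh:
            raw = yaml.safe_load(fh)
    return ScoreRegistry(raw)


def participant_inputs(participant: Participant) -> dict[str, float]:
    """Flat input dictionary a score term's ``input`` field resolves against."""
    d: dict[str, float] = {
        "age": participant.age,
        "bmi": participant.bmi,
        "grs2": participant.grs2,
        "hba1c": participant.hba1c,
        "gender_female": 1.0 if participant.gender == "female" else 0.0,
        "n_autoantibodies": float(participant.n_autoantibodies),
    }
    for m, g, c in zip(OGTT_MINUTES, participant.ogtt_glucose, participant.ogtt_cpeptide):
        d[f"glucose_{m}"] = g
        d[f"cpeptide_{m}"] = c
    return d


def compute_score(name: str, participant: Participant, registry: ScoreRegistry) -> float:
    """Evaluate one registry score for one participant."""
    if name not in registry:
        raise KeyError(f"score {name!r} not in registry")
    entry = registry.entries[name]
    inputs = participant_inputs(participant)
    total = float(entry.get("intercept", 0.0))
    for term in entry.get("terms", []):
        key = term["input"]
        if key not in inputs:
            raise MissingInputError(key)
        total += float(term["coef"]) * _transform(inputs[key], term.get("transform"))
    return total


# ---------------------------------------------------------------------------
# feature vectors

AB_COMBINATION_LEVELS = (
    "GADA",
    "IAA",
    "IA2A",
    "GADA+IAA",
    "GADA+IA2A",
    "IAA+IA2A",
    "GADA+IAA+IA2A",
)


def ab_combination(participant: Participant) -> str:
    present = [a for a in AUTOANTIBODIES if a in participant.autoantibodies]
    if not present:
        raise StagingError(f"{participant.id}: no autoantibodies")
    return "+".join(present)


#: registry scores surfaced as named feature-catalogue variables
SCORE_FEATURES = ("index60", "cpeptide30", "beta2", "dptrs", "dptrs60", "m120", "cph", "lr")


def build_feature_vector(
    participant: Participant,
    registry: ScoreRegistry,
    lms_reference: pd.DataFrame,
    scores: Sequence[str] = SCORE_FEATURES,
) -> dict[str, float | str]:
    """All catalogue variables for one participant.

    Missing-input errors from score evaluation propagate; there is no
    imputation (incomplete records are excluded upstream).
    """
    minutes = np.asarray(OGTT_MINUTES, dtype=float)
    vec: dict[str, float | str] = {
        "age": participant.age,
        "log_age": float(np.log(participant.age)),
        "gender": 1.0 if participant.gender == "female" else 0.0,
        "bmi": participant.bmi,
        "bmi_z": bmi_zscore(participant.bmi, participant.age, participant.gender, lms_reference),
        "grs2": participant.grs2,
        "ia2a_flag": 1.0 if "IA2A" in participant.autoantibodies else 0.0,
        "ab_combination": ab_combination(participant),
        "fasting_cpeptide": participant.ogtt_cpeptide[0],
        "auc_cpeptide": auc_over_ogtt(minutes, participant.ogtt_cpeptide),
        "auc_glucose": auc_over_ogtt(minutes, participant.ogtt_glucose),
        "hba1c": participant.hba1c,
    }
    for name in scores:
        if name in registry:
            vec[name] = compute_score(name, participant, registry)
    return vec


def feature_matrix(
    cohort: Cohort,
    registry: ScoreRegistry | None = None,
    lms_reference: pd.DataFrame | None = None,
    thresholds: GlycaemiaThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Feature matrix for a cohort, indexed by participant id.

    Adds ``stage``, ``followup_time`` and ``event`` columns so the matrix is
    self-sufficient for survival model fitting.
    """
    if len(cohort) == 0:
        raise EmptyCohortError("cannot build features for an empty cohort")
    registry = registry if registry is not None else load_score_registry()
    lms_reference = lms_reference if lms_reference is not None else load_lms_tables()
    rows = []
    for p in cohort:
        row = build_feature_vector(p, registry, lms_reference)
        row["id"] = p.id
        row["entry_date"] = p.entry_date.isoformat()
        row["stage"] = assign_stage(p, thresholds).value
        row["followup_time"] = p.followup_time
        row["event"] = 1 if p.progressed else 0
        rows.append(row)
    df = pd.DataFrame(rows).set_index("id")
    return df


# ---------------------------------------------------------------------------
# printed study-flow bookkeeping


def load_study_flow(path=None) -> dict:
    """Published cohort-selection flow counts (screened, exclusions, events)."""
    if path is None:
        with resources.files("t1dpred.data").joinpath("study_flow.json").open() as fh:
            return json.load(fh)
    with open(str(path)) as fh:
        return json.load(fh)


def flow_summary(flow: Mapping[str, int]) -> dict[str, float]:
    """Eligible-cohort size and progression percentage from flow counts."""
    eligible = (
        int(flow["screened"])
        - int(flow["excluded_hyperglycaemia"])
        - int(flow["excluded_incomplete"])
    )
    pct = 100.0 * int(flow["progressed"]) / eligible if eligible else float("nan")
    return {"eligible_n": eligible, "pct_progressed": pct}
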