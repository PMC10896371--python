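"""EHR-based dementia case/control construction.

Eligibility mirrors real-world longitudinal-record phenotyping: patients need
complete demographics, at least two encounters strictly after their 55th
birthday, and a last recorded encounter before age 90 (older records are
censored).  Cases carry at least one dementia-coded encounter with onset
after age 55; controls carry no dementia-or-related code, are at least 70 at
their last visit, and have >= 5 years of records averaging >= 1 encounter
per year.  Modeling cohorts are drawn by sampling controls without
replacement at a fixed case:control ratio (default 1:3).

Ages are exact to the day (365.25-day years); code matching is by ICD-10
prefix, so G30 matches G30.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import PatientRecord

DEFAULT_DEMENTIA_PREFIXES = ("G30", "F01", "F02", "F03", "G31")
# dementia codes plus mild-cognitive-impairment / related organic syndromes
DEFAULT_EXCLUSION_PREFIXES = DEFAULT_DEMENTIA_PREFIXES + (
    "F05", "F06", "R41")


@dataclass(frozen=True)
class CohortDefinition:
    dementia_prefixes: tuple[str, ...] = DEFAULT_DEMENTIA_PREFIXES
    exclusion_prefixes: tuple[str, ...] = DEFAULT_EXCLUSION_PREFIXES
    min_onset_age: float = 55.0          # strict: onset must exceed this
    control_min_last_age: float = 70.0   # inclusive
    max_last_age: float = 90.0           # exclusive
    min_span_years: float = 5.0
    min_encounter_rate: float = 1.0      # encounters per span-year
    min_encounters_after_55: int = 2

    def __post_init__(self) -> None:
        if not set(self.dementia_prefixes) <= set(self.exclusion_prefixes):
            raise ValueError(
                "dementia prefixes must be a subset of exclusion prefixes")


@dataclass
class CohortSample:
    """One resampled modeling cohort with per-patient derived features."""

    case_ids: list[str]
    control_ids: list[str]
    features: pd.DataFrame  # patient_id, role, onset_age, last_age, span, rate

    @property
    def ids(self) -> list[str]:
        return self.case_ids + self.control_ids

    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.case_ids) + [0] * len(self.control_ids))


def _matches(code: str, prefixes) -> bool:
    return any(code.startswith(p) for p in prefixes)


def derive_features(rec: PatientRecord) -> dict:
    """Per-patient record summaries used by every filter."""
    dates = [d for d, _ in rec.encounters]
    if not dates:
        return {"patient_id": rec.patient_id, "n_encounters": 0,
                "first_age": np.nan, "last_age": np.nan, "span": 0.0,
                "rate": 0.0, "n_after_55": 0}
    first, last = min(dates), max(dates)
    span = (last - first).days / 365.25
    n = len(rec.encounters)
    return {
        "patient_id": rec.patient_id,
        "n_encounters": n,
        "first_age": rec.age_at(first),
        "last_age": rec.age_at(last),
        "span": span,
        "rate": n / span if span > 0 else np.inf,
        "n_after_55": sum(rec.age_at(d) > 55.0 for d in dates),
    }


def apply_base_filters(records: list[PatientRecord],
                       definition: CohortDefinition = CohortDefinition(),
                       ) -> tuple[list[PatientRecord], dict[str, list[str]]]:
    """Keep patients with complete demographics, >= 2 encounters strictly
    after age 55, and last-encounter age below 90 (exclusive).

    Returns ``(eligible, exclusions)`` where exclusions itemizes patient ids
    per violated rule (a patient may appear under several rules).
    """
    excl: dict[str, list[str]] = {
        "incomplete_demographics": [], "too_few_encounters_after_55": [],
        "last_age_90_or_over": []}
    eligible = []
    for rec in records:
        feats = derive_features(rec)
        ok = True
        if rec.sex not in ("female", "male") or rec.birth_date is None:
            excl["incomplete_demographics"].append(rec.patient_id)
            ok = False
        if feats["n_after_55"] < definition.min_encounters_after_55:
            excl["too_few_encounters_after_55"].append(rec.patient_id)
            ok = False
        if not feats["last_age"] < definition.max_last_age:
            excl["last_age_90_or_over"].append(rec.patient_id)
            ok = False
        if ok:
            eligible.append(rec)
    return eligible, excl


def select_cases(eligible: list[PatientRecord],
                 definition: CohortDefinition = CohortDefinition(),
                 ) -> dict[str, float]:
    """Case ids with onset ages.

    A case has >= 1 encounter carrying a dementia-prefix code, with the age
    at the *first* such encounter strictly above the minimum onset age;
    that age is the onset age.
    """
    cases: dict[str, float] = {}
    for rec in eligible:
        onset_dates = [d for d, codes in rec.encounters
                       if any(_matches(c, definition.dementia_prefixes)
                              for c in codes)]
        if not onset_dates:
            continue
        onset_age = rec.age_at(min(onset_dates))
        if onset_age > definition.min_onset_age:
            cases[rec.patient_id] = onset_age
    return cases


def select_control_pool(eligible: list[PatientRecord],
                        definition: CohortDefinition = CohortDefinition(),
                        ) -> list[str]:
    """Control ids: no exclusion-prefix code anywhere in the record, last
    visit at >= 70 (inclusive), >= 5 years of records, and an average of at
    least one encounter per span-year."""
    pool = []
    for rec in eligible:
        if any(_matches(c, definition.exclusion_prefixes)
               for _, codes in rec.encounters for c in codes):
            continue
        feats = derive_features(rec)
        if feats["last_age"] < definition.control_min_last_age:
            continue
        if feats["span"] < definition.min_span_years:
            continue
        if feats["rate"] < definition.min_encounter_rate:
            continue
        pool.append(rec.patient_id)
    return pool


def sample_case_control(cases: dict[str, float], pool: list[str],
                        records_by_id: dict[str, PatientRecord] | None = None,
                        ratio: int = 3, seed: int = 0) -> CohortSample:
    """Draw ``ratio`` controls per case uniformly without replacement.

    Deterministic under ``seed``.  Raises on zero cases or an insufficient
    pool, reporting the counts.
    """
    if not cases:
        raise ValueError("zero cases: cannot build a case-control sample")
    n_controls = ratio * len(cases)
    if len(pool) < n_controls:
        raise ValueError(
            f"control pool of {len(pool)} cannot supply {n_controls} "
            f"controls for {len(cases)} cases at ratio 1:{ratio}")
    rng = np.random.default_rng(seed)
    controls = sorted(rng.choice(sorted(pool), size=n_controls,
                                 replace=False).tolist())
    case_ids = sorted(cases)
    rows = []
    for pid in case_ids + controls:
        row = {"patient_id": pid,
               "role": "case" if pid in cases else "control",
               "onset_age": cases.get(pid, np.nan)}
        if records_by_id and pid in records_by_id:
            row.update({k: v for k, v in
                        derive_features(records_by_id[pid]).items()
                        if k != "patient_id"})
        rows.append(row)
    return CohortSample(case_ids, controls, pd.DataFrame(rows))


def build_cohort(records: list[PatientRecord],
                 definition: CohortDefinition = CohortDefinition(),
                 ) -> tuple[dict[str, float], list[str], dict[str, list[str]]]:
    """Full phenotyping pass: returns ``(cases, control_pool, exclusions)``."""
    eligible, excl = apply_base_filters(records, definition)
    cases = select_cases(eligible, definition)
    pool = select_control_pool(eligible, definition)
    return cases, pool, excl


def model_age(rec: PatientRecord, onset_age: float | None) -> float:
    """The age covariate used in risk models: onset age for cases, age at
    last encounter for controls (configurable upstream)."""
    if onset_age is not None and not np.isnan(onset_age):
        return float(onset_age)
    return derive_features(rec)["last_age"]
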