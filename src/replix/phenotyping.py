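"""Case/control assignment from self-reported survey answers.

A subject is a case for a phenotype if they answered affirmatively to at
least one of the phenotype's questions, a control if every answered
question was negative, and excluded otherwise: uncertain/declined-only
responders, subjects answering the same phenotype's questions
inconsistently (some yes, some no), and subjects failing onset-age, sex or
smoking restrictions.  For common diseases, controls can additionally be
required to have reached an age at which their residual lifetime risk —
(F_inf - F(a)) / (1 - F(a)) under the disease's cumulative-incidence curve
— is at most 10%, so that at least 90% of retained controls would be
expected never to develop the disease.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SurveyResponse",
    "PhenotypeDefinition",
    "IncidenceCurve",
    "PhenotypeAssignment",
    "assign_case_control",
    "restrict_controls_by_age",
    "apply_onset_and_matching",
]

AFFIRMATIVE = "affirmative"
NEGATIVE = "negative"
UNCERTAIN = "uncertain"
DECLINED = "declined"
_ANSWERS = {AFFIRMATIVE, NEGATIVE, UNCERTAIN, DECLINED}


@dataclass(frozen=True)
class SurveyResponse:
    subject_id: str
    question_id: str
    answer: str
    onset_age: float | None = None

    def __post_init__(self) -> None:
        if self.answer not in _ANSWERS:
            raise ValueError(f"unknown answer {self.answer!r}")


@dataclass(frozen=True)
class IncidenceCurve:
    """Cumulative disease incidence by age, linearly interpolated between
    tabulated points; the last value is the lifetime risk."""

    ages: Sequence[float]
    cum_incidence: Sequence[float]

    def __post_init__(self) -> None:
        a = np.asarray(self.ages, float)
        f = np.asarray(self.cum_incidence, float)
        if a.size != f.size or a.size == 0:
            raise ValueError("ages and cum_incidence must have equal nonzero length")
        if np.any(np.diff(a) <= 0) or np.any(np.diff(f) < 0):
            raise ValueError("ages must increase and cum_incidence be nondecreasing")
        if f.min() < 0 or f.max() > 1:
            raise ValueError("cum_incidence must lie in [0,1]")

    @property
    def lifetime(self) -> float:
        return float(self.cum_incidence[-1])

    def at(self, age: float) -> float:
        return float(np.interp(age, self.ages, self.cum_incidence))

    def residual_risk(self, age: float) -> float:
        """Probability an unaffected subject of this age ever develops the
        disease: (F_inf - F(a)) / (1 - F(a))."""
        fa = self.at(age)
        if fa >= 1.0:
            return 0.0
        return max(self.lifetime - fa, 0.0) / (1.0 - fa)


@dataclass(frozen=True)
class PhenotypeDefinition:
    phenotype: str
    question_ids: tuple[str, ...]
    min_onset_age: float | None = None
    max_onset_age: float | None = None
    sex_restriction: str | None = None  # male | female
    smoking_restriction: bool | None = None
    control_age_rule: IncidenceCurve | None = None

    def __post_init__(self) -> None:
        if not self.question_ids:
            raise ValueError("question_ids must be nonempty")


@dataclass(frozen=True)
class PhenotypeAssignment:
    subject_id: str
    phenotype: str
    status: str  # case | control | excluded
    reason: str


def assign_case_control(
    responses: Iterable[SurveyResponse],
    defn: PhenotypeDefinition,
    subjects: Iterable[str] | None = None,
) -> list[PhenotypeAssignment]:
    """Raw case/control/excluded assignment from the answer pattern.

    ``subjects``, when given, lists everyone who should receive an
    assignment; those with no response to any of the phenotype's questions
    are excluded with reason ``no_response``.
    """
    qset = set(defn.question_ids)
    by_subject: dict[str, list[SurveyResponse]] = {}
    for r in responses:
        if r.question_id in qset:
            by_subject.setdefault(r.subject_id, []).append(r)

    ids = list(subjects) if subjects is not None else sorted(by_subject)
    out = []
    for sid in ids:
        rs = by_subject.get(sid, [])
        answers = {r.answer for r in rs}
        if not rs:
            out.append(PhenotypeAssignment(sid, defn.phenotype, "excluded", "no_response"))
        elif AFFIRMATIVE in answers and NEGATIVE in answers:
            out.append(PhenotypeAssignment(sid, defn.phenotype, "excluded", "inconsistent"))
        elif AFFIRMATIVE in answers:
            out.append(PhenotypeAssignment(sid, defn.phenotype, "case", "affirmative_response"))
        elif NEGATIVE in answers:
            out.append(PhenotypeAssignment(sid, defn.phenotype, "control", "negative_response"))
        else:
            out.append(PhenotypeAssignment(sid, defn.phenotype, "excluded", "uncertain"))
    return out


def restrict_controls_by_age(
    assignments: Iterable[PhenotypeAssignment],
    ages: Mapping[str, float],
    curve: IncidenceCurve,
    residual_max: float = 0.10,
) -> list[PhenotypeAssignment]:
    """Exclude controls young enough that their residual lifetime risk of
    the disease exceeds ``residual_max``.  Cases are never touched; if the
    lifetime risk itself is at most ``residual_max`` no control is
    excluded."""
    assignments = list(assignments)
    if curve.lifetime <= residual_max:
        return assignments
    out = []
    for a in assignments:
        if a.status != "control":
            out.append(a)
            continue
        age = ages.get(a.subject_id)
        if age is None:
            out.append(PhenotypeAssignment(a.subject_id, a.phenotype, "excluded", "missing_age"))
        elif curve.residual_risk(age) > residual_max:
            out.append(PhenotypeAssignment(a.subject_id, a.phenotype, "excluded", "control_too_young"))
        else:
            out.append(a)
    return out


def apply_onset_and_matching(
    assignments: Iterable[PhenotypeAssignment],
    responses: Iterable[SurveyResponse],
    defn: PhenotypeDefinition,
    covariates: Mapping[str, Mapping[str, object]] | None = None,
) -> list[PhenotypeAssignment]:
    """Apply onset-age windows to cases and sex/smoking restrictions to
    both groups.

    ``covariates`` maps subject id -> {"sex": "male"/"female",
    "smoker": bool, ...}; it is only consulted for active restrictions.
    """
    covariates = covariates or {}
    onset: dict[str, float] = {}
    qset = set(defn.question_ids)
    for r in responses:
        if r.question_id in qset and r.onset_age is not None:
            prev = onset.get(r.subject_id)
            onset[r.subject_id] = r.onset_age if prev is None else min(prev, r.onset_age)

    out = []
    for a in assignments:
        if a.status == "excluded":
            out.append(a)
            continue
        new = a
        if a.status == "case" and (defn.min_onset_age is not None or defn.max_onset_age is not None):
            oa = onset.get(a.subject_id)
            lo = defn.min_onset_age if defn.min_onset_age is not None else -np.inf
            hi = defn.max_onset_age if defn.max_onset_age is not None else np.inf
            if oa is None or not lo <= oa <= hi:
                new = PhenotypeAssignment(a.subject_id, a.phenotype, "excluded", "onset_outside_window")
        if new.status != "excluded" and defn.sex_restriction is not None:
            if covariates.get(a.subject_id, {}).get("sex") != defn.sex_restriction:
                new = PhenotypeAssignment(a.subject_id, a.phenotype, "excluded", "sex_restriction")
        if new.status != "excluded" and defn.smoking_restriction is not None:
            if covariates.get(a.subject_id, {}).get("smoker") != defn.smoking_restriction:
                new = PhenotypeAssignment(a.subject_id, a.phenotype, "excluded", "smoking_restriction")
        out.append(new)
    return out
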