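"""Coma Recovery Scale-Revised (CRS-R) data model.

The CRS-R rates six behavioural subscales — auditory (0-4), visual (0-5),
motor (0-6), oromotor/verbal (0-3), communication (0-2) and arousal (0-3) —
for a total of 0-23. From the item profile a diagnosis on the DoC spectrum is
derived: UWS (unresponsive wakefulness syndrome), MCS- / MCS+ (minimally
conscious state without/with language-related behaviour) and EMCS (emergence
from MCS). The item-level diagnostic rules here follow the standard published
CRS-R conventions: functional communication or functional object use denote
emergence; command following, intelligible verbalization or intentional
communication denote MCS+; visual fixation/pursuit, object
localization/manipulation or sound localization denote MCS-. Arousal does not
enter the diagnosis.

"Improvement" is a diagnosis-level criterion: a subject improves iff the
3-month diagnosis is strictly higher than the pre-operative one on the
UWS < MCS- < MCS+ < EMCS ordering; a higher total at the same diagnosis does
not count.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

from .errors import ValidationError

#: Subscale name -> maximum score.
SUBSCALE_MAX = {
    "auditory": 4,
    "visual": 5,
    "motor": 6,
    "oromotor": 3,
    "communication": 2,
    "arousal": 3,
}
SUBSCALES = tuple(SUBSCALE_MAX)

TIMEPOINTS = ("pre_op", "month3")


class DiagnosisLabel(IntEnum):
    """Diagnosis on the DoC spectrum, ordered for improvement comparison."""

    UWS = 0
    MCS_minus = 1
    MCS_plus = 2
    EMCS = 3

    def __str__(self) -> str:  # pretty labels for tables
        return {"UWS": "UWS", "MCS_minus": "MCS-",
                "MCS_plus": "MCS+", "EMCS": "EMCS"}[self.name]


@dataclass(frozen=True)
class CRSRAssessment:
    """One CRS-R administration (six integer subscale scores)."""

    auditory: int
    visual: int
    motor: int
    oromotor: int
    communication: int
    arousal: int
    timepoint: str = "pre_op"

    def __post_init__(self) -> None:
        for name, maximum in SUBSCALE_MAX.items():
            value = getattr(self, name)
            if int(value) != value or not (0 <= value <= maximum):
                raise ValidationError(
                    f"{name} score {value!r} outside its range 0..{maximum}"
                )
            object.__setattr__(self, name, int(value))
        if self.timepoint not in TIMEPOINTS:
            raise ValidationError(f"unknown timepoint {self.timepoint!r}")

    @property
    def scores(self) -> dict[str, int]:
        return {name: getattr(self, name) for name in SUBSCALES}


def validate(assessment: CRSRAssessment) -> CRSRAssessment:
    """Return the assessment if valid; construction already validates."""
    return CRSRAssessment(**{**assessment.scores, "timepoint": assessment.timepoint})


def total_score(assessment: CRSRAssessment) -> int:
    """Sum of the six subscales, 0-23."""
    return sum(assessment.scores.values())


def classify(a: CRSRAssessment) -> DiagnosisLabel:
    """Derive the DoC diagnosis from the item profile (arousal ignored)."""
    if a.communication == 2 or a.motor == 6:
        return DiagnosisLabel.EMCS
    if a.auditory >= 3 or a.oromotor == 3 or a.communication == 1:
        return DiagnosisLabel.MCS_plus
    if a.visual >= 2 or a.motor in (3, 4, 5) or a.auditory == 2:
        return DiagnosisLabel.MCS_minus
    return DiagnosisLabel.UWS


def improved(pre: DiagnosisLabel, post: DiagnosisLabel) -> bool:
    """True iff the diagnosis moved strictly up the DoC ordering."""
    return post > pre


def standardize(assessment: CRSRAssessment) -> dict[str, float]:
    """Map each subscale linearly onto [0, 1] (raw / subscale maximum)."""
    return {name: getattr(assessment, name) / maximum
            for name, maximum in SUBSCALE_MAX.items()}


def unstandardize(scores: dict[str, float], timepoint: str = "pre_op") -> CRSRAssessment:
    """Inverse of :func:`standardize` on the valid integer grid."""
    raw = {}
    for name, maximum in SUBSCALE_MAX.items():
        value = scores[name] * maximum
        if abs(value - round(value)) > 1e-9:
            raise ValidationError(f"{name}={scores[name]} is not on the score grid")
        raw[name] = int(round(value))
    return CRSRAssessment(**raw, timepoint=timepoint)
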