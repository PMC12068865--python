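"""Per-criterion verdicts and the accessibility score.

The screening instrument has 17 equally weighted transparency criteria,
listed in :class:`Criterion` in instrument order. An article's accessibility
score is the fraction of criteria it satisfies out of the criteria applicable
to its study type. The denominator depends only on the study type: 17 for
materials-capable empirical types, 15 for meta-analyses / systematic reviews
and nonclinical secondary-data analyses (which cannot share materials, so the
two materials items are dropped). Non-empirical articles are not scored.

Conditional criteria (e.g. "can you open the data files") stay in the
denominator even when their gating statement is negative — they are simply
unsatisfied — so the score denominator is constant within a study type.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .schema_io import (
    MATERIALS_EXEMPT_TYPES,
    AvailabilityStatement,
    CoiStatement,
    FundingStatement,
    OpenAccess,
    PreregStatement,
    RecordSet,
    RecordValidationError,
    ScreeningRecord,
    StudyAspect,
    StudyType,
    TriState,
    validate_record,
)

__all__ = [
    "Criterion",
    "CriterionResult",
    "AccessibilityScore",
    "NotScorableError",
    "applicable_criteria",
    "evaluate_criteria",
    "accessibility_score",
    "score_record",
    "prereg_completeness",
    "score_table",
]

_ALL_ASPECTS = frozenset(StudyAspect)


class Criterion(str, Enum):
    """The 17 instrument criteria, in coding-form order."""

    STUDY_TYPE_STATED = "STUDY_TYPE_STATED"
    MATERIALS_STATEMENT = "MATERIALS_STATEMENT"
    MATERIALS_ACCESSIBLE = "MATERIALS_ACCESSIBLE"
    DATA_STATEMENT = "DATA_STATEMENT"
    DATA_ACCESSIBLE = "DATA_ACCESSIBLE"
    DATA_DOCUMENTED = "DATA_DOCUMENTED"
    DATA_COMPLETE = "DATA_COMPLETE"
    SCRIPTS_STATEMENT = "SCRIPTS_STATEMENT"
    SCRIPTS_ACCESSIBLE = "SCRIPTS_ACCESSIBLE"
    PREREG_STATEMENT = "PREREG_STATEMENT"
    PREREG_ACCESSIBLE = "PREREG_ACCESSIBLE"
    PREREG_ASPECTS_COMPLETE = "PREREG_ASPECTS_COMPLETE"
    PROTOCOL_LINKED = "PROTOCOL_LINKED"
    PROTOCOL_ASPECTS_COMPLETE = "PROTOCOL_ASPECTS_COMPLETE"
    COI_STATEMENT = "COI_STATEMENT"
    FUNDING_STATEMENT = "FUNDING_STATEMENT"
    OPEN_ACCESS = "OPEN_ACCESS"


#: The two criteria dropped for study types without shareable materials.
MATERIALS_CRITERIA = frozenset(
    {Criterion.MATERIALS_STATEMENT, Criterion.MATERIALS_ACCESSIBLE}
)


class NotScorableError(ValueError):
    """Raised when scoring is requested for a non-empirical article."""


@dataclass(frozen=True)
class CriterionResult:
    criterion: Criterion
    applicable: bool
    satisfied: bool

    def __post_init__(self) -> None:
        if self.satisfied and not self.applicable:
            raise ValueError(f"{self.criterion.value}: satisfied implies applicable")


@dataclass(frozen=True)
class AccessibilityScore:
    """Satisfied / applicable criterion counts and their ratio."""

    numerator: int
    denominator: int

    def __post_init__(self) -> None:
        if not 0 <= self.numerator <= self.denominator:
            raise ValueError("numerator must lie in [0, denominator]")

    @property
    def value(self) -> float:
        return self.numerator / self.denominator


def applicable_criteria(study_type: StudyType) -> frozenset[Criterion]:
    """Criteria entering the score denominator for a study type."""
    if study_type is StudyType.NON_EMPIRICAL:
        raise NotScorableError("non-empirical articles are not scored")
    if study_type in MATERIALS_EXEMPT_TYPES:
        return frozenset(Criterion) - MATERIALS_CRITERIA
    return frozenset(Criterion)


# Per-criterion satisfaction predicates, keyed by criterion.
_SATISFIED = {
    Criterion.STUDY_TYPE_STATED: lambda r: r.study_type_stated,
    Criterion.MATERIALS_STATEMENT: lambda r: r.materials_statement
    is AvailabilityStatement.YES_AVAILABLE,
    Criterion.MATERIALS_ACCESSIBLE: lambda r: r.materials_accessible is TriState.YES,
    Criterion.DATA_STATEMENT: lambda r: r.data_statement
    is AvailabilityStatement.YES_AVAILABLE,
    Criterion.DATA_ACCESSIBLE: lambda r: r.data_accessible is TriState.YES,
    Criterion.DATA_DOCUMENTED: lambda r: r.data_documented is TriState.YES,
    Criterion.DATA_COMPLETE: lambda r: r.data_complete is TriState.YES,
    Criterion.SCRIPTS_STATEMENT: lambda r: r.scripts_statement
    is AvailabilityStatement.YES_AVAILABLE,
    Criterion.SCRIPTS_ACCESSIBLE: lambda r: r.scripts_accessible is TriState.YES,
    Criterion.PREREG_STATEMENT: lambda r: r.prereg_statement is PreregStatement.YES,
    Criterion.PREREG_ACCESSIBLE: lambda r: r.prereg_accessible is TriState.YES,
    Criterion.PREREG_ASPECTS_COMPLETE: lambda r: r.prereg_aspects == _ALL_ASPECTS,
    Criterion.PROTOCOL_LINKED: lambda r: r.protocol_linked,
    Criterion.PROTOCOL_ASPECTS_COMPLETE: lambda r: r.protocol_aspects == _ALL_ASPECTS,
    Criterion.COI_STATEMENT: lambda r: r.coi_statement is not CoiStatement.ABSENT,
    Criterion.FUNDING_STATEMENT: lambda r: r.funding_statement
    is not FundingStatement.ABSENT,
    Criterion.OPEN_ACCESS: lambda r: r.open_access is not OpenAccess.NO,
}


def evaluate_criteria(record: ScreeningRecord) -> list[CriterionResult]:
    """One verdict per applicable criterion, in instrument order."""
    violations = validate_record(record)
    if violations:
        raise RecordValidationError("; ".join(violations))
    applicable = applicable_criteria(record.study_type)
    return [
        CriterionResult(criterion=c, applicable=True, satisfied=bool(_SATISFIED[c](record)))
        for c in Criterion
        if c in applicable
    ]


def accessibility_score(results: list[CriterionResult]) -> AccessibilityScore:
    """Fraction of satisfied criteria out of all applicable ones."""
    if not results:
        raise ValueError("accessibility_score requires at least one criterion result")
    denominator = sum(1 for r in results if r.applicable)
    if denominator == 0:
        raise ValueError("no applicable criteria")
    numerator = sum(1 for r in results if r.satisfied)
    return AccessibilityScore(numerator=numerator, denominator=denominator)


def score_record(record: ScreeningRecord) -> AccessibilityScore:
    return accessibility_score(evaluate_criteria(record))


def prereg_completeness(record: ScreeningRecord) -> int:
    """Number of pre-registered aspects (0-3); 0 unless the
    pre-registration is accessible."""
    violations = validate_record(record)
    if violations:
        raise RecordValidationError("; ".join(violations))
    if record.prereg_accessible is not TriState.YES:
        return 0
    return len(record.prereg_aspects)


def score_table(rs: RecordSet) -> pd.DataFrame:
    """Per-article score table over the empirical records of a RecordSet.

    Columns: article_id, journal, study_type, numerator, denominator, score.
    """
    rows = []
    for rec in rs.empirical:
        s = score_record(rec)
        rows.append(
            {
                "article_id": rec.article_id,
                "journal": rec.journal.value,
                "study_type": rec.study_type.value,
                "numerator": s.numerator,
                "denominator": s.denominator,
                "score": s.value,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["article_id", "journal", "study_type", "numerator", "denominator", "score"],
    )
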